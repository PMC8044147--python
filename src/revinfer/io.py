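"""Delimited trial tables and JSON sidecars.

One row per trial; per-stimulus vectors (tilts, orientations) are stored
as semicolon-joined decimal strings so the table stays a plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .task import Block, StimulusSequence, TaskConfig, Trial

__all__ = ["blocks_to_table", "table_to_blocks", "write_blocks", "read_blocks"]


def _join(v) -> str:
    return ";".join(f"{x:.10g}" for x in np.atleast_1d(v))


def _split(s: str) -> np.ndarray:
    return np.array([float(x) for x in str(s).split(";")])


def blocks_to_table(
    blocks: list[Block],
    responses: list[np.ndarray] | None = None,
    subject: int | None = None,
) -> pd.DataFrame:
    rows = []
    for b_idx, block in enumerate(blocks):
        resp = responses[b_idx] if responses is not None else [None] * block.n_trials
        for t, trial in enumerate(block.trials):
            seq = trial.sequence
            rows.append(
                {
                    "subject": subject if subject is not None else 0,
                    "block": b_idx,
                    "pair_id": block.pair_id,
                    "condition": block.condition,
                    "volatility": block.volatility,
                    "initial_response": block.initial_response,
                    "trial": t,
                    "episode": trial.episode_id,
                    "state": trial.state,
                    "category": trial.category,
                    "n_stimuli": seq.n,
                    "mu_a": seq.mu_a,
                    "tilts": _join(seq.tilts),
                    "orientations": (
                        _join(seq.orientations) if seq.orientations is not None else ""
                    ),
                    "response": resp[t] if resp[t] is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def table_to_blocks(
    df: pd.DataFrame, config: TaskConfig | None = None
) -> tuple[list[Block], list[np.ndarray]]:
    config = config or TaskConfig()
    blocks, responses = [], []
    for b_idx, grp in df.groupby("block", sort=True):
        grp = grp.sort_values("trial")
        trials = []
        for _, row in grp.iterrows():
            seq = StimulusSequence(
                tilts=_split(row["tilts"]),
                mu_a=float(row["mu_a"]),
                orientations=(
                    _split(row["orientations"]) if row["orientations"] else None
                ),
            )
            trials.append(
                Trial(
                    index=int(row["trial"]),
                    episode_id=int(row["episode"]),
                    state=int(row["state"]),
                    sequence=seq,
                    category=(
                        int(row["category"]) if not pd.isna(row["category"]) else None
                    ),
                    response=(
                        int(row["response"]) if not pd.isna(row["response"]) else None
                    ),
                )
            )
        first = grp.iloc[0]
        blocks.append(
            Block(
                trials=trials,
                condition=str(first["condition"]),
                volatility=str(first["volatility"]),
                initial_response=int(first["initial_response"]),
                pair_id=int(first["pair_id"]),
                config=config,
            )
        )
        resp = grp["response"].to_numpy()
        responses.append(
            resp.astype(int) if not np.any(pd.isna(resp)) else resp
        )
    return blocks, responses


def write_blocks(
    path: str | Path,
    blocks: list[Block],
    responses: list[np.ndarray] | None = None,
    config: TaskConfig | None = None,
    meta: dict | None = None,
) -> None:
    path = Path(path)
    blocks_to_table(blocks, responses).to_csv(path, index=False)
    sidecar = {"config": asdict(config or blocks[0].config)}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_blocks(path: str | Path) -> tuple[list[Block], list[np.ndarray], dict]:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=True, na_values=[""])
    df["orientations"] = df["orientations"].fillna("")
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    cfg_fields = meta.get("config", {})
    config = TaskConfig(
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg_fields.items()
            if k in TaskConfig.__dataclass_fields__
        }
    )
    blocks, responses = table_to_blocks(df, config)
    return blocks, responses, meta
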