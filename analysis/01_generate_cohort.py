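"""Generate a synthetic cohort and verify the task design.

Creates a small cohort (6 subjects by default) of evidence-matched
cue-based/outcome-based blocks with noisy-Bayesian responses, writes the
per-subject trial tables to results/cohort/, and prints design checks:
episode counts per volatility, evidence matching across matched pairs,
and overall response accuracy per condition.
"""

import sys
from pathlib import Path

import numpy as np

from revinfer import io as rio
from revinfer.inference import accuracy, block_evidence
from revinfer.synthetic import CohortSpec, generate_cohort
from revinfer.task import TaskConfig

SEED = 20_240
N_SUBJECTS = 6


def main() -> int:
    out_dir = Path("results/cohort")
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    config = TaskConfig()
    spec = CohortSpec(n_subjects=N_SUBJECTS)
    cohort = generate_cohort(spec, config, rng)

    acc = {"Cb": [], "Ob": []}
    for subj in cohort:
        rio.write_blocks(
            out_dir / f"subject_{subj.subject:02d}.csv",
            subj.blocks,
            subj.responses,
            config,
            meta={"subject": subj.subject, "seed": SEED},
        )
        by_pair = {}
        for block, resp in zip(subj.blocks, subj.responses):
            acc[block.condition].append(accuracy(resp, block.states))
            by_pair.setdefault(block.pair_id, []).append(block)
            n_ep = len(np.unique(block.episode_ids))
            assert n_ep == (6 if block.volatility == "stable" else 12)
        for pair in by_pair.values():
            ev = [block_evidence(b)[0] for b in pair]
            assert np.allclose(ev[0], ev[1], atol=1e-12)

    print(f"wrote {N_SUBJECTS} subjects to {out_dir}")
    print("episode counts: 6 (stable) / 12 (volatile) in every block")
    print("evidence streams identical within every matched Cb/Ob pair")
    for cond in ("Cb", "Ob"):
        print(f"accuracy {cond}: {100 * np.mean(acc[cond]):.1f}%")
    return 0


if __name__ == "__main__":
    sys.exit(main())
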