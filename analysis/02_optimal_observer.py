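"""Simulate the Bayes-optimal and group-mean noisy observers.

Reports (a) the optimal observer's accuracy over many synthetic
sessions, by volatility, and (b) the increase in mean absolute prior
belief produced by the lower outcome-based hazard rate on matched
blocks. Writes a summary table to results/optimal_observer.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from revinfer.inference import (
    OPTIMAL_PARAMS,
    ModelParams,
    accuracy,
    simulate_responses,
)
from revinfer.task import TaskConfig, generate_block_pair

SEED = 20_241
N_SESSIONS = 50
CB = ModelParams(h=0.191, sigma_inf=0.512)
OB = ModelParams(h=0.115, sigma_inf=0.550)


def main() -> int:
    rng = np.random.default_rng(SEED)
    config = TaskConfig()
    rows = []
    priors = {"Cb": [], "Ob": []}
    for session in range(N_SESSIONS):
        for vol in ("stable", "stable", "volatile", "volatile"):
            cb, ob = generate_block_pair(config, vol, rng)
            for block in (cb, ob):
                r, _ = simulate_responses(OPTIMAL_PARAMS, block, rng)
                rows.append(
                    {"session": session, "volatility": vol,
                     "condition": block.condition, "model": "optimal",
                     "accuracy": accuracy(r, block.states)}
                )
            _, t_cb = simulate_responses(CB, cb, rng)
            _, t_ob = simulate_responses(OB, ob, rng)
            priors["Cb"].append(np.abs(t_cb.prior))
            priors["Ob"].append(np.abs(t_ob.prior))

    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/optimal_observer.csv", index=False)

    overall = 100 * df["accuracy"].mean()
    by_vol = df.groupby("volatility")["accuracy"].mean() * 100
    mean_cb = np.mean(np.concatenate(priors["Cb"]))
    mean_ob = np.mean(np.concatenate(priors["Ob"]))
    boost = 100 * (mean_ob / mean_cb - 1)

    print(f"optimal accuracy: {overall:.1f}% "
          f"(stable {by_vol['stable']:.1f}%, volatile {by_vol['volatile']:.1f}%)")
    print(f"mean |prior| Cb {mean_cb:.3f}, Ob {mean_ob:.3f} -> boost {boost:.1f}%")
    print("note: under i.i.d. kappa=0.5 sequences the optimal accuracy sits")
    print("around 83%, see docs/methods.md for the analysis of this ceiling")
    return 0


if __name__ == "__main__":
    sys.exit(main())
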