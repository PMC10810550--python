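#!/usr/bin/env python
"""Run the reduced simulation study over the full 16-scenario grid.

Compares the ML and Bayesian NB models across dispersion theta in
{1.5, 5, 10, 100} and series length n in {60, 120, 240, 360} with a
desk-scale number of replicates and short MCMC chains, then writes the
wide summary (results/table1.csv) and the per-replicate records
(results/replicates.csv).  With the study's residual-perturbation
generator the rows are expected to be nearly identical across theta.
"""

import argparse
import time
import warnings
from pathlib import Path

from firefreq import evaluation as ev
from firefreq import models as m
from firefreq import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=10,
                        help="replicates per scenario (default %(default)s)")
    parser.add_argument("--seed", type=int, default=76568)
    args = parser.parse_args()
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)

    grid = syn.scenario_grid(
        [1.5, 5.0, 10.0, 100.0], [60, 120, 240, 360],
        n_replicates=args.reps, master_seed=args.seed,
    )
    sampler = m.SamplerSettings(n_walkers=12, n_warmup=300, n_keep=150, thin=2)
    t0 = time.time()
    records, reps = ev.run_simulation_study(
        grid, sampler=sampler, return_replicates=True
    )
    table1 = ev.summarize_study(records)
    table1.to_csv(OUT / "table1.csv", index=False)
    reps.to_csv(OUT / "replicates.csv", index=False)

    print(table1.round(3).to_string(index=False))
    print(f"\n{len(grid)} scenarios x {args.reps} replicates in "
          f"{time.time() - t0:.0f} s; wrote table1.csv and replicates.csv to {OUT}")

    bnb_better_mase = (table1["BNB_mase"] < table1["NB_mase"]).sum()
    nb_better_bias = (table1["NB_bias"].abs() < table1["BNB_bias"].abs()).sum()
    print(f"\nBNB has lower test MASE in {bnb_better_mase}/16 cells; "
          f"NB has smaller |bias| in {nb_better_bias}/16 cells.")
    ref = table1[table1["n"] == 60]
    spread = ref["NB_mase"].max() - ref["NB_mase"].min()
    print(f"across theta at n=60, NB MASE varies by only {spread:.3g} — "
          "the residual-perturbation generator makes dispersion inert.")


if __name__ == "__main__":
    main()
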