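#!/usr/bin/env python
"""Power of the pair screen vs LD-pruning level on planted-epistasis cohorts.

Runs the desk-scale power grid (two 100-SNP segments, 91 founders expanded to
2,000; 500 cases + 500 controls; beta3 = 1.2; 20 replicates x 199
permutations) for the four causal-placement settings: A (both DSLs in one
block), B (second DSL mid-block elsewhere), C (second DSL at a block edge),
D (DSLs on different chromosomes).  Each replicate is screened unpruned and
after sliding-window pruning at r2 <= 0.75/0.60/0.50/0.20, and exact/signal
sensitivities are aggregated into results/sensitivity.tsv.

Finding (synthetic panels): signal sensitivity dominates exact sensitivity
everywhere; pruning that removes a causal SNP collapses exact sensitivity
while tag-based signal sensitivity survives; the r2 >= 0.20 tag definition
captures at least as much signal as r2 >= 0.45.

Pass ``--settings A`` for a quicker single-setting run (~2 min); the full
four-setting grid takes ~10 min.
"""

import argparse
import time
from pathlib import Path

import dataclasses

from epildsim import pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--settings", nargs="+", default=["A", "B", "C", "D"])
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = dataclasses.replace(
        pipeline.ScenarioConfig.scaled(master_seed=args.seed),
        settings=tuple(args.settings),
    )
    t0 = time.time()
    df = pipeline.run_grid(cfg, verbose=False)
    df.to_csv(args.out / "sensitivity.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\n{cfg.n_datasets} datasets screened in {time.time() - t0:.0f} s")
    ok = (df["signal_sensitivity_r2_0.2"] >= df["exact_sensitivity"]).all()
    print("signal >= exact everywhere:", ok)


if __name__ == "__main__":
    main()
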