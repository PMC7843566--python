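"""Replicate analysis: how reliably does the group pattern reproduce?

Draws 200 cohorts from the published group summary statistics and records
the Kruskal-Wallis p-value of every parameter in each replicate. The
perfusion parameters (peak amplitude, steepness) reject essentially always
at alpha 0.05; the timing parameters reach the 0.001 level only rarely —
but, because the published per-group means for time-to-peak and duration
differ by up to ~0.8 SD, independent resimulation of those printed values
rejects them at 0.05 far more often than the original data did. The
replicate table quantifies this. Writes results/significance_pattern.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from onhpleth.cohort import PARAMETERS
from onhpleth.stats import simulate_headline_pattern

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    pvals = simulate_headline_pattern(n_replicates=200, seed=SEED)
    out = ROOT / "results" / "significance_pattern.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pvals.to_csv(out, index=False)

    print(f"{'parameter':15s} {'p<0.001':>8s} {'p<0.05':>8s} {'median p':>10s} {'p95':>10s}")
    for p in PARAMETERS:
        print(f"{p:15s} {np.mean(pvals[p] < 0.001):8.3f} {np.mean(pvals[p] < 0.05):8.3f} "
              f"{np.median(pvals[p]):10.2e} {np.percentile(pvals[p], 95):10.2e}")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
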