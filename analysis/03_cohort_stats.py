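"""Cohort analysis on one synthetic cohort calibrated to the study groups.

Draws a 110-subject cohort (norm 19, OHT 17, prep 24, perim 50) from the
published group summary statistics, then runs the full statistics layer:
per-group summaries, Kruskal-Wallis omnibus tests, Mann-Whitney tests vs
normals with Bonferroni correction, Spearman correlation with RNFL
thickness, regression slopes per 10 um RNFL, and the test-retest CV from
a simulated repeated-measurement session. Writes tables and figures under
results/cohort/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"

from onhpleth.cohort import PARAMETERS, generate_cohort, generate_repeated_measurements, write_cohort_csv
from onhpleth import stats
from onhpleth.cli import _figures

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = generate_cohort(seed=SEED)
    write_cohort_csv(table, OUT / "cohort.csv")

    summary = stats.group_summary(table)
    summary.to_csv(OUT / "group_summary.csv", index=False)
    print("per-group mean +- SD (synthetic cohort):")
    for _, row in summary.iterrows():
        print(f"  {row['group']:5s} n={row['n']:3.0f} amplitude "
              f"{row['peak_amplitude_mean']:.2f} +- {row['peak_amplitude_sd']:.2f} %A, "
              f"steepness {row['steepness_mean']:.2f} +- {row['steepness_sd']:.2f} %A/s")

    rows = []
    for p in PARAMETERS:
        h, pval = stats.kruskal_wallis(table, p)
        rows.append({"parameter": p, "test": "kruskal_wallis", "stat": h, "p": pval})
        for _, r in stats.pairwise_vs_normal(table, p).iterrows():
            rows.append({
                "parameter": p, "test": f"mannwhitney_{r['group']}_vs_norm",
                "stat": r["U"], "p": r["p_raw"], "p_bonferroni": r["p_bonferroni"],
                "significant": r["significant"],
            })
        r_s, p_s = stats.spearman(table, p)
        rows.append({"parameter": p, "test": "spearman_rnfl", "stat": r_s, "p": p_s})
    tests = pd.DataFrame(rows)
    tests.to_csv(OUT / "tests.csv", index=False)

    kw = tests[tests["test"] == "kruskal_wallis"].set_index("parameter")["p"]
    print("\nKruskal-Wallis p-values:")
    for p in PARAMETERS:
        verdict = "< 0.001" if kw[p] < 0.001 else ("n.s." if kw[p] >= 0.05 else f"{kw[p]:.3f}")
        print(f"  {p:15s} {verdict}")

    for p in ("peak_amplitude", "steepness"):
        r_s = tests.query("parameter == @p and test == 'spearman_rnfl'")["stat"].iloc[0]
        slope10, _ = stats.regression_slope(table, p)
        print(f"{p}: Spearman R vs RNFL {r_s:.3f}, slope {slope10:.2f} per 10 um RNFL")

    repeats = generate_repeated_measurements(n_subjects=9, cv=0.086, seed=SEED)
    cv = stats.cv_repeated(repeats, "peak_amplitude")
    print(f"test-retest CV (9 subjects, 2 repeats, generated at 0.086): {cv:.3f}")
    pd.DataFrame([{"parameter": "peak_amplitude", "cv": cv}]).to_csv(OUT / "cv.csv", index=False)

    _figures(table, OUT)
    print(f"wrote tables and figures to {OUT}")


if __name__ == "__main__":
    main()
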