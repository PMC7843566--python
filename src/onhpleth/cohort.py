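"""Synthetic subject cohorts calibrated to published group statistics.

The study population is four diagnostic groups — normal controls (norm),
ocular hypertension (OHT), preperimetric glaucoma (prep), and perimetric
glaucoma (perim) — each summarized by mean +/- SD of seven pulse-waveform
parameters and of RNFL thickness. The generator draws per-subject values
from truncated-normal marginals (truncated at 0: all parameters are
positive) and couples peak amplitude and steepness to RNFL thickness
through a Gaussian copula at a requested Spearman rank correlation, so the
group-comparison and correlation analyses can be exercised on cohorts with
known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

PARAMETERS = (
    "peak_amplitude",
    "steepness",
    "ttp_s",
    "ttp_pct",
    "fwhm_s",
    "fwhm_pct",
    "duration_s",
)

GROUPS = ("norm", "OHT", "prep", "perim")

# Published per-group calibration: n, then (mean, SD) of the seven pulse
# parameters in PARAMETERS order, then (mean, SD) RNFL thickness in um.
DEFAULT_GROUP_STATS: dict[str, dict] = {
    "norm": {
        "n": 19,
        "peak_amplitude": (5.86, 1.84),
        "steepness": (29.23, 6.72),
        "ttp_s": (0.34, 0.09),
        "ttp_pct": (33.09, 7.67),
        "fwhm_s": (0.56, 0.12),
        "fwhm_pct": (50.29, 8.93),
        "duration_s": (1.05, 0.18),
        "rnfl_um": (92.45, 9.81),
    },
    "OHT": {
        "n": 17,
        "peak_amplitude": (6.60, 2.41),
        "steepness": (32.55, 9.98),
        "ttp_s": (0.30, 0.05),
        "ttp_pct": (32.25, 7.30),
        "fwhm_s": (0.51, 0.08),
        "fwhm_pct": (50.68, 7.16),
        "duration_s": (0.94, 0.16),
        "rnfl_um": (92.82, 9.62),
    },
    "prep": {
        "n": 24,
        "peak_amplitude": (5.17, 1.80),
        "steepness": (24.27, 9.33),
        "ttp_s": (0.35, 0.08),
        "ttp_pct": (32.54, 5.29),
        "fwhm_s": (0.55, 0.12),
        "fwhm_pct": (47.28, 7.72),
        "duration_s": (1.08, 0.13),
        "rnfl_um": (76.10, 14.32),
    },
    "perim": {
        "n": 50,
        "peak_amplitude": (4.06, 1.67),
        "steepness": (18.84, 8.26),
        "ttp_s": (0.35, 0.08),
        "ttp_pct": (35.88, 7.27),
        "fwhm_s": (0.55, 0.09),
        "fwhm_pct": (51.86, 7.61),
        "duration_s": (1.00, 0.17),
        "rnfl_um": (61.36, 11.54),
    },
}


@dataclass
class CohortSpec:
    """Per-group sample sizes and marginals plus the RNFL coupling.

    rho_amp_rnfl / rho_steep_rnfl are the within-group Spearman rank
    correlations of peak amplitude and steepness with RNFL thickness
    (defaults: the pooled correlations reported for the real cohort).
    """

    group_stats: dict[str, dict] = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_STATS.items()})
    rho_amp_rnfl: float = 0.523
    rho_steep_rnfl: float = 0.568
    seed: int = 0

    def __post_init__(self) -> None:
        for g, stats in self.group_stats.items():
            if stats["n"] <= 0:
                raise ValueError(f"group {g!r}: n must be positive")
            for key, val in stats.items():
                if key == "n":
                    continue
                if val[1] < 0:
                    raise ValueError(f"group {g!r}: SD of {key} must be non-negative")
        for rho in (self.rho_amp_rnfl, self.rho_steep_rnfl):
            if abs(rho) > 1:
                raise ValueError("rank correlations must lie in [-1, 1]")


def _latent_rho(rho_spearman: float) -> float:
    """Gaussian-copula latent correlation giving a target Spearman rho."""
    return float(np.clip(2.0 * np.sin(np.pi * rho_spearman / 6.0), -1.0, 1.0))


def _truncnorm_from_latent(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal latents to a zero-truncated normal marginal."""
    if sd == 0:
        return np.full_like(z, mean, dtype=float)
    a = (0.0 - mean) / sd
    u = norm.cdf(z)
    # clip away exact 0/1 so ppf stays finite
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort.

    Returns a table with one row per subject and columns
    ``subject_id, group, <seven parameters>, rnfl_um``. Reproducible for a
    fixed spec and seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rho_l = {
        "peak_amplitude": _latent_rho(spec.rho_amp_rnfl),
        "steepness": _latent_rho(spec.rho_steep_rnfl),
    }
    rows = []
    for group in spec.group_stats:
        stats = spec.group_stats[group]
        n = stats["n"]
        z_rnfl = rng.standard_normal(n)
        rnfl = _truncnorm_from_latent(z_rnfl, *stats["rnfl_um"])
        values: dict[str, np.ndarray] = {"rnfl_um": rnfl}
        for p in PARAMETERS:
            eps = rng.standard_normal(n)
            if p in rho_l:
                r = rho_l[p]
                z = r * z_rnfl + np.sqrt(max(1.0 - r * r, 0.0)) * eps
            else:
                z = eps
            values[p] = _truncnorm_from_latent(z, *stats[p])
        for i in range(n):
            rows.append(
                {"subject_id": f"{group}_{i + 1:03d}", "group": group}
                | {p: values[p][i] for p in PARAMETERS}
                | {"rnfl_um": values["rnfl_um"][i]}
            )
    return pd.DataFrame(rows)


def generate_repeated_measurements(
    n_subjects: int = 9,
    parameter: str = "peak_amplitude",
    cv: float = 0.086,
    seed: int = 0,
) -> pd.DataFrame:
    """Two repeated measurements per subject with a known per-measurement CV.

    Each measurement is the subject's true value times ``(1 + e)`` with
    ``e ~ N(0, cv)``, so the repeated-measures ANOVA coefficient of
    variation of the resulting table has expectation ``cv``.
    """
    rng = np.random.default_rng(seed)
    mean, sd = DEFAULT_GROUP_STATS["norm"][parameter]
    a = (0.0 - mean) / sd
    true = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n_subjects, random_state=rng)
    rows = []
    for i, t in enumerate(true):
        for rep in (1, 2):
            rows.append(
                {
                    "subject_id": f"rep_{i + 1:03d}",
                    "group": "norm",
                    "repeat_id": rep,
                    parameter: t * (1.0 + rng.normal(0.0, cv)),
                }
            )
    return pd.DataFrame(rows)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    cols = ["subject_id", "group", *PARAMETERS, "rnfl_um"]
    table[cols].to_csv(path, index=False)
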