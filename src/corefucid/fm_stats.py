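"""Case/control statistics of characteristic-ion intensities.

The log10 relative intensity of each characteristic ion is approximately
Gaussian within a cohort. Comparing the FUT8-knockout case cohort (pure nCF)
with the wild-type control cohort (CF + nCF mixture) per ion quantifies the
fucose-migration / fucose-release battle:

* per-ion Gaussian fits N(μ, σ) of log10 relative intensity,
* the symmetrized Kullback–Leibler distance
  D(P, Q) = (KL(P‖Q) + KL(Q‖P)) / 2 between case and control,
* the fucose-migration ratio 100·10^(μ_YiF − μ_Yi) within the case cohort —
  how intense the (purely migration-born) YiF peak typically is relative to
  its Yi parent.

Unmatched (zero) intensities are excluded before the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glyco_core import CI_LABELS


@dataclass(frozen=True)
class CohortGaussian:
    """Gaussian fit of log10 relative intensity for one ion in one cohort."""

    ci_index: int  # 1..10
    cohort: str  # "case" | "control"
    mu: float
    sigma: float
    n: int


def fit_log_gaussian(intensities) -> tuple[float, float]:
    """Sample mean and standard deviation (ddof=1) of log10(intensities).

    Zeros (unmatched ions) must be filtered out upstream; any non-positive
    value is rejected since its log is undefined.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values to fit mean and sd")
    if np.any(x <= 0):
        raise ValueError("non-positive intensity passed to log10 fit; pre-filter zeros")
    logs = np.log10(x)
    return float(np.mean(logs)), float(np.std(logs, ddof=1))


def kl_gaussian(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Closed-form KL(P‖Q) for univariate Gaussians given as (mean, sd)."""
    mu_p, s_p = p
    mu_q, s_q = q
    if s_p <= 0 or s_q <= 0:
        raise ValueError("standard deviations must be positive")
    return float(
        np.log(s_q / s_p) + (s_p**2 + (mu_p - mu_q) ** 2) / (2 * s_q**2) - 0.5
    )


def symmetric_kl_gaussian(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Symmetrized Gaussian KL distance (KL(P‖Q) + KL(Q‖P)) / 2."""
    return 0.5 * (kl_gaussian(p, q) + kl_gaussian(q, p))


def fm_ratio(mu_yif: float, mu_yi: float) -> float:
    """Fucose-migration ratio in percent: 100·10^(μ_YiF − μ_Yi).

    The mode of a log10-Gaussian intensity is 10^mean, so this is the ratio
    of the most-popular YiF intensity to the most-popular Yi intensity.
    """
    return 100.0 * 10.0 ** (mu_yif - mu_yi)


def build_kl_report(
    case_vectors,
    control_vectors,
    min_n: int = 30,
) -> pd.DataFrame:
    """Per-ion case/control Gaussian fits, KL distances and FM ratios.

    Parameters
    ----------
    case_vectors, control_vectors : sequence of CIFeatureVector or (n, 10) array
        Raw relative intensities; zeros are treated as unmatched and dropped
        per ion before fitting.
    min_n : int
        Minimum matched values per ion per cohort; ions below it get NaN
        fits (flagged absent rather than zero).

    Returns
    -------
    DataFrame indexed CI1..CI10 with columns case_mu, case_sigma, case_n,
    control_mu, control_sigma, control_n, kl_distance, and fm_ratio_pct on
    the Y1F..Y5F rows (ratio of that ion to its unfucosylated parent within
    the case cohort).
    """
    X_case = _as_matrix(case_vectors)
    X_ctrl = _as_matrix(control_vectors)
    if len(X_case) == 0 or len(X_ctrl) == 0:
        raise ValueError("both cohorts must be nonempty")

    rows = []
    fits: dict[tuple[str, int], tuple[float, float]] = {}
    for i in range(10):
        row: dict = {"ci": CI_LABELS[i]}
        for cohort, X in (("case", X_case), ("control", X_ctrl)):
            vals = X[:, i]
            vals = vals[vals > 0]
            row[f"{cohort}_n"] = int(vals.size)
            if vals.size >= max(min_n, 2):
                mu, sigma = fit_log_gaussian(vals)
                fits[(cohort, i)] = (mu, sigma)
                row[f"{cohort}_mu"] = mu
                row[f"{cohort}_sigma"] = sigma
            else:
                row[f"{cohort}_mu"] = np.nan
                row[f"{cohort}_sigma"] = np.nan
        p, q = fits.get(("case", i)), fits.get(("control", i))
        row["kl_distance"] = symmetric_kl_gaussian(p, q) if p and q else np.nan
        rows.append(row)
    # FM ratios: YiF (index i+5) vs Yi within the case cohort
    for i in range(5):
        p_yi, p_yif = fits.get(("case", i)), fits.get(("case", i + 5))
        rows[i + 5]["fm_ratio_pct"] = (
            fm_ratio(p_yif[0], p_yi[0]) if p_yi and p_yif else np.nan
        )
        rows[i]["fm_ratio_pct"] = np.nan
    df = pd.DataFrame(rows).set_index("ci")
    return df


def _as_matrix(vectors) -> np.ndarray:
    arr = np.asarray(vectors, dtype=object)
    if arr.ndim == 2 or (arr.ndim == 1 and arr.size and np.isscalar(arr[0])):
        return np.asarray(vectors, dtype=np.float64)
    from .features import feature_matrix

    return feature_matrix(list(vectors), normalized=False)
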