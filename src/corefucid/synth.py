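"""Synthetic feature cohorts and toy spectra.

Real training data for core-fucose identification are intact-glycopeptide
MS/MS runs of FUT8-knockout (case, all nCF) and wild-type (control, CF + nCF
mixture) tissue. This module emulates their *statistical* structure so every
stage of the package is exercisable without any download:

* per-ion log10 relative intensities drawn from the published case/control
  Gaussian parameters (the defaults below), with per-ion dropout for missing
  peaks;
* the control cohort as a two-component mixture. Only the mixture's marginals
  are published, never a pure-CF component, so the CF component here is an
  explicit synthetic choice (see ``cf_component``): fucose-retaining ions
  nearly as intense as their unfucosylated parents, the spectral signature
  of a genuine core fucose, and rarely missing;
* toy spectra that place peaks at the theoretical characteristic-ion m/z so
  the matching/extraction path can be driven end to end.

All sampling is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import CIFeatureVector, normalize, theoretical_ci_mz
from .glyco_core import CI_LABELS, MONOSACCHARIDE_MASSES, ci_mz as ci_mz_of
from .labeling import CF, NCF
from .spectra_io import GlycoPSM, Spectrum

# Published per-ion Gaussian parameters of log10 relative intensity,
# ordered CI1..CI10 = Y1..Y5, Y1F..Y5F.
CASE_MU = np.array([-0.78, -1.05, -1.17, -1.04, -1.06, -1.72, -1.86, -1.69, -1.43, -1.35])
CASE_SIGMA = np.array([0.25, 0.25, 0.23, 0.20, 0.30, 0.16, 0.24, 0.24, 0.19, 0.22])
CONTROL_MU = np.array([-1.04, -1.25, -1.37, -1.37, -1.53, -1.19, -1.51, -1.74, -1.52, -1.53])
CONTROL_SIGMA = np.array([0.30, 0.24, 0.23, 0.24, 0.30, 0.16, 0.18, 0.14, 0.17, 0.23])

#: Default missing-peak probabilities for an nCF component: the unfucosylated
#: core ions are nearly always present, while a migrated-fucose (YiF) peak
#: exists only when fucose migration happened during fragmentation.
NCF_DROPOUT = np.array([0.05] * 5 + [0.5] * 5)
#: In a genuine CF spectrum the fucose-retaining series is as reliable as the
#: bare series.
CF_DROPOUT = np.array([0.05] * 10)

#: Log-decade deficit of the synthetic CF component's YiF means relative to
#: the matching Yi means (YiF ≈ 10^-0.2 ≈ 63% of Yi intensity).
CF_YF_OFFSET = 0.2
CF_YF_SIGMA = 0.25


@dataclass(frozen=True)
class CohortSpec:
    """One Gaussian component: per-ion (μ, σ) of log10 intensity plus dropout."""

    mu: np.ndarray
    sigma: np.ndarray
    dropout: np.ndarray
    name: str = "component"

    def __post_init__(self):
        for attr in ("mu", "sigma", "dropout"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=np.float64))
        if not (self.mu.shape == self.sigma.shape == self.dropout.shape == (10,)):
            raise ValueError("mu, sigma, dropout must each have 10 entries")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if np.any((self.dropout < 0) | (self.dropout > 1)):
            raise ValueError("dropout must lie in [0, 1]")


@dataclass(frozen=True)
class MixtureSpec:
    """Weighted mixture of components with per-vector ground-truth labels."""

    components: tuple[tuple[float, CohortSpec, str], ...]  # (weight, spec, truth label)

    def __post_init__(self):
        w = np.array([c[0] for c in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")


def case_spec(dropout: np.ndarray | None = None) -> CohortSpec:
    """The case (FUT8-knockout, all-nCF) cohort at the published parameters."""
    return CohortSpec(CASE_MU, CASE_SIGMA,
                      NCF_DROPOUT if dropout is None else dropout, name="case")


def cf_component(yf_offset: float = CF_YF_OFFSET) -> CohortSpec:
    """The synthetic pure-CF component (no published counterpart).

    Yi rows follow the case parameters; each YiF mean sits ``yf_offset``
    decades below its Yi parent with σ ``CF_YF_SIGMA``, and the F-series is
    rarely missing.
    """
    mu = CASE_MU.copy()
    mu[5:] = CASE_MU[:5] - yf_offset
    sigma = CASE_SIGMA.copy()
    sigma[5:] = CF_YF_SIGMA
    return CohortSpec(mu, sigma, CF_DROPOUT, name="cf")


def control_mixture(cf_weight: float = 0.3, yf_offset: float = CF_YF_OFFSET) -> MixtureSpec:
    """Control cohort: (1−w) nCF (case-parameter) + w synthetic CF component."""
    return MixtureSpec((
        (1.0 - cf_weight, replace(case_spec(), name="ncf"), NCF),
        (cf_weight, cf_component(yf_offset), CF),
    ))


def control_marginal_spec() -> CohortSpec:
    """The published control *marginals* as a single Gaussian component.

    Useful for the distribution-level statistics (KL analysis), where only
    the mixture's per-ion marginals matter.
    """
    return CohortSpec(CONTROL_MU, CONTROL_SIGMA, NCF_DROPOUT, name="control")


def sample_feature_cohort(
    spec: CohortSpec | MixtureSpec,
    n: int,
    seed: int,
    norm: str = "sum",
    scan_prefix: str = "synth",
) -> list[CIFeatureVector]:
    """Draw ``n`` labeled feature vectors from a component or mixture.

    Per vector: pick the mixture component by weight, draw each ion intensity
    as 10^N(μ_i, σ_i), apply dropout (intensity 0, mask false), clip to
    (0, 1], and normalize the surviving vector. Ground truth goes into
    ``label`` (the component's label for mixtures, nCF for a bare component).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    if isinstance(spec, CohortSpec):
        mixture = MixtureSpec(((1.0, spec, NCF if spec.name != "cf" else CF),))
    else:
        mixture = spec
    weights = np.array([c[0] for c in mixture.components])
    choice = rng.choice(len(weights), size=n, p=weights)
    out: list[CIFeatureVector] = []
    for idx in range(n):
        _, comp, truth = mixture.components[choice[idx]]
        x = 10.0 ** rng.normal(comp.mu, comp.sigma)
        keep = rng.random(10) >= comp.dropout
        x = np.where(keep, np.clip(x, 0.0, 1.0), 0.0)
        vec = CIFeatureVector(scan_id=f"{scan_prefix}_{idx}", x=x,
                              matched_mask=keep & (x > 0), label=truth)
        if vec.x.sum() > 0:
            vec.X = normalize(vec.x, norm)
        out.append(vec)
    return out


# ---------------------------------------------------------------------------
# toy spectra

def synthesize_spectrum(
    psm: GlycoPSM,
    x: np.ndarray,
    charges=(1,),
    noise_peaks: int = 0,
    jitter_ppm: float = 0.0,
    seed: int = 0,
    guard_charges=(1, 2),
    guard_ppm: float = 50.0,
) -> Spectrum:
    """Build a spectrum whose extraction recovers the intended intensities x.

    The base peak (intensity 1.0) and any noise peaks are placed outside
    every characteristic-ion window (±``guard_ppm`` over ``guard_charges``);
    each ion with x[i] > 0 gets one peak at its theoretical m/z for the first
    charge in ``charges``, perturbed by at most ``jitter_ppm``.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    if psm.peptide_mass is None:
        raise ValueError("synthesize_spectrum needs an explicit peptide_mass")
    rng = np.random.default_rng(seed)
    theo_guard = theoretical_ci_mz(psm.peptide_mass, guard_charges).ravel()
    windows = np.sort(
        np.column_stack([theo_guard * (1 - guard_ppm * 1e-6),
                         theo_guard * (1 + guard_ppm * 1e-6)]), axis=0
    )

    def in_ci_window(mz: float) -> bool:
        return bool(np.any((mz >= windows[:, 0]) & (mz <= windows[:, 1])))

    lo, hi = 150.0, float(theo_guard.max() * 1.1)
    mzs, intens = [], []
    # base peak
    while True:
        m = rng.uniform(lo, hi)
        if not in_ci_window(m):
            mzs.append(m)
            intens.append(1.0)
            break
    # characteristic-ion peaks at the first requested charge
    theo = theoretical_ci_mz(psm.peptide_mass, charges)[:, 0]
    for i in range(10):
        if x[i] > 0:
            shift = rng.uniform(-jitter_ppm, jitter_ppm) * 1e-6 if jitter_ppm else 0.0
            mzs.append(theo[i] * (1 + shift))
            intens.append(float(x[i]))
    # noise, resampled out of every guard window
    placed = 0
    while placed < noise_peaks:
        m = rng.uniform(lo, hi)
        if in_ci_window(m):
            continue
        mzs.append(m)
        intens.append(float(rng.uniform(0.005, 0.5)))
        placed += 1
    # precursor: intact glycopeptide at 2+ (peptide + full composition)
    glycan_mass = sum(MONOSACCHARIDE_MASSES.get(name, 0.0) * cnt
                      for name, cnt in psm.glycan_composition.items())
    return Spectrum(scan_id=psm.scan_id, mz=np.array(mzs), intensity=np.array(intens),
                    precursor_mz=ci_mz_of(psm.peptide_mass + glycan_mass, 2),
                    precursor_charge=2)


# ---------------------------------------------------------------------------
# benchmark

@dataclass
class Benchmark:
    """Tagged/untagged split with hidden ground truth for the untagged set."""

    tagged: list[CIFeatureVector]  # case cohort, all truly nCF
    untagged: list[CIFeatureVector]  # control mixture, labels hidden
    truth: np.ndarray  # ground-truth CF/nCF per untagged vector
    cf_weight: float = 0.3
    seed: int = 0


def make_benchmark(
    n_case: int,
    n_control: int,
    cf_weight: float = 0.3,
    seed: int = 0,
    norm: str = "sum",
) -> Benchmark:
    """Sample a tagged case cohort and an untagged control mixture.

    The untagged vectors' ``label`` fields are blanked; the returned ``truth``
    array holds the generating component per vector.
    """
    tagged = sample_feature_cohort(case_spec(), n_case, seed=seed, norm=norm,
                                   scan_prefix="case")
    untagged = sample_feature_cohort(control_mixture(cf_weight), n_control,
                                     seed=seed + 1, norm=norm, scan_prefix="ctrl")
    truth = np.array([v.label for v in untagged])
    for v in tagged:
        v.label = NCF
    for v in untagged:
        v.label = None
    return Benchmark(tagged=tagged, untagged=untagged, truth=truth,
                     cf_weight=cf_weight, seed=seed)
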