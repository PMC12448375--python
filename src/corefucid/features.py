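"""Characteristic-ion feature extraction.

For each PSM the ten core Y-ions (Y1..Y5, Y1F..Y5F) are matched against the
spectrum at a ppm tolerance over one or more charge states; their intensities
relative to the base peak form the 10-dimensional feature vector x. Spectra
with fewer than a minimum number of matched ions are discarded, and x is
normalized (Max or Sum) into the model-facing vector X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .glyco_core import CHARACTERISTIC_IONS, ci_mz, ci_neutral_mass, peptide_monoisotopic_mass
from .spectra_io import GlycoPSM, Spectrum

DEFAULT_TOL_PPM = 20.0
DEFAULT_CHARGES = (1, 2)
DEFAULT_MIN_CI = 3

NORMALIZATIONS = ("max", "sum")


@dataclass
class CIFeatureVector:
    """Relative intensities of the ten characteristic ions for one scan.

    ``x`` holds base-peak-relative intensities in [0, 1] ordered CI1..CI10;
    unmatched ions are zero-filled and flagged false in ``matched_mask``.
    ``X`` is the normalized vector actually fed to the classifiers.
    """

    scan_id: str
    x: np.ndarray
    X: np.ndarray = field(default=None)  # type: ignore[assignment]
    matched_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (10,):
            raise ValueError("x must have exactly 10 components")
        if self.matched_mask is None:
            self.matched_mask = self.x > 0
        self.matched_mask = np.asarray(self.matched_mask, dtype=bool)
        if np.any((self.x > 0) & ~self.matched_mask):
            raise ValueError("nonzero intensity at an unmatched ion")
        if np.any(self.x < 0) or np.any(self.x > 1):
            raise ValueError("relative intensities must lie in [0, 1]")
        if self.X is None:
            self.X = np.zeros(10)
        self.X = np.asarray(self.X, dtype=np.float64)

    @property
    def n_matched(self) -> int:
        return int(self.matched_mask.sum())


def theoretical_ci_mz(peptide_mass: float, charges: Sequence[int]) -> np.ndarray:
    """(10, n_charges) array of theoretical m/z for the characteristic ions."""
    return np.array(
        [
            [ci_mz(ci_neutral_mass(peptide_mass, ci), z) for z in charges]
            for ci in CHARACTERISTIC_IONS
        ]
    )


def match_ci_peaks(
    spectrum: Spectrum,
    peptide_mass: float,
    tol_ppm: float = DEFAULT_TOL_PPM,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> tuple[np.ndarray, np.ndarray]:
    """Match the ten characteristic ions in a spectrum.

    A peak matches ion i at charge z if |obs − theo| / theo · 1e6 ≤ tol_ppm.
    Within one (ion, charge) window the highest-intensity peak wins; the raw
    intensity of an ion is the sum over charge states, and its mask entry is
    true if any charge state matched.

    Returns
    -------
    raw : ndarray, shape (10,)
        Summed matched peak intensities (spectrum units).
    matched_mask : ndarray of bool, shape (10,)
    """
    if peptide_mass <= 0:
        raise ValueError("peptide_mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    raw = np.zeros(10)
    mask = np.zeros(10, dtype=bool)
    if spectrum.n_peaks == 0:
        return raw, mask
    mz, inten = spectrum.mz, spectrum.intensity
    theo = theoretical_ci_mz(peptide_mass, charges)
    for i in range(10):
        for j in range(len(charges)):
            t = theo[i, j]
            half = t * tol_ppm * 1e-6
            lo = np.searchsorted(mz, t - half, side="left")
            hi = np.searchsorted(mz, t + half, side="right")
            if hi > lo:
                raw[i] += float(inten[lo:hi].max())
                mask[i] = True
    return raw, mask


def relative_intensities(
    raw: np.ndarray, spectrum: Spectrum, denominator: str = "base_peak"
) -> np.ndarray:
    """Convert raw matched intensities to relative intensities in [0, 1].

    The default denominator is the base peak (most intense peak); ``"tic"``
    divides by the total ion current instead.
    """
    if denominator == "base_peak":
        denom = spectrum.base_peak_intensity
    elif denominator == "tic":
        denom = float(spectrum.intensity.sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError(f"spectrum {spectrum.scan_id!r} has no positive intensity")
    return np.clip(np.asarray(raw, dtype=np.float64) / denom, 0.0, 1.0)


def min_ci_filter(vec: CIFeatureVector, min_matched: int = DEFAULT_MIN_CI) -> bool:
    """Keep a spectrum only if at least ``min_matched`` characteristic ions matched."""
    return vec.n_matched >= min_matched


def max_normalize(x: np.ndarray) -> np.ndarray:
    """X_i = x_i / max_j x_j (Max Normalization)."""
    x = np.asarray(x, dtype=np.float64)
    m = x.max()
    if m <= 0:
        raise ValueError("max_normalize needs at least one positive component")
    return x / m


def sum_normalize(x: np.ndarray) -> np.ndarray:
    """X_i = x_i / Σ_j x_j (Sum Normalization)."""
    x = np.asarray(x, dtype=np.float64)
    s = x.sum()
    if s <= 0:
        raise ValueError("sum_normalize needs a positive sum")
    return x / s


def normalize(x: np.ndarray, method: str) -> np.ndarray:
    if method == "max":
        return max_normalize(x)
    if method == "sum":
        return sum_normalize(x)
    raise ValueError(f"unknown normalization {method!r} (use 'max' or 'sum')")


def extract_features(
    spectra: Iterable[Spectrum],
    psms: Sequence[GlycoPSM],
    tol_ppm: float = DEFAULT_TOL_PPM,
    charges: Sequence[int] = DEFAULT_CHARGES,
    norm: str = "sum",
    min_ci: int = DEFAULT_MIN_CI,
    denominator: str = "base_peak",
) -> list[CIFeatureVector]:
    """Join spectra with PSMs on scan_id and build filtered feature vectors.

    An explicit ``peptide_mass`` on the PSM takes precedence over the mass
    derived from the peptide sequence.
    """
    by_scan: dict[str, list[GlycoPSM]] = {}
    for p in psms:
        by_scan.setdefault(p.scan_id, []).append(p)
    out: list[CIFeatureVector] = []
    for spec in spectra:
        for psm in by_scan.get(spec.scan_id, ()):
            if psm.peptide_mass is not None:
                pep_mass = psm.peptide_mass
            else:
                pep_mass = peptide_monoisotopic_mass(psm.peptide)
            raw, mask = match_ci_peaks(spec, pep_mass, tol_ppm, charges)
            if spec.base_peak_intensity <= 0:
                continue
            x = relative_intensities(raw, spec, denominator)
            vec = CIFeatureVector(scan_id=spec.scan_id, x=x, matched_mask=mask)
            if not min_ci_filter(vec, min_ci):
                continue
            vec.X = normalize(vec.x, norm)
            out.append(vec)
    return out


def feature_matrix(vectors: Sequence[CIFeatureVector], normalized: bool = True) -> np.ndarray:
    """Stack vectors into an (n, 10) array (normalized X by default)."""
    if not vectors:
        return np.empty((0, 10))
    return np.stack([v.X if normalized else v.x for v in vectors])
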