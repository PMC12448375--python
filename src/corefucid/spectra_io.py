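"""Spectrum and PSM-table I/O.

Spectra come in as MGF or mzML (parsed with pyteomics); glycopeptide-spectrum
matches (PSMs) come in as a TSV with columns

    scan_id, peptide, peptide_mass, glycan_composition,
    structure_annotation, source_tag  [, id_fdr, collision_energy, ...]

Feature tables and predictions go out as TSV. All readers/writers round-trip
losslessly on the in-memory data model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml

logger = logging.getLogger("corefucid")

#: Recognised cohort/source tags for a PSM.
SOURCE_TAGS = ("FUT8_KO", "WILD_TYPE", "OTHER")

_KNOWN_MONOSACCHARIDES = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc")
# longest names first so HexNAc is not read as Hex + "NAc"
_COMPOSITION_RE = re.compile(
    "(" + "|".join(sorted(_KNOWN_MONOSACCHARIDES, key=len, reverse=True)) + r")(\d*)"
)


@dataclass
class Spectrum:
    """One MS/MS scan: sorted peak list plus precursor metadata."""

    scan_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in scan {self.scan_id!r}")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass
class GlycoPSM:
    """A glycopeptide assignment for one scan, with cohort provenance."""

    scan_id: str
    peptide: str | None = None
    peptide_mass: float | None = None
    glycan_composition: Mapping[str, int] = field(default_factory=dict)
    structure_annotation: str | None = None
    source_tag: str = "OTHER"
    id_fdr: float | None = None

    def __post_init__(self) -> None:
        if self.peptide is None and self.peptide_mass is None:
            raise ValueError(f"PSM {self.scan_id!r}: need peptide or peptide_mass")
        if any(v < 0 for v in self.glycan_composition.values()):
            raise ValueError(f"PSM {self.scan_id!r}: negative composition count")

    def composition_count(self, name: str) -> int:
        return int(self.glycan_composition.get(name, 0))


def parse_composition(text: str) -> dict[str, int]:
    """Parse a glycan composition string like ``"HexNAc2Hex5Fuc1"``.

    Grammar is name-count pairs with the count optional (missing count = 1).
    Unknown monosaccharide names are rejected.
    """
    text = (text or "").strip()
    comp: dict[str, int] = {}
    if not text:
        return comp
    pos = 0
    while pos < len(text):
        m = _COMPOSITION_RE.match(text, pos)
        if m is None:
            raise ValueError(f"cannot parse composition {text!r} at offset {pos}")
        name, count = m.group(1), m.group(2)
        comp[name] = comp.get(name, 0) + (int(count) if count else 1)
        pos = m.end()
    return comp


def format_composition(comp: Mapping[str, int]) -> str:
    return "".join(
        f"{name}{comp[name]}" for name in _KNOWN_MONOSACCHARIDES if comp.get(name, 0)
    )


# ---------------------------------------------------------------------------
# spectra

def _spectrum_from_mgf(entry: dict) -> Spectrum:
    params = entry.get("params", {})
    title = str(params.get("title", "")).strip()
    pep = params.get("pepmass")
    precursor_mz = float(pep[0]) if pep else None
    charge = params.get("charge")
    precursor_charge = int(charge[0]) if charge else None
    if precursor_mz is None:
        logger.warning("MGF spectrum %r lacks PEPMASS; precursor unknown", title)
    return Spectrum(
        scan_id=title,
        mz=entry["m/z array"],
        intensity=entry["intensity array"],
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
    )


def _spectrum_from_mzml(entry: dict) -> Spectrum:
    scan_id = entry.get("id", "")
    precursor_mz = None
    precursor_charge = None
    try:
        ion = entry["precursorList"]["precursor"][0]["selectedIonList"]["selectedIon"][0]
        precursor_mz = float(ion["selected ion m/z"])
        if "charge state" in ion:
            precursor_charge = int(ion["charge state"])
    except (KeyError, IndexError, TypeError):
        logger.warning("mzML spectrum %r lacks precursor info", scan_id)
    return Spectrum(
        scan_id=str(scan_id),
        mz=entry["m/z array"],
        intensity=entry["intensity array"],
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
    )


def read_spectra(path: str | Path, fmt: str | None = None) -> Iterator[Spectrum]:
    """Stream spectra from an MGF or mzML file.

    ``fmt`` is inferred from the suffix when omitted. Peak lists are sorted by
    m/z on load; scan ids are preserved verbatim (MGF TITLE / mzML id).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "mgf":
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                yield _spectrum_from_mgf(entry)
    elif fmt == "mzml":
        with _mzml.MzML(str(path)) as reader:
            for entry in reader:
                yield _spectrum_from_mzml(entry)
    else:
        raise ValueError(f"unsupported spectrum format {fmt!r} (use mzML or MGF)")


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (used by the simulator; round-trips read_spectra)."""
    entries = []
    for s in spectra:
        params: dict = {"title": s.scan_id}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# PSM tables

PSM_COLUMNS = (
    "scan_id",
    "peptide",
    "peptide_mass",
    "glycan_composition",
    "structure_annotation",
    "source_tag",
)


def read_psm_table(path: str | Path) -> list[GlycoPSM]:
    """Read a PSM TSV; rows lacking both peptide and mass are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("scan_id", "glycan_composition") if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks required columns {missing}")
    psms: list[GlycoPSM] = []
    n_skipped = 0
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        peptide = d.get("peptide", "").strip() or None
        mass_txt = d.get("peptide_mass", "").strip()
        peptide_mass = float(mass_txt) if mass_txt else None
        if peptide is None and peptide_mass is None:
            n_skipped += 1
            continue
        scan_id = d["scan_id"]
        if scan_id in seen:
            logger.warning("duplicate scan_id %r in PSM table; both rows kept", scan_id)
        seen.add(scan_id)
        fdr_txt = d.get("id_fdr", "").strip()
        psms.append(
            GlycoPSM(
                scan_id=scan_id,
                peptide=peptide,
                peptide_mass=peptide_mass,
                glycan_composition=parse_composition(d["glycan_composition"]),
                structure_annotation=d.get("structure_annotation", "").strip() or None,
                source_tag=d.get("source_tag", "").strip() or "OTHER",
                id_fdr=float(fdr_txt) if fdr_txt else None,
            )
        )
    if n_skipped:
        logger.warning("skipped %d PSM rows lacking both peptide and mass", n_skipped)
    return psms


def write_psm_table(psms: Sequence[GlycoPSM], path: str | Path) -> None:
    rows = [
        {
            "scan_id": p.scan_id,
            "peptide": p.peptide or "",
            "peptide_mass": "" if p.peptide_mass is None else repr(p.peptide_mass),
            "glycan_composition": format_composition(p.glycan_composition),
            "structure_annotation": p.structure_annotation or "",
            "source_tag": p.source_tag,
            "id_fdr": "" if p.id_fdr is None else repr(p.id_fdr),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS) + ["id_fdr"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(vectors: Sequence["CIFeatureVector"], path: str | Path) -> None:
    """Write feature vectors to TSV (scan_id, x1..x10, X1..X10, mask, label).

    Zeros are written as ``0``; NaN is forbidden by the data model.
    """
    from .features import CIFeatureVector  # local import to avoid a cycle

    rows = []
    for v in vectors:
        if np.any(~np.isfinite(v.x)) or np.any(~np.isfinite(v.X)):
            raise ValueError(f"non-finite feature value in scan {v.scan_id!r}")
        row: dict = {"scan_id": v.scan_id}
        # shortest-repr strings: exact binary round-trip, zeros written as "0"
        fmt = lambda val: "0" if val == 0 else repr(float(val))  # noqa: E731
        row.update({f"x{i + 1}": fmt(v.x[i]) for i in range(10)})
        row.update({f"X{i + 1}": fmt(v.X[i]) for i in range(10)})
        row["matched_mask"] = "".join("1" if m else "0" for m in v.matched_mask)
        row["label"] = v.label or ""
        rows.append(row)
    cols = (
        ["scan_id"]
        + [f"x{i + 1}" for i in range(10)]
        + [f"X{i + 1}" for i in range(10)]
        + ["matched_mask", "label"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> list["CIFeatureVector"]:
    from .features import CIFeatureVector

    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"scan_id": str, "matched_mask": str, "label": str})
    out: list[CIFeatureVector] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        mask = np.array([c == "1" for c in d["matched_mask"]], dtype=bool)
        label = d.get("label")
        if label is None or (isinstance(label, float) and np.isnan(label)):
            label = None
        out.append(
            CIFeatureVector(
                scan_id=d["scan_id"],
                x=np.array([d[f"x{i + 1}"] for i in range(10)], dtype=np.float64),
                X=np.array([d[f"X{i + 1}"] for i in range(10)], dtype=np.float64),
                matched_mask=mask,
                label=label or None,
            )
        )
    return out
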