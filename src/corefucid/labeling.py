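"""Trustworthy labels and the Y1F/Y1 ratio baseline.

Fucose migration (FM) and fucose release (FR) during fragmentation make most
core-fucosylation labels untrustworthy: FM fakes a core fucose on an nCF
glycan, FR strips a real one. Two label sources escape this confound:

* spectra from FUT8-knockout tissue — the α1,6-fucosyltransferase is gone, so
  every glycan is genuinely non-core-fucosylated (nCF);
* core-fucosylated high-mannose glycans called by an upstream structure tool —
  a pure-mannose glycan carries no antennary fucose that could migrate, so an
  observed core fucose must be real (CF).

Everything else stays UNLABELED. The baseline classifier thresholds the
Y1F/Y1 relative-intensity ratio at 0.1, the literature rule this package's
models are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import CIFeatureVector
from .spectra_io import GlycoPSM

CF = "CF"
NCF = "nCF"
UNLABELED = "UNLABELED"
UNDETERMINED = "UNDETERMINED"

#: structure_annotation values accepted as an explicit upstream core-fucose call
CORE_FUCOSE_FLAGS = frozenset({"core_fucose", "core-fucose", "corefuc", "cf", "1", "true", "yes"})


@dataclass(frozen=True)
class Label:
    """A trustworthy label with its provenance rule."""

    value: str  # CF | nCF | UNLABELED
    provenance: str  # FUT8_KO_rule | core_fuc_mannose_rule | none


def has_core_fucose_annotation(psm: GlycoPSM) -> bool:
    ann = (psm.structure_annotation or "").strip().lower()
    return ann in CORE_FUCOSE_FLAGS


def is_core_fucosylated_mannose(psm: GlycoPSM) -> bool:
    """Composition test for a core-fucosylated high-mannose glycan.

    HexNAc2 Fuc1, three or more Hex, no sialic acids — the pentasaccharide
    core plus mannoses plus exactly the core fucose — together with an
    explicit upstream structure call placing the fucose on the core.
    """
    c = psm.composition_count
    return (
        c("HexNAc") == 2
        and c("Fuc") == 1
        and c("NeuAc") == 0
        and c("NeuGc") == 0
        and c("Hex") >= 3
        and has_core_fucose_annotation(psm)
    )


def trustworthy_label(psm: GlycoPSM, max_fdr: float | None = None) -> Label:
    """Assign nCF (FUT8-KO rule), CF (core-fucosylated mannose rule) or UNLABELED.

    ``max_fdr``, when given, refuses the CF rule for PSMs whose upstream
    identification FDR exceeds it (the producer normally pre-filters).
    """
    if psm.source_tag == "FUT8_KO":
        return Label(NCF, "FUT8_KO_rule")
    if is_core_fucosylated_mannose(psm):
        if max_fdr is not None and psm.id_fdr is not None and psm.id_fdr > max_fdr:
            return Label(UNLABELED, "none")
        return Label(CF, "core_fuc_mannose_rule")
    return Label(UNLABELED, "none")


def y1f_y1_baseline(vec: CIFeatureVector, threshold: float = 0.1) -> str:
    """Threshold baseline: CF iff Y1F/Y1 relative intensity ratio exceeds ``threshold``.

    Returns UNDETERMINED when Y1 is unmatched (ratio undefined). The decision
    uses raw relative intensities, so it is invariant to Max/Sum normalization.
    """
    y1 = vec.x[0]
    y1f = vec.x[5]
    if y1 <= 0:
        return UNDETERMINED
    return CF if y1f / y1 > threshold else NCF
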