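"""Mass bookkeeping for the ten core-related characteristic ions.

Core-fucose identification works on the Y-type fragment ions that retain the
peptide plus a growing prefix of the N-glycan pentasaccharide core (two GlcNAc
and three mannose residues), with and without one fucose:

    Y1  = peptide + HexNAc            Y1F = Y1 + Fuc
    Y2  = peptide + 2 HexNAc          Y2F = Y2 + Fuc
    Y3  = peptide + 2 HexNAc + Hex    Y3F = Y3 + Fuc
    Y4  = peptide + 2 HexNAc + 2 Hex  Y4F = Y4 + Fuc
    Y5  = peptide + 2 HexNAc + 3 Hex  Y5F = Y5 + Fuc

These ten ions (CI1..CI10 = Y1..Y5, Y1F..Y5F) are the feature set; this module
computes their theoretical neutral masses and m/z from a peptide mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

# Standard monoisotopic glycan residue masses (Da). Injectable via the
# ``masses`` argument of the operations below for alternate conventions.
MONOSACCHARIDE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "HexNAc": 203.07937,
        "Hex": 162.05282,
        "Fuc": 146.05791,
    }
)

PROTON_MASS = 1.0072764665  # Da

WATER_MASS = 18.0105646863  # Da, monoisotopic

# Monoisotopic amino-acid residue masses (Da), standard 20 residues.
AA_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
        "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
        "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
        "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
        "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
    }
)

# Default fixed modifications: carbamidomethylation of cysteine, the
# near-universal alkylation in intact-glycopeptide workflows.
DEFAULT_FIXED_MODS: Mapping[str, float] = MappingProxyType({"C": 57.02146})


@dataclass(frozen=True)
class CharacteristicIon:
    """One of the ten core Y-ions, as glycan residue counts kept on the peptide.

    Attributes
    ----------
    index : int
        Position 1..10 in the feature vector (CI1..CI10).
    label : str
        Conventional name, ``Y1``..``Y5`` or ``Y1F``..``Y5F``.
    hexnac, hex, fuc : int
        Residue counts of HexNAc / Hex / Fuc retained with the peptide.
    """

    index: int
    label: str
    hexnac: int
    hex: int
    fuc: int

    @property
    def glycan_part(self) -> tuple[int, int, int]:
        return (self.hexnac, self.hex, self.fuc)


def _build_ions() -> tuple[CharacteristicIon, ...]:
    core = [(1, 0), (2, 0), (2, 1), (2, 2), (2, 3)]  # (HexNAc, Hex) for Y1..Y5
    ions = [
        CharacteristicIon(i + 1, f"Y{i + 1}", n, h, 0)
        for i, (n, h) in enumerate(core)
    ]
    ions += [
        CharacteristicIon(i + 6, f"Y{i + 1}F", n, h, 1)
        for i, (n, h) in enumerate(core)
    ]
    return tuple(ions)


#: The ten characteristic ions in feature-vector order (Y1..Y5, Y1F..Y5F).
CHARACTERISTIC_IONS: tuple[CharacteristicIon, ...] = _build_ions()

#: label -> ion lookup
ION_BY_LABEL: Mapping[str, CharacteristicIon] = MappingProxyType(
    {ion.label: ion for ion in CHARACTERISTIC_IONS}
)

CI_LABELS: tuple[str, ...] = tuple(ion.label for ion in CHARACTERISTIC_IONS)


def peptide_monoisotopic_mass(
    sequence: str,
    fixed_mods: Mapping[str, float] | None = None,
) -> float:
    """Neutral monoisotopic peptide mass including water and fixed mods.

    Parameters
    ----------
    sequence : str
        Peptide in standard one-letter code.
    fixed_mods : mapping, optional
        Residue letter -> added mass (Da). Defaults to carbamidomethyl-Cys.

    Raises
    ------
    ValueError
        On an empty sequence or an unknown residue letter.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    mods = DEFAULT_FIXED_MODS if fixed_mods is None else fixed_mods
    mass = WATER_MASS
    for aa in sequence:
        try:
            mass += AA_RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {aa!r} in {sequence!r}") from None
        mass += mods.get(aa, 0.0)
    return mass


def ci_neutral_mass(
    peptide_mass: float,
    ci: CharacteristicIon,
    masses: Mapping[str, float] = MONOSACCHARIDE_MASSES,
) -> float:
    """Neutral mass of a characteristic ion: peptide plus retained glycan part."""
    if peptide_mass <= 0:
        raise ValueError(f"peptide_mass must be positive, got {peptide_mass}")
    return (
        peptide_mass
        + ci.hexnac * masses["HexNAc"]
        + ci.hex * masses["Hex"]
        + ci.fuc * masses["Fuc"]
    )


def ci_mz(neutral_mass: float, charge: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of a neutral mass at a positive integer charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * proton_mass) / charge
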