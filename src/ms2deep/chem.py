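"""Monoisotopic mass arithmetic and the built-in motif / neutral-loss tables.

Flavonoid aglycones fragment to a characteristic "featured ion" (the
protonated or deprotonated aglycone), while sugar and acyl decorations
depart as characteristic neutral losses. The tables here hold the featured
ions of common flavone/flavonol skeletons and the recurrent losses of
glycosyl, sulfate and acyl-glycosyl groups, with masses derived from
standard monoisotopic atomic masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError

#: Mass of a proton in Da, used to convert between neutral monoisotopic
#: mass and the m/z of [M+H]+ / [M-H]- ions.
PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic neutral mass (Da) of an elemental formula.

    Uses standard monoisotopic atomic masses (C = 12 exactly,
    H = 1.00782503, O = 15.9949146, ...).
    """
    try:
        return float(_pmass.calculate_mass(formula=formula))
    except PyteomicsError as exc:  # unknown element symbol, bad syntax
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from exc


def formula_ion_mass(formula: str, adduct: str = "M") -> float:
    """Mass of a formula as a neutral (``M``) or ionised species.

    Parameters
    ----------
    formula:
        Elemental formula, e.g. ``"C15H10O5"``.
    adduct:
        ``"[M+H]+"`` for the protonated ion, ``"[M-H]-"`` for the
        deprotonated ion, or ``"M"`` for the neutral monoisotopic mass.

    Returns
    -------
    float
        m/z (Th) for ionic adducts, Da for the neutral species.
    """
    m = monoisotopic_mass(formula)
    if adduct == "M":
        return m
    if adduct in ("[M+H]+", "M+H"):
        return m + PROTON_MASS
    if adduct in ("[M-H]-", "[M−H]-", "M-H"):
        return m - PROTON_MASS
    raise ValueError(f"unknown adduct {adduct!r}")


@dataclass(frozen=True)
class MotifEntry:
    """A structural motif: a fragment ion characteristic of a skeleton."""

    name: str
    ion_mz: float
    ion_mode: str = "positive"
    compound_class: str = ""

    def __post_init__(self):
        if self.ion_mz <= 0:
            raise ValueError("motif ion m/z must be positive")


@dataclass(frozen=True)
class NeutralLossEntry:
    """A characteristic neutral loss (departing group) with its mass in Da."""

    name: str
    mass: float
    max_multiplicity: int = 3

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("neutral-loss mass must be positive")


# Aglycone formulas of the flavone/flavonol skeletons used in the default
# motif table.  Featured ions are the protonated aglycones in positive mode.
_AGLYCONE_FORMULAS = {
    "apigenin": "C15H10O5",
    "kaempferol": "C15H10O6",
    "quercetin": "C15H10O7",
    "chrysoeriol": "C16H12O6",
    "luteolin": "C15H10O6",
    "tricin": "C17H14O7",
    "isoorientin": "C21H20O11",
}

# Neutral-loss group formulas (the departing residue, i.e. sugar minus H2O
# for glycosides).
_LOSS_FORMULAS = {
    "hexoside": "C6H10O5",
    "pentoside": "C5H8O4",
    "rhamnoside": "C6H10O4",
    "hexuronide": "C6H8O6",
    "sulfate": "SO3",
    "coumaroylhexoside": "C15H16O7",
}

# Masses as printed in the source motif/loss tables of the original survey
# of flavone/flavonol fragmentation; they deviate from formula-derived
# monoisotopic values by up to ~2e-4 Da, within matching tolerances.
_PRINTED_MOTIFS = {
    "apigenin": 271.0600999,
    "kaempferol": 287.0550145,
    "quercetin": 303.0499291,
    "chrysoeriol": 301.0706646,
}

_PRINTED_LOSSES = {
    "hexoside": 162.0530308,
    "pentoside": 132.0423309,
    "rhamnoside": 146.0576808,
    "hexuronide": 176.0322455,
    "sulfate": 79.9568149,
    "coumaroylhexoside": 308.0892455,
}


def motif_table(provenance: str = "formula") -> list[MotifEntry]:
    """Default flavonoid motif table (positive-mode protonated aglycones).

    ``provenance="formula"`` derives every ion mass from its elemental
    formula; ``provenance="printed"`` uses the published table values for
    the four skeletons that have them.
    """
    entries = []
    for name, formula in _AGLYCONE_FORMULAS.items():
        mz = formula_ion_mass(formula, "[M+H]+")
        if provenance == "printed" and name in _PRINTED_MOTIFS:
            mz = _PRINTED_MOTIFS[name]
        entries.append(
            MotifEntry(name=name, ion_mz=mz, ion_mode="positive",
                       compound_class="flavonoid")
        )
    return entries


def neutral_loss_table(provenance: str = "formula") -> list[NeutralLossEntry]:
    """Default neutral-loss table for flavonoid decorations."""
    entries = []
    for name, formula in _LOSS_FORMULAS.items():
        m = monoisotopic_mass(formula)
        if provenance == "printed":
            m = _PRINTED_LOSSES[name]
        entries.append(NeutralLossEntry(name=name, mass=m))
    return entries
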