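"""Monoisotopic peptide mass arithmetic.

Masses are needed to decide whether an apparent amino-acid substitution is
distinguishable from a modified form of the canonical peptide.  A
phenylalanine-to-methionine swap plus one methionine oxidation, for example,
shifts the peptide mass by only -0.033 Da and is indistinguishable from the
canonical peptidoform at typical instrument tolerances.

All masses are monoisotopic and expressed in daltons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASS",
    "WATER_MONOISOTOPIC",
    "MODIFICATION_DELTAS",
    "MassModel",
    "peptide_mass",
    "substitution_delta",
]

#: Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276384,
    "V": 99.06841390,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406396,
    "I": 113.08406396,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496301,
    "E": 129.04259308,
    "M": 131.04048508,
    "H": 137.05891185,
    "F": 147.06841390,
    "R": 156.10111102,
    "Y": 163.06332852,
    "W": 186.07931294,
}

#: Mass of one water molecule (H2O), added once per peptide.
WATER_MONOISOTOPIC: float = 18.01056468

#: Variable/fixed modification mass shifts, Da.
MODIFICATION_DELTAS: dict[str, float] = {
    "Oxidation": 15.9949146221,
    "Carbamidomethyl": 57.0214637236,
    "Acetyl": 42.0105646863,
}

#: Aliases accepted in report modification strings (case-insensitive keys).
_MOD_ALIASES = {
    "oxidation": "Oxidation",
    "ox": "Oxidation",
    "carbamidomethyl": "Carbamidomethyl",
    "cam": "Carbamidomethyl",
    "acetyl": "Acetyl",
    "ac": "Acetyl",
}


def resolve_modification(name: str) -> str:
    """Map a modification name or alias to its canonical name."""
    canonical = _MOD_ALIASES.get(name.strip().lower())
    if canonical is None:
        raise KeyError(f"unknown modification name: {name!r}")
    return canonical


@dataclass(frozen=True)
class MassModel:
    """Residue and modification masses plus the isobaric match tolerance.

    Parameters
    ----------
    residue_masses : mapping of one-letter residue to monoisotopic mass, Da.
    modification_deltas : mapping of modification name to mass shift, Da.
    water : monoisotopic mass of water, Da.
    isobaric_tolerance : absolute mass difference, Da, below which two
        peptidoforms are treated as indistinguishable.  The default of
        0.04 Da is the smallest round value covering both phenylalanine
        near-isobaric patterns (|Δ| 0.0153 and 0.0330 Da).
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASS)
    )
    modification_deltas: dict[str, float] = field(
        default_factory=lambda: dict(MODIFICATION_DELTAS)
    )
    water: float = WATER_MONOISOTOPIC
    isobaric_tolerance: float = 0.04

    def __post_init__(self) -> None:
        if self.isobaric_tolerance <= 0:
            raise ValueError("isobaric tolerance must be positive")

    def residue(self, aa: str) -> float:
        try:
            return self.residue_masses[aa]
        except KeyError:
            raise KeyError(f"unknown residue: {aa!r}") from None

    def modification(self, name: str) -> float:
        key = name if name in self.modification_deltas else resolve_modification(name)
        return self.modification_deltas[key]


DEFAULT_MASS_MODEL = MassModel()


def peptide_mass(
    sequence: str,
    modifications: list[tuple[str, int]] | None = None,
    mass_model: MassModel = DEFAULT_MASS_MODEL,
) -> float:
    """Monoisotopic mass of a (possibly modified) peptide, Da.

    ``modifications`` is a list of ``(name, position)`` with 1-based
    positions; position 0 is accepted for terminal modifications such as
    N-terminal acetylation.

    Raises
    ------
    KeyError
        On a residue or modification name the model does not know.
    ValueError
        On a modification position outside the peptide.
    """
    total = mass_model.water
    for aa in sequence:
        total += mass_model.residue(aa)
    for name, pos in modifications or []:
        if pos < 0 or pos > len(sequence):
            raise ValueError(
                f"modification position {pos} outside peptide of length {len(sequence)}"
            )
        total += mass_model.modification(name)
    return total


def substitution_delta(
    original: str, substituted: str, mass_model: MassModel = DEFAULT_MASS_MODEL
) -> float:
    """Mass shift, Da, of replacing one ``original`` residue by ``substituted``."""
    return mass_model.residue(substituted) - mass_model.residue(original)
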