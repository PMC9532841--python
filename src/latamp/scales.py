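"""Per-residue property scales and mass constants.

Two hydrophobicity scales are shipped: the Fauchère–Pliška octanol/water
partition scale (the HeliQuest default, and the default here because it is
the convention under which the study peptides' printed descriptors are
reproduced) and the Eisenberg consensus scale as an alternative.

Mass tables carry the standard IUPAC average and monoisotopic residue
masses for the 20 canonical amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Residues counted as hydrophobic for the percentage descriptor.
HYDROPHOBIC_RESIDUES = frozenset("ACFILMVW")


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric scale covering all 20 canonical residues."""

    scale_name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_RESIDUES) - set(self.values)
        extra = set(self.values) - set(CANONICAL_RESIDUES)
        if missing or extra:
            raise ValueError(
                f"scale {self.scale_name!r} must cover exactly the 20 canonical "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        # freeze the mapping so descriptor results can never mutate it
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} is not a canonical amino acid"
            ) from None


FAUCHERE_PLISKA = ResidueScale(
    "fauchere-pliska",
    {
        "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
        "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
        "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
        "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
    },
)

EISENBERG_CONSENSUS = ResidueScale(
    "eisenberg-consensus",
    {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
)

SCALES: Mapping[str, ResidueScale] = MappingProxyType(
    {s.scale_name: s for s in (FAUCHERE_PLISKA, EISENBERG_CONSENSUS)}
)

# Standard IUPAC residue masses (Da): the mass of the amino acid minus water,
# i.e. the in-chain residue contribution.
_AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

_MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


@dataclass(frozen=True)
class MassTable:
    """Residue masses plus the terminal-group and adduct constants.

    ``amide_delta_*`` is the mass removed when the C-terminal carboxylic
    acid is replaced by a carboxamide (-OH -> -NH2).
    """

    average_mass: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(_AVERAGE_RESIDUE_MASS)
    )
    monoisotopic_mass: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(_MONOISOTOPIC_RESIDUE_MASS)
    )
    water_avg: float = 18.0153
    water_mono: float = 18.01056
    proton: float = 1.00728
    amide_delta_mono: float = 0.98402
    amide_delta_avg: float = 0.98476

    def __post_init__(self) -> None:
        for res in CANONICAL_RESIDUES:
            avg, mono = self.average_mass[res], self.monoisotopic_mass[res]
            if mono <= 0 or avg <= 0 or mono > avg:
                raise ValueError(f"inconsistent masses for residue {res}")


DEFAULT_MASS_TABLE = MassTable()
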