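"""Physicochemical descriptors of amphipathic helical peptides.

Implements the classic descriptor set used to steer cationic
antimicrobial-peptide design: net charge at neutral pH, mean per-residue
hydrophobicity, hydrophobic-residue percentage, the Eisenberg hydrophobic
moment, and the helical-wheel projection with its hydrophobic face.

Conventions
-----------
* Charge: side chains only by default (K, R = +1; D, E = -1; H = 0).
  The ``include-termini`` model additionally counts the protonated
  N-terminal amine (+1); the C-terminal carboxylate (-1 when a free acid)
  is only counted when explicitly requested.
* Hydrophobic moment: mu_H = |sum_n h_n exp(i * delta * (n-1))| / N with
  delta = 100 degrees per residue for an ideal alpha-helix.
* Hydrophobic percentage truncates toward zero (7/13 -> 53), matching the
  convention of the reference descriptor tables this package reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .peptides import PeptideSequence, FREE_ACID
from .scales import FAUCHERE_PLISKA, HYDROPHOBIC_RESIDUES, ResidueScale

SIDE_CHAINS = "side-chains"
INCLUDE_TERMINI = "include-termini"

#: Ideal alpha-helix angular step, degrees per residue (3.6 residues/turn).
ALPHA_HELIX_DELTA = 100.0

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


@dataclass(frozen=True)
class DescriptorSet:
    """Bundle of descriptors for one peptide, with provenance fields."""

    name: str
    length: int
    Z: int
    H: float
    H_pct: int
    muH: float
    scale_name: str
    charge_model: str

    def __post_init__(self) -> None:
        assert 0 <= self.H_pct <= 100
        assert self.muH >= 0
        assert abs(self.Z) <= self.length + 1


@dataclass(frozen=True)
class WheelEntry:
    index: int          # 1-based sequence position
    residue: str
    angle: float        # degrees in [0, 360)
    hydrophobic: bool


@dataclass(frozen=True)
class WheelProjection:
    """Helical-wheel projection: per-residue angles plus the hydrophobic face.

    ``face_arc`` is the (start, end) of the half-plane centred on the
    hydrophobic-moment direction; traversing counterclockwise from start
    to end covers the face.
    """

    entries: tuple[WheelEntry, ...]
    delta: float
    moment_angle: float
    face_arc: tuple[float, float]

    def in_face(self, index: int) -> bool:
        """Whether the residue at 1-based ``index`` lies on the hydrophobic face."""
        entry = self.entries[index - 1]
        diff = (entry.angle - self.moment_angle + 180.0) % 360.0 - 180.0
        return abs(diff) <= 90.0


def net_charge(
    seq: PeptideSequence,
    model: str = SIDE_CHAINS,
    count_c_terminus: bool = False,
) -> int:
    """Net charge at neutral pH.

    ``side-chains`` counts (#K + #R) - (#D + #E); histidine contributes 0.
    ``include-termini`` adds +1 for the free N-terminal amine and, only when
    ``count_c_terminus`` is set, -1 for a free-acid C-terminus.
    """
    z = sum(1 for r in seq if r in _POSITIVE) - sum(1 for r in seq if r in _NEGATIVE)
    if model == INCLUDE_TERMINI:
        z += 1
        if count_c_terminus and seq.c_term == FREE_ACID:
            z -= 1
    elif model != SIDE_CHAINS:
        raise ValueError(f"unknown charge model {model!r}")
    return z


def mean_hydrophobicity(seq: PeptideSequence, scale: ResidueScale = FAUCHERE_PLISKA) -> float:
    """Arithmetic mean of per-residue hydrophobicity values (unrounded)."""
    return sum(scale[r] for r in seq) / len(seq)


def hydrophobic_fraction(seq: PeptideSequence) -> int:
    """Percentage of residues in the hydrophobic set, truncated to an integer."""
    n_hyd = sum(1 for r in seq if r in HYDROPHOBIC_RESIDUES)
    return int(100 * n_hyd / len(seq))


def _moment_vector(
    residues: Sequence[str], scale: ResidueScale, delta: float
) -> tuple[float, float]:
    x = y = 0.0
    for n, res in enumerate(residues):
        theta = math.radians(delta * n)
        h = scale[res]
        x += h * math.cos(theta)
        y += h * math.sin(theta)
    return x, y


def hydrophobic_moment(
    seq: PeptideSequence,
    scale: ResidueScale = FAUCHERE_PLISKA,
    delta: float = ALPHA_HELIX_DELTA,
) -> float:
    """Length-normalized Eisenberg hydrophobic moment (unrounded).

    mu_H = (1/N) * sqrt[(sum h_n cos(delta (n-1)))^2 + (sum h_n sin(delta (n-1)))^2]
    """
    x, y = _moment_vector(seq.residues, scale, delta)
    return math.hypot(x, y) / len(seq)


def wheel_projection(
    seq: PeptideSequence,
    delta: float = ALPHA_HELIX_DELTA,
    scale: ResidueScale = FAUCHERE_PLISKA,
) -> WheelProjection:
    """Project the sequence onto a helical wheel.

    Residue n sits at angle ((n-1) * delta) mod 360. The hydrophobic face is
    the half-plane centred on the direction of the hydrophobic-moment vector.
    """
    entries = tuple(
        WheelEntry(
            index=n,
            residue=res,
            angle=(delta * (n - 1)) % 360.0,
            hydrophobic=res in HYDROPHOBIC_RESIDUES,
        )
        for n, res in enumerate(seq.residues, start=1)
    )
    x, y = _moment_vector(seq.residues, scale, delta)
    moment_angle = math.degrees(math.atan2(y, x)) % 360.0
    face_arc = ((moment_angle - 90.0) % 360.0, (moment_angle + 90.0) % 360.0)
    return WheelProjection(entries=entries, delta=delta,
                           moment_angle=moment_angle, face_arc=face_arc)


def describe(
    seq: PeptideSequence,
    scale: ResidueScale = FAUCHERE_PLISKA,
    charge_model: str = SIDE_CHAINS,
    delta: float = ALPHA_HELIX_DELTA,
) -> DescriptorSet:
    """All descriptors for one peptide; H and muH reported to 3 decimals."""
    return DescriptorSet(
        name=seq.name,
        length=len(seq),
        Z=net_charge(seq, model=charge_model),
        H=round(mean_hydrophobicity(seq, scale), 3),
        H_pct=hydrophobic_fraction(seq),
        muH=round(hydrophobic_moment(seq, scale, delta), 3),
        scale_name=scale.scale_name,
        charge_model=charge_model,
    )
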