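"""Pairwise sequence identity and position-wise substitution listing.

Equal-length pairs are compared position-wise without gaps (the mode used
throughout the design workflow, where analogs match the parent region in
length). Unequal lengths fall back to a simple global alignment (match +1,
mismatch 0, linear gap -1) and identity is counted over alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align

from .peptides import PeptideSequence


@dataclass(frozen=True)
class IdentityResult:
    matches: int
    alignment_length: int
    identity_pct: float  # 100 * matches / alignment_length, 1 decimal, half-up

    def __post_init__(self) -> None:
        assert 0 <= self.matches <= self.alignment_length


def _round1(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_identity(a: PeptideSequence, b: PeptideSequence) -> IdentityResult:
    """Percent identity between two peptides.

    Equal lengths: ungapped position-wise comparison. Unequal lengths:
    global alignment (match +1, mismatch 0, gap -1) first, identities
    counted over all alignment columns.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequences must be non-empty")
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a.residues, b.residues))
        length = len(a)
    else:
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=0,
            open_gap_score=-1,
            extend_gap_score=-1,
        )
        aln = aligner.align(a.residues, b.residues)[0]
        col_a, col_b = str(aln[0]), str(aln[1])
        matches = sum(x == y and x != "-" for x, y in zip(col_a, col_b))
        length = len(col_a)
    return IdentityResult(
        matches=matches,
        alignment_length=length,
        identity_pct=_round1(100.0 * matches / length),
    )


def position_diffs(
    a: PeptideSequence, b: PeptideSequence, offset: int = 1
) -> list[tuple[int, str, str]]:
    """Positions where two equal-length sequences differ.

    Returns (position, residue_in_a, residue_in_b) tuples. ``offset`` is the
    1-based position of the first residue in the parent's full-sequence
    numbering, so a fragment starting at parent position 5 reports parent
    coordinates when ``offset=5``.
    """
    if len(a) != len(b):
        raise ValueError("position_diffs requires equal-length sequences")
    return [
        (i + offset, x, y)
        for i, (x, y) in enumerate(zip(a.residues, b.residues))
        if x != y
    ]
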