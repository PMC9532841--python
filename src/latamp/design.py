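"""Constrained analog design on the parent helix region.

The design procedure is an explicit search: take the alpha-helical region
of the parent peptide, apply class-based residue substitutions (e.g.
Met/Ala -> aliphatic Leu/Ile, Glu -> Lys) at any subset of positions,
discard candidates whose amino-acid *composition* diverges from the parent
by more than the allowed fraction or that introduce helix-breaking
residues, and rank the remainder by a charge-first amphipathicity score.

Composition divergence is a multiset distance — it compares residue
counts, not positions — because a designer who swaps two residues between
wheel faces has changed the arrangement, not the composition.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .descriptors import (
    ALPHA_HELIX_DELTA,
    DescriptorSet,
    SIDE_CHAINS,
    describe,
)
from .peptides import PeptideSequence
from .scales import FAUCHERE_PLISKA, ResidueScale

#: Substitution classes of the study design: aliphatic replacements that
#: preserve helicity plus acid-to-base swaps that raise the net charge.
DEFAULT_RULES: Mapping[str, frozenset[str]] = {
    "M": frozenset("L"),
    "A": frozenset("LI"),
    "E": frozenset("K"),
    "K": frozenset("AILV"),
    "L": frozenset("A"),
}

STRICT = "strict"
TOLERANT = "tolerant"

#: Search spaces up to this size are enumerated exhaustively.
EXHAUSTIVE_LIMIT = 1_000_000


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the design objective.

    score = z_weight * (Z - Z_parent) + muh_weight * (muH - muH_parent)
            - h_penalty * (distance of H outside [h_min, h_max])

    The default H band (0.0, 0.5) keeps candidates moderately hydrophobic:
    cationic helices below ~0 mean hydrophobicity lose membrane insertion,
    while above ~0.5 hemolytic liability rises.
    """

    z_weight: float = 1.0
    muh_weight: float = 1.0
    h_penalty: float = 1.0
    h_min: float = 0.0
    h_max: float = 0.5


@dataclass(frozen=True)
class DesignConstraints:
    region: tuple[int, int] | None = None
    max_divergence: float = 0.30
    substitution_rules: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_RULES)
    )
    divergence_mode: str = TOLERANT
    helix_guard: frozenset[str] = frozenset("PG")
    weights: ScoreWeights = ScoreWeights()

    def __post_init__(self) -> None:
        if not (0 < self.max_divergence <= 1):
            raise ValueError("max_divergence must be in (0, 1]")
        if self.divergence_mode not in (STRICT, TOLERANT):
            raise ValueError(f"unknown divergence mode {self.divergence_mode!r}")
        if self.region is not None:
            start, end = self.region
            if not (1 <= start <= end):
                raise ValueError("region must satisfy 1 <= start <= end")

    def max_units(self, length: int) -> int:
        """Allowed composition-divergence units for a region of ``length``.

        Strict mode enforces divergence <= max_divergence exactly; tolerant
        mode (the default) admits one extra composition unit, reflecting
        that the cap is approximate by design.
        """
        units = math.floor(self.max_divergence * length)
        return units + 1 if self.divergence_mode == TOLERANT else units


@dataclass(frozen=True)
class AnalogCandidate:
    sequence: PeptideSequence
    descriptors: DescriptorSet
    composition_divergence: float
    n_substitutions: int
    score: float


def extract_region(parent: PeptideSequence, start: int, end: int) -> PeptideSequence:
    """Contiguous subsequence by 1-based inclusive coordinates, with provenance."""
    if not (1 <= start <= end <= len(parent)):
        raise ValueError(
            f"region {start}..{end} out of range for length {len(parent)} "
            "(coordinates are 1-based inclusive)"
        )
    return PeptideSequence(
        name=f"{parent.name}[{start}-{end}]",
        residues=parent.residues[start - 1 : end],
        c_term=parent.c_term,
        parent_name=parent.name,
        parent_start=start,
    )


def composition_divergence(a: PeptideSequence, b: PeptideSequence) -> float:
    """Multiset distance between amino-acid compositions, as a fraction.

    1 - (sum over residue types of min(count_a, count_b)) / length;
    insensitive to residue order.
    """
    if len(a) != len(b):
        raise ValueError("composition_divergence requires equal lengths")
    ca, cb = Counter(a.residues), Counter(b.residues)
    shared = sum(min(ca[r], cb[r]) for r in ca)
    return 1.0 - shared / len(a)


def score_candidate(
    candidate: AnalogCandidate | DescriptorSet,
    parent: DescriptorSet,
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """Charge-first amphipathicity score relative to the parent region."""
    d = candidate.descriptors if isinstance(candidate, AnalogCandidate) else candidate
    penalty = 0.0
    if d.H < weights.h_min:
        penalty = weights.h_min - d.H
    elif d.H > weights.h_max:
        penalty = d.H - weights.h_max
    return (
        weights.z_weight * (d.Z - parent.Z)
        + weights.muh_weight * (d.muH - parent.muH)
        - weights.h_penalty * penalty
    )


def _position_options(
    parent: str, rules: Mapping[str, Iterable[str]], guard: frozenset[str]
) -> list[str]:
    opts = []
    for res in parent:
        allowed = {res} | (set(rules.get(res, ())) - guard)
        opts.append("".join(sorted(allowed)))
    return opts


def enumerate_analogs(
    parent_region: PeptideSequence,
    constraints: DesignConstraints = DesignConstraints(),
    limit: int | None = None,
    seed: int = 0,
    scale: ResidueScale = FAUCHERE_PLISKA,
) -> list[AnalogCandidate]:
    """Generate, filter, and rank analog candidates of the parent region.

    Candidates arise from applying the substitution rules at any subset of
    positions. Feasible candidates satisfy the composition-divergence cap
    (strict or tolerant mode) and never introduce helix-guard residues.
    Ranking is by score, ties broken by higher Z, higher muH, lower
    divergence, then sequence string order; deterministic for a given seed.
    Search spaces above ``EXHAUSTIVE_LIMIT`` are sampled with a seeded RNG.
    """
    parent = parent_region.residues
    n = len(parent)
    opts = _position_options(parent, constraints.substitution_rules,
                             constraints.helix_guard)
    space = math.prod(len(o) for o in opts)
    max_units = constraints.max_units(n)
    parent_counts = Counter(parent)

    if space <= EXHAUSTIVE_LIMIT:
        pool: Iterable[tuple[str, ...]] = itertools.product(*opts)
    else:
        rng = np.random.default_rng(seed)
        draws = {
            tuple(o[k] for o, k in zip(opts, idx))
            for idx in rng.integers(0, [len(o) for o in opts],
                                    size=(EXHAUSTIVE_LIMIT, n))
        }
        pool = sorted(draws)  # order independent of hash seed

    # Fast feasibility pass on raw strings before building typed objects.
    feasible: list[str] = []
    for tup in pool:
        cand = "".join(tup)
        counts = Counter(cand)
        units = n - sum(min(parent_counts[r], counts[r]) for r in parent_counts)
        if units <= max_units:
            feasible.append(cand)

    parent_desc = describe(parent_region, scale=scale, charge_model=SIDE_CHAINS)
    # Precomputed per-position helix unit vectors; descriptors are evaluated
    # on raw strings here and re-derived on typed objects only for the
    # returned candidates.
    cos_t = [math.cos(math.radians(ALPHA_HELIX_DELTA * k)) for k in range(n)]
    sin_t = [math.sin(math.radians(ALPHA_HELIX_DELTA * k)) for k in range(n)]
    sv = scale.values
    w = constraints.weights
    scored: list[tuple[float, int, float, float, str, int]] = []
    for cand in feasible:
        z = mx = my = hsum = 0.0
        for k, r in enumerate(cand):
            h = sv[r]
            hsum += h
            mx += h * cos_t[k]
            my += h * sin_t[k]
            if r in "KR":
                z += 1
            elif r in "DE":
                z -= 1
        z = int(z)
        muh = round(math.hypot(mx, my) / n, 3)
        hmean = round(hsum / n, 3)
        counts = Counter(cand)
        div = 1.0 - sum(min(parent_counts[r], counts[r]) for r in parent_counts) / n
        n_sub = sum(a != b for a, b in zip(cand, parent))
        penalty = max(0.0, w.h_min - hmean, hmean - w.h_max)
        s = (w.z_weight * (z - parent_desc.Z)
             + w.muh_weight * (muh - parent_desc.muH)
             - w.h_penalty * penalty)
        scored.append((s, z, muh, div, cand, n_sub))

    scored.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3], t[4]))
    if limit is not None:
        scored = scored[:limit]

    out = []
    for s, _, _, div, cand, n_sub in scored:
        seq = PeptideSequence(name=cand, residues=cand, c_term=parent_region.c_term)
        out.append(
            AnalogCandidate(
                sequence=seq,
                descriptors=describe(seq, scale=scale, charge_model=SIDE_CHAINS),
                composition_divergence=div,
                n_substitutions=n_sub,
                score=s,
            )
        )
    return out


def feasible_sequences(
    parent_region: PeptideSequence,
    constraints: DesignConstraints = DesignConstraints(),
) -> set[str]:
    """The raw feasible set (sequence strings only), for membership checks."""
    parent = parent_region.residues
    n = len(parent)
    opts = _position_options(parent, constraints.substitution_rules,
                             constraints.helix_guard)
    max_units = constraints.max_units(n)
    parent_counts = Counter(parent)
    out = set()
    for tup in itertools.product(*opts):
        counts = Counter(tup)
        units = n - sum(min(parent_counts[r], counts[r]) for r in parent_counts)
        if units <= max_units:
            out.add("".join(tup))
    return out
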