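"""Theoretical peptide masses, b/y fragment ladders, and peak matching.

Covers the mass-spectrometric verification step of the design pipeline:
average and monoisotopic masses, the singly protonated [M+H]+ ion, the
singly charged b/y ion series used to read a sequence off a MALDI LIFT
spectrum, and assignment of an observed peak list to the theoretical
ladder. Only unmodified, singly charged b and y ions are modelled; no
a-ions, neutral losses, or isotope envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .peptides import AMIDE, PeptideSequence
from .scales import DEFAULT_MASS_TABLE, MassTable


@dataclass(frozen=True)
class MassResult:
    M_avg: float
    M_mono: float
    MH_plus: float
    c_term: str

    def __post_init__(self) -> None:
        assert self.MH_plus > self.M_mono


@dataclass(frozen=True)
class FragmentSeries:
    """b/y ladders (index 1..N-1) and the parent [M+H]+, all singly charged."""

    b_ions: tuple[float, ...]
    y_ions: tuple[float, ...]
    parent_MH: float

    def __len__(self) -> int:
        return len(self.b_ions) + 1


@dataclass(frozen=True)
class PeakList:
    """Observed m/z values (ascending) with a matching tolerance in Da."""

    mz_values: tuple[float, ...]
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        object.__setattr__(self, "mz_values", tuple(sorted(self.mz_values)))


@dataclass(frozen=True)
class PeakAssignment:
    mz: float
    ion: str | None        # e.g. "b3", "y7", "parent"; None if unassigned
    theoretical: float | None
    error: float | None


@dataclass(frozen=True)
class MatchReport:
    assignments: tuple[PeakAssignment, ...]
    b_coverage: float      # fraction of b positions hit
    y_coverage: float
    parent_matched: bool

    @property
    def n_matched(self) -> int:
        return sum(1 for a in self.assignments if a.ion is not None)


def peptide_mass(
    seq: PeptideSequence, table: MassTable = DEFAULT_MASS_TABLE
) -> MassResult:
    """Average and monoisotopic mass plus the singly protonated ion.

    A C-terminal amide replaces the terminal -OH by -NH2, lowering both
    masses by the amide correction.
    """
    m_avg = sum(table.average_mass[r] for r in seq) + table.water_avg
    m_mono = sum(table.monoisotopic_mass[r] for r in seq) + table.water_mono
    if seq.c_term == AMIDE:
        m_avg -= table.amide_delta_avg
        m_mono -= table.amide_delta_mono
    return MassResult(
        M_avg=m_avg, M_mono=m_mono, MH_plus=m_mono + table.proton, c_term=seq.c_term
    )


def by_series(
    seq: PeptideSequence, table: MassTable = DEFAULT_MASS_TABLE
) -> FragmentSeries:
    """Singly charged b and y ion ladders.

    b_i = sum of the first i residue masses + proton;
    y_j = sum of the last j residue masses + water + proton (the C-terminal
    amide correction applies to every y ion and the parent, never to b ions).
    By construction b_i + y_(N-i) = parent_MH + proton for every i.
    """
    if len(seq) < 2:
        raise ValueError("fragment series requires length >= 2")
    mono = table.monoisotopic_mass
    n = len(seq)
    prefix = 0.0
    b = []
    for res in seq.residues[: n - 1]:
        prefix += mono[res]
        b.append(prefix + table.proton)
    c_term_mass = table.water_mono + table.proton
    if seq.c_term == AMIDE:
        c_term_mass -= table.amide_delta_mono
    suffix = 0.0
    y = []
    for res in reversed(seq.residues[1:]):
        suffix += mono[res]
        y.append(suffix + c_term_mass)
    parent = peptide_mass(seq, table)
    return FragmentSeries(b_ions=tuple(b), y_ions=tuple(y), parent_MH=parent.MH_plus)


def match_peaks(theory: FragmentSeries, observed: PeakList) -> MatchReport:
    """Assign each observed peak to the nearest theoretical ion within tolerance.

    Coverage is the fraction of b (resp. y) ladder positions hit by at least
    one observed peak. An empty peak list yields an empty report.
    """
    catalog: list[tuple[str, float]] = [("parent", theory.parent_MH)]
    catalog += [(f"b{i}", mz) for i, mz in enumerate(theory.b_ions, start=1)]
    catalog += [(f"y{j}", mz) for j, mz in enumerate(theory.y_ions, start=1)]

    assignments = []
    hit: set[str] = set()
    for mz in observed.mz_values:
        ion, theo, err = None, None, None
        best = observed.tolerance
        for name, t in catalog:
            d = abs(mz - t)
            if d <= best:
                best, ion, theo, err = d, name, t, mz - t
        if ion is not None:
            hit.add(ion)
        assignments.append(PeakAssignment(mz=mz, ion=ion, theoretical=theo, error=err))

    n = len(theory.b_ions)
    b_cov = sum(1 for i in range(1, n + 1) if f"b{i}" in hit) / n
    y_cov = sum(1 for j in range(1, n + 1) if f"y{j}" in hit) / n
    return MatchReport(
        assignments=tuple(assignments),
        b_coverage=b_cov,
        y_coverage=y_cov,
        parent_matched="parent" in hit,
    )


def read_peaklist(handle: IO[str], tolerance: float = 0.5) -> PeakList:
    """Read a peak list from one-column (m/z) or two-column (m/z, intensity)
    whitespace/tab-delimited text; intensity is ignored; '#' lines skipped."""
    values = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values.append(float(line.split()[0]))
    return PeakList(mz_values=tuple(values), tolerance=tolerance)


def write_fragment_table(series: FragmentSeries, handle: IO[str]) -> None:
    """TSV of the ladder: position, b_mz, y_mz (y indexed from the C-terminus)."""
    handle.write("position\tb_mz\ty_mz\n")
    for i, (b, y) in enumerate(zip(series.b_ions, series.y_ions), start=1):
        handle.write(f"{i}\t{b:.5f}\t{y:.5f}\n")
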