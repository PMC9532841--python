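"""Reduction of plate-format assay data to antimicrobial-peptide endpoints.

Implements the endpoint calls of a broth-microdilution workflow:

* MIC — lowest tested concentration with no significant growth (OD600),
  operationalized as blank-corrected growth <= 10% of the no-peptide
  control, required to hold at every higher tested concentration as well
  (a monotone-from-the-top rule that is robust to single noisy wells);
* MBC — lowest concentration with zero colonies after plating;
* MBIC — the MIC rule applied to crystal-violet biofilm signal (A595);
* hemolysis % — linear normalization between a PBS blank (0%) and a
  Triton X-100 lysis control (100%);
* viability % — resazurin signal normalized between medium blank and
  untreated control, with the >= 60% cell-death activity rule;
* EC50 — four-parameter logistic (4PL) dose-response fit, with optional
  fixed asymptotes for responses already expressed as percentages.

Endpoints are always members of the tested concentration series or
censored as ">max" — never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from scipy.optimize import curve_fit

MIC = "MIC"
MBC = "MBC"
MBIC = "MBIC"

#: Default growth fraction below which a well counts as inhibited.
DEFAULT_INHIBITION_THRESHOLD = 0.10

#: Cell-death percentage at and above which a compound is called active.
ACTIVITY_DEATH_THRESHOLD = 60.0


class PlateError(ValueError):
    """Raised for uninterpretable plates (e.g. degenerate controls)."""


class FitError(RuntimeError):
    """Raised when a dose-response fit cannot converge; carries diagnostics."""


@dataclass(frozen=True)
class PlateAssay:
    """A concentration-by-replicate absorbance matrix with control wells.

    ``concentrations`` must be strictly decreasing (the plate layout of a
    serial dilution, e.g. 128, 64, ..., 4 ug/ml); ``readings`` has one row
    per concentration. ``growth_control`` are no-peptide wells and
    ``sterile_blank`` medium-only wells.
    """

    concentrations: tuple[float, ...]
    readings: np.ndarray
    growth_control: np.ndarray
    sterile_blank: np.ndarray
    wavelength: float = 600.0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        readings = np.asarray(self.readings, dtype=float)
        if len(conc) < 2:
            raise PlateError("need at least 2 concentrations")
        if any(lower >= higher for lower, higher in zip(conc[1:], conc)):
            raise PlateError("concentrations must be strictly decreasing")
        if readings.shape[0] != len(conc):
            raise PlateError("one reading row per concentration required")
        if (readings < 0).any():
            raise PlateError("absorbance readings must be non-negative")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "readings", readings)
        object.__setattr__(self, "growth_control",
                           np.asarray(self.growth_control, dtype=float))
        object.__setattr__(self, "sterile_blank",
                           np.asarray(self.sterile_blank, dtype=float))

    def growth_fractions(self) -> np.ndarray:
        """Blank-corrected growth relative to control, clamped to [0, 1]."""
        blank = float(np.mean(self.sterile_blank))
        control = float(np.mean(self.growth_control))
        if control <= blank:
            raise PlateError(
                f"growth control ({control:.3f}) does not exceed blank "
                f"({blank:.3f}); plate is uninterpretable"
            )
        g = (self.readings.mean(axis=1) - blank) / (control - blank)
        return np.clip(g, 0.0, 1.0)


@dataclass(frozen=True)
class AssayEndpoint:
    """An endpoint concentration, or censored above the tested range."""

    kind: str
    value: float | None          # None when censored
    max_tested: float

    @property
    def censored(self) -> bool:
        return self.value is None

    def __str__(self) -> str:
        if self.censored:
            return f">{self.max_tested:g}"
        return f"{self.value:g}"


@dataclass(frozen=True)
class DoseResponseFit:
    EC50: float
    hill: float
    top: float
    bottom: float
    rss: float

    def __post_init__(self) -> None:
        assert self.EC50 > 0
        assert self.bottom <= self.top


def _lowest_monotone(concentrations: Sequence[float], inhibited: Sequence[bool],
                     kind: str) -> AssayEndpoint:
    """Lowest concentration inhibited with every higher one also inhibited.

    Concentrations are descending, so this is the longest all-True prefix.
    """
    value = None
    for conc, flag in zip(concentrations, inhibited):
        if not flag:
            break
        value = conc
    return AssayEndpoint(kind=kind, value=value, max_tested=concentrations[0])


def call_mic(
    plate: PlateAssay,
    inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD,
) -> AssayEndpoint:
    """MIC: lowest concentration whose normalized growth is at or below the
    threshold, with all higher concentrations also inhibited."""
    g = plate.growth_fractions()
    inhibited = g <= inhibition_threshold
    return _lowest_monotone(plate.concentrations, inhibited, MIC)


def call_mbc(
    concentrations: Sequence[float], colony_counts: Sequence[int]
) -> AssayEndpoint:
    """MBC: lowest concentration with zero colonies after plating,
    monotone from the top as for MIC; censored if all wells grew."""
    conc = tuple(float(c) for c in concentrations)
    counts = [int(c) for c in colony_counts]
    if len(conc) != len(counts):
        raise ValueError("one colony count per concentration required")
    if any(c < 0 for c in counts):
        raise ValueError("colony counts must be non-negative")
    return _lowest_monotone(conc, [c == 0 for c in counts], MBC)


def call_mbic(
    plate: PlateAssay,
    inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD,
) -> AssayEndpoint:
    """MBIC from a crystal-violet biofilm plate (A595), same rule as MIC."""
    g = plate.growth_fractions()
    inhibited = g <= inhibition_threshold
    return _lowest_monotone(plate.concentrations, inhibited, MBIC)


def hemolysis_percent(A, A_blank: float, A_triton: float):
    """Percent hemolysis: 100 * (A - blank) / (triton - blank), in [0, 100].

    The blank is intact erythrocytes in PBS (0% lysis); Triton X-100 is the
    100% lysis control. Accepts scalars or arrays.
    """
    if A_triton <= A_blank:
        raise PlateError("Triton control must exceed the blank")
    pct = 100.0 * (np.asarray(A, dtype=float) - A_blank) / (A_triton - A_blank)
    out = np.clip(pct, 0.0, 100.0)
    return float(out) if np.isscalar(A) else out


def viability_percent(treated, control: float, blank: float):
    """Percent viability: 100 * (treated - blank) / (control - blank), >= 0."""
    if control <= blank:
        raise PlateError("untreated control must exceed the blank")
    pct = 100.0 * (np.asarray(treated, dtype=float) - blank) / (control - blank)
    out = np.clip(pct, 0.0, None)
    return float(out) if np.isscalar(treated) else out


def activity_flag(death_pct: float) -> bool:
    """Active iff cell death reaches the 60% screening threshold."""
    if death_pct < 0:
        raise ValueError("death percentage must be non-negative")
    return death_pct >= ACTIVITY_DEATH_THRESHOLD


def four_pl(conc, bottom, top, ec50, hill):
    """Four-parameter logistic: response rises from bottom to top with dose."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)


def fit_dose_response(
    concs: Sequence[float],
    responses: Sequence[float],
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of response (%) against concentration.

    ``fix_bottom``/``fix_top`` pin the asymptotes, which is the
    recommended mode when responses are already normalized percentages
    (0 and 100): with few dose levels the free four-parameter problem is
    weakly identified. Raises :class:`FitError` with diagnostics on
    non-convergence or degenerate (constant) responses.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 4:
        raise FitError("need at least 4 distinct concentrations")
    if np.ptp(y) < 1e-9:
        raise FitError(
            f"responses are constant ({y[0]:.3g}); EC50 is unidentifiable"
        )

    ec50_0 = float(np.exp(np.mean(np.log(x))))
    names, p0, lo, hi = [], [], [], []
    if fix_bottom is None:
        names.append("bottom"); p0.append(float(y.min())); lo.append(-50.0); hi.append(200.0)
    if fix_top is None:
        names.append("top"); p0.append(float(y.max())); lo.append(-50.0); hi.append(200.0)
    names += ["ec50", "hill"]
    p0 += [ec50_0, 1.0]
    lo += [1e-6, 0.05]
    hi += [1e6, 20.0]

    def model(c, *params):
        it = iter(params)
        bottom = fix_bottom if fix_bottom is not None else next(it)
        top = fix_top if fix_top is not None else next(it)
        ec50, hill = it
        return four_pl(c, bottom, top, ec50, hill)

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lo, hi), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(
            f"4PL fit did not converge (n={len(x)}, response range "
            f"{y.min():.3g}..{y.max():.3g}): {exc}"
        ) from exc

    fitted = dict(zip(names, popt))
    bottom = fix_bottom if fix_bottom is not None else fitted["bottom"]
    top = fix_top if fix_top is not None else fitted["top"]
    if bottom > top:  # orient so bottom <= top; slope sign is in hill
        bottom, top = top, bottom
    resid = y - model(x, *popt)
    return DoseResponseFit(
        EC50=float(fitted["ec50"]),
        hill=float(fitted["hill"]),
        top=float(top),
        bottom=float(bottom),
        rss=float(np.sum(resid**2)),
    )


def read_plate_csv(handle: IO[str], wavelength: float = 600.0) -> PlateAssay:
    """Read a plate from CSV: one row per labelled concentration plus
    ``control`` and ``blank`` rows; columns after the label are replicates.

    Example::

        label,rep1,rep2,rep3
        128,0.05,0.06,0.05
        ...
        control,0.51,0.49,0.50
        blank,0.05,0.05,0.04
    """
    import csv

    concs, rows, control, blank = [], [], None, None
    reader = csv.reader(handle)
    header = next(reader)
    del header
    for row in reader:
        if not row or not row[0].strip():
            continue
        label, values = row[0].strip().lower(), [float(v) for v in row[1:] if v != ""]
        if label == "control":
            control = values
        elif label == "blank":
            blank = values
        else:
            concs.append(float(row[0]))
            rows.append(values)
    if control is None or blank is None:
        raise PlateError("plate CSV must include 'control' and 'blank' rows")
    return PlateAssay(
        concentrations=tuple(concs),
        readings=np.array(rows),
        growth_control=np.array(control),
        sterile_blank=np.array(blank),
        wavelength=wavelength,
    )


def write_plate_csv(plate: PlateAssay, handle: IO[str]) -> None:
    n_rep = plate.readings.shape[1]
    handle.write("label," + ",".join(f"rep{i+1}" for i in range(n_rep)) + "\n")
    for conc, row in zip(plate.concentrations, plate.readings):
        handle.write(f"{conc:g}," + ",".join(f"{v:.4f}" for v in row) + "\n")
    handle.write("control," + ",".join(f"{v:.4f}" for v in plate.growth_control) + "\n")
    handle.write("blank," + ",".join(f"{v:.4f}" for v in plate.sterile_blank) + "\n")
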