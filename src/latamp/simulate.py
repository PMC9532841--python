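"""Seeded generators emulating every plate and spectrum the pipeline reads.

The generators implement a deliberately simple measurement model — wells
are either "grown" or "inhibited" around a true endpoint, with additive
truncated Gaussian absorbance noise — which is sufficient to exercise and
validate the endpoint callers without modelling growth kinetics.

All generators are bit-reproducible for a given spec/seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import PlateAssay
from .fragments import PeakList, by_series
from .peptides import PeptideSequence

#: The study's serial two-fold dilution series, ug/ml, descending.
DEFAULT_SERIES: tuple[float, ...] = (128.0, 64.0, 32.0, 16.0, 8.0, 4.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic assay world.

    ``true_mic`` is the lowest concentration at which growth is fully
    suppressed (None = no inhibition anywhere in the tested range);
    ``true_ec50``/``hill`` parameterize the underlying 4PL response;
    ``noise_sd`` is additive Gaussian noise in absorbance units for plates
    and in percentage points for dose-response curves.
    """

    seed: int = 0
    true_mic: float | None = 32.0
    true_ec50: float = 127.0
    hill: float = 1.5
    noise_sd: float = 0.02
    n_replicates: int = 3
    concentration_series: tuple[float, ...] = DEFAULT_SERIES
    grown_od: float = 0.50
    blank_od: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_mic is not None and self.true_mic not in self.concentration_series:
            raise ValueError("true_mic must lie in the concentration series (or None)")
        if self.hill <= 0:
            raise ValueError("hill slope must be positive")


def _noisy(rng: np.random.Generator, level: float, shape, sd: float) -> np.ndarray:
    return np.clip(level + rng.normal(0.0, sd, size=shape), 0.0, None)


def gen_mic_plate(spec: GeneratorSpec, wavelength: float = 600.0) -> PlateAssay:
    """A microdilution plate with a known true MIC.

    Wells at concentrations >= true_mic read near the sterile blank,
    wells below read near the growth control; noise is truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    n_conc, n_rep = len(spec.concentration_series), spec.n_replicates
    readings = np.empty((n_conc, n_rep))
    for i, conc in enumerate(spec.concentration_series):
        inhibited = spec.true_mic is not None and conc >= spec.true_mic
        level = spec.blank_od if inhibited else spec.grown_od
        readings[i] = _noisy(rng, level, n_rep, spec.noise_sd)
    return PlateAssay(
        concentrations=spec.concentration_series,
        readings=readings,
        growth_control=_noisy(rng, spec.grown_od, n_rep, spec.noise_sd),
        sterile_blank=_noisy(rng, spec.blank_od, n_rep, spec.noise_sd),
        wavelength=wavelength,
    )


def gen_biofilm_plate(spec: GeneratorSpec) -> PlateAssay:
    """A crystal-violet biofilm plate (A595) with a known true MBIC."""
    return gen_mic_plate(spec, wavelength=595.0)


def gen_dose_response(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Concentrations and noisy 4PL responses (%, bottom 0, top 100).

    The response rises from 0 toward 100 with dose and is exactly 50 at
    the true EC50 when noise_sd is zero.
    """
    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.concentration_series, dtype=float)
    clean = 100.0 / (1.0 + (spec.true_ec50 / concs) ** spec.hill)
    return concs, clean + rng.normal(0.0, spec.noise_sd, size=concs.shape)


def gen_peaklist(
    seq: PeptideSequence,
    dropout: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    tolerance: float = 0.5,
) -> PeakList:
    """An observed-spectrum peak list from the theoretical b/y ladder.

    Each fragment peak survives with probability 1 - dropout and receives
    Gaussian m/z jitter; the parent ion is always retained.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    series = by_series(seq)
    mz = []
    for peak in (*series.b_ions, *series.y_ions):
        if rng.random() >= dropout:
            mz.append(peak + rng.normal(0.0, jitter_sd))
    mz.append(series.parent_MH + rng.normal(0.0, jitter_sd))
    return PeakList(mz_values=tuple(mz), tolerance=tolerance)
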