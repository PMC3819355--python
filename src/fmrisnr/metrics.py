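"""The six SNR/CNR definitions for fMRI time series and their conversions.

An fMRI series is modelled as activation signal S(t) plus noise N(t).
With baseline b, activation amplitude a (peak minus baseline),
activation fluctuation SD sigma_S and noise SD sigma_N, the six
definitions found in the literature are

    Definition 1 (SNR):  mean(S) / sigma_N        (temporal SNR)
    Definition 2 (CNR):  a / sigma_N
    Definition 3 (CNR):  20 log10(a / sigma_N)            [dB]
    Definition 4 (CNR):  sigma_S / sigma_N
    Definition 5 (CNR):  sigma_S^2 / sigma_N^2  (= Def4 squared)
    Definition 6 (CNR):  20 log10(sigma_S / sigma_N)      [dB]

All share the noise SD as denominator, so they differ only in how the
signal of interest is quantified.  The dB scale here is the
amplitude-ratio convention (20 log10); 0 dB means equal signal and
noise, negative values less signal than noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .designs import ActivationSignal

__all__ = [
    "NoiseModel",
    "MetricSet",
    "snr_mean",
    "cnr_amplitude",
    "cnr_sd",
    "cnr_var",
    "to_db",
    "from_db",
    "amplitude_from_psc",
    "metric_set",
]

#: Column order matching the printed reference tables.
METRIC_COLUMNS = ("def1", "def2", "def3", "def4", "def5", "def6")


@dataclass(frozen=True)
class NoiseModel:
    """Noise level, given directly as an SD or estimated from samples.

    If ``noise_samples`` is provided, sigma_N is the population SD of
    the samples after removing their mean; otherwise ``sd`` is used.
    """

    sd: float | None = None
    noise_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.noise_samples is None and self.sd is None:
            raise ValueError("either sd or noise_samples is required")

    @property
    def sigma(self) -> float:
        if self.noise_samples is not None:
            samples = np.asarray(self.noise_samples, dtype=float)
            s = float(np.std(samples - samples.mean()))
        else:
            s = float(self.sd)
        if s <= 0:
            raise ValueError("noise SD must be positive")
        return s


@dataclass(frozen=True)
class MetricSet:
    """The six SNR/CNR values for one (signal, noise) configuration.

    dB entries are NaN when the corresponding linear ratio is 0 (a
    zero-amplitude or constant signal), since the logarithm is
    undefined there.
    """

    snr_mean: float
    cnr_amp: float
    cnr_amp_db: float
    cnr_sd: float
    cnr_var: float
    cnr_sd_db: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.snr_mean,
            self.cnr_amp,
            self.cnr_amp_db,
            self.cnr_sd,
            self.cnr_var,
            self.cnr_sd_db,
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(METRIC_COLUMNS, self.as_tuple()))


def _sigma(noise) -> float:
    if isinstance(noise, NoiseModel):
        return noise.sigma
    s = float(noise)
    if s <= 0:
        raise ValueError("noise SD must be positive")
    return s


def snr_mean(signal: ActivationSignal, noise) -> float:
    """Definition 1: temporal mean of the series over the noise SD.

    The baseline is included in the mean, so this grows roughly
    linearly with the baseline and carries little information about the
    task-induced fluctuations.
    """
    return signal.mean / _sigma(noise)


def cnr_amplitude(signal: ActivationSignal, noise) -> float:
    """Definition 2: activation amplitude a over the noise SD."""
    return signal.amplitude / _sigma(noise)


def cnr_sd(signal: ActivationSignal, noise) -> float:
    """Definition 4: activation fluctuation SD sigma_S over sigma_N."""
    if signal.n_samples < 2:
        raise ValueError("need at least 2 samples for an SD-based CNR")
    return signal.fluctuation_sd / _sigma(noise)


def cnr_var(signal: ActivationSignal, noise) -> float:
    """Definition 5: variance ratio; exactly the square of Definition 4."""
    return cnr_sd(signal, noise) ** 2


def to_db(linear_ratio: float) -> float:
    """Convert an amplitude-type ratio to decibels (20 log10)."""
    if linear_ratio <= 0:
        raise ValueError("dB is undefined for a non-positive ratio")
    return 20.0 * math.log10(linear_ratio)


def from_db(db_value: float) -> float:
    """Invert :func:`to_db`: 10^(dB/20)."""
    return 10.0 ** (db_value / 20.0)


def amplitude_from_psc(psc: float, baseline: float) -> float:
    """Activation amplitude implied by a percent signal change: a = p b / 100."""
    return psc * baseline / 100.0


def metric_set(signal: ActivationSignal, noise) -> MetricSet:
    """All six definitions for one signal/noise configuration.

    Zero-amplitude (or constant) signals give 0 for the linear CNRs and
    NaN for the dB entries.
    """
    c2 = cnr_amplitude(signal, noise)
    c4 = cnr_sd(signal, noise)
    return MetricSet(
        snr_mean=snr_mean(signal, noise),
        cnr_amp=c2,
        cnr_amp_db=to_db(c2) if c2 > 0 else math.nan,
        cnr_sd=c4,
        cnr_var=c4 ** 2,
        cnr_sd_db=to_db(c4) if c4 > 0 else math.nan,
    )
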