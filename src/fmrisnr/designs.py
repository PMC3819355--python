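"""Experimental-design templates and noise-free BOLD activation signals.

Three canonical fMRI design templates are supported:

``block``
    Alternating task and rest epochs of equal length, task first.
``event_related``
    A fixed number of brief stimulus events placed uniformly at random
    (seeded) on the sampling grid, constrained not to overlap.
``contrast``
    Two task conditions presented in a repeating
    [condition 1, condition 2, rest] block sequence; the effect of
    condition 1 is twice that of condition 2.

A stimulus boxcar is convolved with the canonical double-gamma
haemodynamic response function (HRF) and the convolved response is
peak-anchored: its maximum is scaled to the amplitude

    a = p * b / 100

implied by the requested percent signal change ``p`` over baseline
intensity ``b``, after which the baseline is added.  The fluctuation
standard deviation of the resulting activation signal, ``sigma_S``,
depends on the design (epoch lengths, number of events) and is the
design-dependent ingredient of the SD-based contrast-to-noise ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "DesignSpec",
    "HRFParams",
    "ActivationSignal",
    "boxcar",
    "canonical_hrf",
    "activation_signal",
    "contrast_signal",
]

DESIGN_TYPES = ("block", "event_related", "contrast")


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of an experimental design.

    Parameters
    ----------
    design_type : {"block", "event_related", "contrast"}
    total_duration : float
        Run length in seconds.
    sampling_interval : float
        Time between samples (the repetition time, TR) in seconds.
        ``total_duration`` must be an integer multiple of it.
    block_length : float
        Epoch length in seconds for the block and contrast templates.
    n_events : int
        Number of events for the event-related template.
    event_duration : float, optional
        Event duration in seconds; ``None`` means a single-sample
        impulse.  Events never overlap.
    rng_seed : int, optional
        Seed for random event placement.  Identical seeds give
        bitwise-identical stimulus vectors.
    """

    design_type: str
    total_duration: float = 200.0
    sampling_interval: float = 2.0
    block_length: float = 20.0
    n_events: int = 25
    event_duration: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.design_type not in DESIGN_TYPES:
            raise ValueError(
                f"design_type must be one of {DESIGN_TYPES}, got {self.design_type!r}"
            )
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        ratio = self.total_duration / self.sampling_interval
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                "total_duration must be a positive integer multiple of sampling_interval"
            )
        if self.design_type in ("block", "contrast") and self.block_length <= 0:
            raise ValueError("block_length must be positive for block/contrast designs")
        if self.design_type == "event_related" and self.n_events < 1:
            raise ValueError("n_events must be >= 1 for event-related designs")
        if self.event_duration is not None and self.event_duration <= 0:
            raise ValueError("event_duration must be positive when given")

    @property
    def n_samples(self) -> int:
        return round(self.total_duration / self.sampling_interval)

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval

    def to_config(self) -> dict[str, str]:
        """Flat key-value representation (round-trips via ``from_config``)."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = str(v)
        return out

    @classmethod
    def from_config(cls, cfg: dict[str, str]) -> "DesignSpec":
        kwargs: dict = {}
        for f in fields(cls):
            if f.name in cfg:
                raw = cfg[f.name]
                if f.name == "design_type":
                    kwargs[f.name] = raw
                elif f.name in ("n_events", "rng_seed"):
                    kwargs[f.name] = int(raw)
                else:
                    kwargs[f.name] = float(raw)
        return cls(**kwargs)

    def with_seed(self, seed: int | None) -> "DesignSpec":
        return replace(self, rng_seed=seed)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF, parameterised by its response modes.

    The kernel is the difference of two mode-parameterised gamma shapes,

        h(t) = (t/d1)^(d1/b1) exp(-(t - d1)/b1)
             - c (t/d2)^(d2/b2) exp(-(t - d2)/b2),

    where ``d1 = peak_delay`` and ``d2 = undershoot_delay`` are the
    modes of the positive response and the undershoot, ``b1``/``b2``
    their dispersions and ``c`` the undershoot ratio.  The defaults
    (5.4 s peak, 10.8 s undershoot, dispersions 0.9, ratio 0.35) are
    the conventional canonical HRF of the fMRI simulation literature.
    The first term peaks at exactly ``peak_delay`` with value 1, and
    h(0) = 0.
    """

    peak_delay: float = 5.4
    undershoot_delay: float = 10.8
    peak_dispersion: float = 0.9
    undershoot_dispersion: float = 0.9
    undershoot_ratio: float = 0.35

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "undershoot_ratio":
                if v < 0:
                    raise ValueError("undershoot_ratio must be >= 0")
            elif v <= 0:
                raise ValueError(f"{f.name} must be positive")

    def to_config(self) -> dict[str, str]:
        return {f.name: str(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_config(cls, cfg: dict[str, str]) -> "HRFParams":
        return cls(**{f.name: float(cfg[f.name]) for f in fields(cls) if f.name in cfg})


@dataclass(frozen=True)
class ActivationSignal:
    """A sampled, noise-free activation time course.

    ``samples`` includes the baseline ``b``; ``amplitude`` is ``a``,
    the absolute difference between the baseline and the signal peak
    (for a contrast signal: max minus min of the difference course);
    ``fluctuation_sd`` is ``sigma_S``, the population SD of the
    baseline-subtracted samples (invariant to the baseline value).
    """

    samples: np.ndarray
    baseline: float
    amplitude: float
    percent_signal_change: float
    sampling_interval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def fluctuation_sd(self) -> float:
        # population (1/n) denominator; the SD is taken about the sample
        # mean, so the stored baseline does not enter
        return float(np.std(self.samples - self.baseline))

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))


def boxcar(spec: DesignSpec):
    """Binary stimulus vector(s) for a design.

    Returns a single 0/1 vector for block and event-related designs and
    a tuple of two 0/1 vectors (one per condition) for the contrast
    design.

    Block: alternating task/rest starting with task, period
    ``2 * block_length``.  Event-related: ``n_events`` non-overlapping
    events placed uniformly at random (seeded via ``spec.rng_seed``).
    Contrast: repeating [condition 1, condition 2, rest] epochs of
    ``block_length`` each.
    """
    n = spec.n_samples
    dt = spec.sampling_interval
    if spec.design_type == "block":
        half = max(1, round(spec.block_length / dt))
        idx = np.arange(n)
        return ((idx % (2 * half)) < half).astype(float)
    if spec.design_type == "contrast":
        third = max(1, round(spec.block_length / dt))
        phase = np.arange(n) % (3 * third)
        b1 = (phase < third).astype(float)
        b2 = ((phase >= third) & (phase < 2 * third)).astype(float)
        return b1, b2
    # event-related
    width = 1 if spec.event_duration is None else max(1, round(spec.event_duration / dt))
    k = spec.n_events
    free = n - k * width
    if free < 0:
        raise ValueError(
            f"cannot place {k} non-overlapping events of {width} sample(s) "
            f"in {n} samples ({spec.total_duration} s at {dt} s)"
        )
    rng = np.random.default_rng(spec.rng_seed)
    # classic gap construction: choose k slots among n - k*(width-1)
    # positions, then spread them so events cannot overlap
    slots = np.sort(rng.choice(n - k * (width - 1), size=k, replace=False))
    onsets = slots + np.arange(k) * (width - 1)
    vec = np.zeros(n)
    for o in onsets:
        vec[o : o + width] = 1.0
    return vec


def canonical_hrf(time_grid: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF kernel on a time grid.

    The grid must start at 0 and be uniformly spaced.  The kernel is 0
    at t = 0 and its positive lobe peaks at ``params.peak_delay`` with
    unit height (before undershoot subtraction).
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time_grid must be a 1-D vector with at least 2 points")
    if abs(t[0]) > 1e-12:
        raise ValueError("time_grid must start at 0")
    steps = np.diff(t)
    if np.ptp(steps) > 1e-9 * max(steps.max(), 1.0):
        raise ValueError("time_grid must be uniformly spaced")

    def lobe(delay: float, disp: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (t / delay) ** (delay / disp) * np.exp(-(t - delay) / disp)
        out[t <= 0] = 0.0
        return out

    p = params
    return lobe(p.peak_delay, p.peak_dispersion) - p.undershoot_ratio * lobe(
        p.undershoot_delay, p.undershoot_dispersion
    )


def _convolve(stim: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(stim, kernel)[: stim.size]


def _scaled_response(
    stim: np.ndarray, kernel: np.ndarray, amplitude: float
) -> np.ndarray:
    """Convolved response peak-anchored so its maximum equals ``amplitude``."""
    resp = _convolve(stim, kernel)
    peak = resp.max()
    if amplitude == 0:
        return np.zeros_like(resp)
    if peak <= 0:
        raise ValueError("convolved response has no positive peak; cannot scale")
    return resp * (amplitude / peak)


def activation_signal(
    spec: DesignSpec,
    hrf: HRFParams = HRFParams(),
    baseline: float = 100.0,
    psc: float = 1.0,
):
    """Noise-free activation signal(s) for a design at a given percent
    signal change.

    The stimulus boxcar is convolved with the canonical HRF on the
    sampling grid, truncated to the run length and peak-anchored so the
    maximum of the convolved response equals ``baseline * psc / 100``.
    For the contrast design a tuple of two :class:`ActivationSignal` is
    returned: condition 1 is anchored to the full amplitude and
    condition 2 to half of it (condition 1's effect is twice
    condition 2's).
    """
    if psc < 0:
        raise ValueError("psc must be >= 0")
    kernel = canonical_hrf(spec.time_grid, hrf)
    a = baseline * psc / 100.0

    def build(stim: np.ndarray, amplitude: float) -> ActivationSignal:
        resp = _scaled_response(stim, kernel, amplitude)
        return ActivationSignal(
            samples=baseline + resp,
            baseline=baseline,
            amplitude=amplitude,
            percent_signal_change=psc,
            sampling_interval=spec.sampling_interval,
        )

    if spec.design_type == "contrast":
        b1, b2 = boxcar(spec)
        return build(b1, a), build(b2, a / 2.0)
    return build(boxcar(spec), a)


def contrast_signal(s1: ActivationSignal, s2: ActivationSignal) -> ActivationSignal:
    """Difference of the two condition signals.

    Baselines cancel (the stored baseline is 0) and the amplitude is
    the difference between the maximum and minimum of the difference
    course.
    """
    if s1.n_samples != s2.n_samples:
        raise ValueError(
            f"length mismatch: {s1.n_samples} vs {s2.n_samples} samples"
        )
    if not math.isclose(s1.sampling_interval, s2.sampling_interval):
        raise ValueError("sampling_interval mismatch between conditions")
    diff = s1.samples - s2.samples
    return ActivationSignal(
        samples=diff,
        baseline=0.0,
        amplitude=float(diff.max() - diff.min()),
        percent_signal_change=s1.percent_signal_change,
        sampling_interval=s1.sampling_interval,
    )
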