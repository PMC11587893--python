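"""Sensor-level conditioning of epochs and evoked responses.

Baseline correction, zero-phase low-pass filtering, planar-gradiometer vector
sums, regional (areal) averages, category-evoked averaging, and
baseline-window z-scoring.  All operations are pure: they return new
containers and never mutate their inputs.

The baseline window convention is inclusive of the start sample and exclusive
of the end sample, so the stimulus-onset sample (0 ms) is never shared between
baseline and response.  The low-pass filter is a 4th-order Butterworth applied
forward-backward (zero phase), which preserves the peak latencies that the
downstream analyses report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .synthetic import EpochsSet, SensorLayout

__all__ = [
    "EvokedResponse",
    "ArealAverage",
    "baseline_correct",
    "lowpass",
    "vector_sum",
    "evoked_average",
    "areal_average",
    "baseline_zscore",
]


@dataclass
class EvokedResponse:
    """Trial-averaged response of one category: channels x samples."""

    category: str
    data: np.ndarray
    n_trials: int
    sampling_rate: float
    t0_offset: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("evoked data must be channels x samples")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def sample_index(self, t_ms: float) -> int:
        idx = int(round((t_ms - self.t0_offset) * self.sampling_rate / 1000.0))
        if not (0 <= idx < self.n_samples):
            raise ValueError(f"time {t_ms} ms falls outside the epoch")
        return idx


@dataclass
class ArealAverage:
    """Mean vector-sum trace of one region group for one category."""

    group: str
    category: str
    trace: np.ndarray
    n_channels_pooled: int
    sampling_rate: float
    t0_offset: float


def _baseline_bounds(obj, baseline: tuple[float, float]) -> slice:
    b0, b1 = baseline
    if b1 <= b0:
        raise ValueError("baseline end must exceed its start")
    i0 = obj.sample_index(b0)
    i1 = int(round((b1 - obj.t0_offset) * obj.sampling_rate / 1000.0))
    if not (0 <= i1 <= obj.data.shape[-1]):
        raise ValueError("baseline window falls outside the epoch")
    if i1 <= i0:
        raise ValueError("baseline window contains no samples")
    return slice(i0, i1)  # inclusive start, exclusive end


def baseline_correct(obj, baseline: tuple[float, float] = (-200.0, 0.0)):
    """Subtract the per-trace baseline-window mean (idempotent)."""
    sl = _baseline_bounds(obj, baseline)
    data = obj.data - obj.data[..., sl].mean(axis=-1, keepdims=True)
    return replace(obj, data=data)


def lowpass(obj, cutoff_hz: float, order: int = 4):
    """Zero-phase Butterworth low-pass along the time axis.

    Raises if the cutoff reaches the Nyquist frequency.  DC gain is unity and
    no group delay is introduced (forward-backward application).
    """
    nyq = obj.sampling_rate / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    b, a = butter(order, cutoff_hz, btype="low", fs=obj.sampling_rate)
    data = filtfilt(b, a, obj.data, axis=-1)
    return replace(obj, data=data)


def vector_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise sqrt(a^2 + b^2) of a planar-gradiometer pair's traces.

    Orientation-invariant and non-negative: rotating the field pattern between
    the two orthogonal gradiometers leaves the vector sum unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trace shapes differ: {a.shape} vs {b.shape}")
    return np.hypot(a, b)


def evoked_average(epochs: EpochsSet, category: str) -> EvokedResponse:
    """Arithmetic mean over all trials of one category (sets pooled)."""
    mask = epochs.labels == category
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no trials of category {category!r}")
    return EvokedResponse(
        category=category,
        data=epochs.data[mask].mean(axis=0),
        n_trials=n,
        sampling_rate=epochs.sampling_rate,
        t0_offset=epochs.t0_offset,
    )


def areal_average(
    evoked: EvokedResponse, layout: SensorLayout, group: str
) -> ArealAverage:
    """Mean of the pair vector sums over one gradiometer region group."""
    groups = layout.groups
    if group not in groups:
        raise ValueError(
            f"unknown group {group!r}; layout has {sorted(groups)}"
        )
    members = set(groups[group])
    traces = []
    for pid, (i, j) in layout.pairs.items():
        if i in members or j in members:
            if not (i in members and j in members):
                raise ValueError(f"pair {pid} is split across groups")
            traces.append(vector_sum(evoked.data[i], evoked.data[j]))
    return ArealAverage(
        group=group,
        category=evoked.category,
        trace=np.mean(traces, axis=0),
        n_channels_pooled=len(members),
        sampling_rate=evoked.sampling_rate,
        t0_offset=evoked.t0_offset,
    )


def baseline_zscore(
    evoked: EvokedResponse, baseline: tuple[float, float] = (-200.0, 0.0)
) -> EvokedResponse:
    """Divide each channel by its own baseline-window SD (unitless output)."""
    sl = _baseline_bounds(evoked, baseline)
    sd = evoked.data[:, sl].std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(
            f"zero baseline SD on channel index(es) {bad.tolist()}; cannot z-score"
        )
    return replace(evoked, data=evoked.data / sd[:, None])
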