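"""Escape-behaviour quantification and von Frey bending-onset detection.

Treadmill behaviour (speed, direction, distance, eyeblink, forelimb) is
captured as frame-by-frame ROI-difference traces; each channel is z-scored
against a pre-stimulus baseline so animals can be compared on a common
scale, and the response is summarized by the maximum z within a 5 s
post-stimulus horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DegenerateInputError, ParameterError, ValidationError

CHANNELS = ("speed", "direction", "distance", "eyeblink", "forelimb")


@dataclass
class BehaviorTrace:
    """Uniformly sampled motion trace for one behavioural channel."""

    times: np.ndarray
    values: np.ndarray
    stimulus_onset_s: float
    channel: str = "speed"
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        d = np.diff(self.times)
        if d.size and (d.min() <= 0 or d.max() - d.min() > 1e-6 * d.mean()):
            raise ValidationError("times must be uniformly sampled and increasing")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class EscapeMetrics:
    z_trace: np.ndarray        # z-scored full trace
    max_z: float               # maximum z within the response window
    time_of_max_s: float       # seconds relative to stimulus onset


@dataclass
class BendTrace:
    """Skin-bending signal under a von Frey filament (camera at ~200 Hz)."""

    times: np.ndarray
    bend: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bend = np.asarray(self.bend, dtype=float)
        if self.times.shape != self.bend.shape:
            raise ValidationError("times and bend must have equal length")
        if not np.all(np.isfinite(self.bend)):
            raise ValidationError("bend contains non-finite entries")
        if self.times.size < 2 or self.times[-1] - self.times[0] < 1.0:
            raise ValidationError("bend trace must span at least 1 s")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def roi_motion(stack, roi: tuple[int, int, int, int],
               channel: str = "speed") -> BehaviorTrace:
    """Frame-by-frame motion energy: mean absolute pixel difference between
    consecutive frames inside ``roi = (r0, c0, r1, c1)``; the first sample
    is 0 by convention."""
    r0, c0, r1, c1 = roi
    T, H, W = stack.frames.shape
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ParameterError(f"roi {roi} outside frame bounds {(H, W)}")
    sub = stack.frames[:, r0:r1, c0:c1]
    motion = np.zeros(T)
    motion[1:] = np.abs(np.diff(sub, axis=0)).mean(axis=(1, 2))
    times = np.arange(T) / stack.frame_rate
    onset = stack.stimulus_onset_index / stack.frame_rate
    return BehaviorTrace(times=times, values=motion, stimulus_onset_s=onset,
                         channel=channel)


def escape_metrics(trace: BehaviorTrace,
                   baseline_window: tuple[float, float] = (-5.0, 0.0),
                   response_window: tuple[float, float] = (0.0, 5.0)
                   ) -> EscapeMetrics:
    """Z-score the trace against its pre-stimulus baseline and take the
    maximum z (and its time) within the post-stimulus response window.

    Windows are seconds relative to the stimulus onset.  Z-scoring uses the
    baseline mean and population SD, so the metrics are exactly invariant to
    positive affine rescaling of the raw trace.
    """
    rel = trace.times - trace.stimulus_onset_s
    base = (rel >= baseline_window[0]) & (rel < baseline_window[1])
    resp = (rel >= response_window[0]) & (rel < response_window[1])
    if base.sum() < 2 or resp.sum() < 1:
        raise ParameterError("baseline/response windows do not fit inside the trace")
    mu = trace.values[base].mean()
    sd = trace.values[base].std()
    if sd == 0.0:
        raise DegenerateInputError("baseline has zero variance; z-score undefined")
    z = (trace.values - mu) / sd
    i = np.flatnonzero(resp)[np.argmax(z[resp])]
    return EscapeMetrics(z_trace=z, max_z=float(z[i]), time_of_max_s=float(rel[i]))


def vonfrey_onset(trace: BendTrace, derivative_fraction: float = 0.05,
                  smoothing_sigma_s: float = 0.025) -> float:
    """Bending onset of a von Frey filament = the saturation point of the
    skin-bending signal.

    Operationalized as derivative collapse: smooth the bend signal
    (Gaussian, ``smoothing_sigma_s``), find the maximum derivative of the
    rise, and return the first subsequent time the derivative falls below
    ``derivative_fraction`` times that maximum.  Returns NaN when the
    derivative never collapses (no plateau) or the trace has no rise.

    Smoothing shifts the detected point by O(sigma); pass
    ``smoothing_sigma_s=0`` for clean, noise-free traces.
    """
    if not (0.0 < derivative_fraction < 1.0):
        raise ParameterError("derivative_fraction must be in (0, 1)")
    sr = trace.sample_rate
    if smoothing_sigma_s > 0:
        bend = gaussian_filter1d(trace.bend, smoothing_sigma_s * sr, mode="nearest")
    else:
        bend = trace.bend
    d = np.gradient(bend, trace.times)
    i_max = int(np.argmax(d))
    d_max = d[i_max]
    if d_max <= 0:
        return float("nan")
    after = d[i_max:]
    below = np.flatnonzero(after < derivative_fraction * d_max)
    if below.size == 0:
        return float("nan")
    return float(trace.times[i_max + below[0]])
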