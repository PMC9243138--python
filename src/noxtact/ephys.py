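"""Core response quantification: PSTHs, windowed S/N statistics, four-way
cell classification, thermal thresholds, onset latencies, and suppression.

The S/N statistic
-----------------
For noxious heat, the signal window S is the 0.5 s the Peltier surface
spends in the noxious 45-50 degC range (rising phase + plateau) and the
noise window N is the preceding 1.0 s innocuous traversal of 33-45 degC;
an alternative noise mode uses the 1.0 s of steady-state baseline
temperature (~30 degC) ending at ramp onset.  For whisker deflections, S is
the 30 ms after each deflection onset and N the 60 ms before it, pooled
over all deflections.

Because the S and N windows differ in duration, the statistic is a ratio of
*rates*, regularized as ``(s_rate + eps) / (n_rate + eps)`` with a small
eps (default 0.1 Hz) so units silent in the noise window stay finite while
the ordering of responses is preserved.

Classification uses per-modality cutoffs on the S/N: a unit is nociceptive
if only its noxious-heat S/N exceeds the noxious cutoff, tactile if only
the tactile S/N exceeds the tactile cutoff, integrative if both do, and
non-reactive otherwise.  Ties sit on the non-responsive side.  The
study-level cutoffs estimated from the recorded population are the medians
1.46 (noxious heat) and 1.81 (tactile); they ship as named defaults because
they are not recomputable without the in-vivo data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError, StimulusError, ValidationError
from .session import HeatTrace, RecordingSession, SpikeTrain, TactileEvents

#: study-level median S/N cutoffs (noxious heat, tactile)
STUDY_CUTOFFS = (1.46, 1.81)

#: rate regularization for the S/N ratio, Hz
DEFAULT_EPSILON_HZ = 0.1

#: tactile S/N windows, s
TACTILE_S_WINDOW_S = 0.030
TACTILE_N_WINDOW_S = 0.060

#: heat S/N window temperatures, degC
NOXIOUS_RANGE_C = (45.0, 50.0)
INNOXIOUS_RANGE_C = (33.0, 45.0)

CELL_LABELS = ("nociceptive", "tactile", "integrative", "none")


@dataclass(frozen=True)
class PSTH:
    """Trial-pooled peristimulus time histogram (half-open uniform bins)."""

    unit_id: str
    bin_edges: np.ndarray     # s relative to the alignment event
    counts: np.ndarray        # pooled spike counts per bin
    n_trials: int

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        w = np.diff(self.bin_edges)
        if np.any(w <= 0) or (w.size and w.max() - w.min() > 1e-9 * w.mean()):
            raise ValidationError("bin edges must be strictly increasing and uniform")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def rate(self) -> np.ndarray:
        """Firing rate per bin, Hz."""
        return self.counts / (self.n_trials * self.bin_width)


@dataclass(frozen=True)
class SNResult:
    unit_id: str
    modality: str              # "noxH" | "tactile"
    s_rate: float
    n_rate: float
    ratio: float
    noise_mode: str | None = None   # heat only

    def __post_init__(self):
        if self.modality not in ("noxH", "tactile"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.s_rate < 0 or self.n_rate < 0 or self.ratio <= 0:
            raise ValidationError("rates must be >= 0 and ratio > 0")


@dataclass(frozen=True)
class CellClass:
    label: str
    cutoff_nox: float
    cutoff_tact: float

    def __post_init__(self):
        if self.label not in CELL_LABELS:
            raise ValidationError(f"unknown class label {self.label!r}")


@dataclass(frozen=True)
class ThermalThreshold:
    """Temperature at which the smoothed response reaches 80% of its peak.

    ``threshold_c`` is NaN when the unit fired no spikes in the stimulus
    epoch (undefined threshold, excluded from dispersion comparisons).
    """

    unit_id: str
    threshold_c: float
    peak_rate: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.threshold_c)


@dataclass(frozen=True)
class HeatTrialWindows:
    """Stimulus windows of one heat trial, in session time (seconds)."""

    ramp_onset: float          # start of the rising ramp
    s_window: tuple            # [45, 50] degC: rising phase + plateau
    n_window: tuple            # last 1.0 s of the rising 33-45 degC traversal
    steady_window: tuple       # 1.0 s at baseline temperature ending at ramp onset
    plateau_end: float


# ---------------------------------------------------------------------------
# heat-window recovery by thresholding the trace
# ---------------------------------------------------------------------------

def _rising_crossings(times, temps, level):
    """Linear-interpolated times where the trace crosses ``level`` upward."""
    below = temps[:-1] < level
    atabove = temps[1:] >= level
    idx = np.flatnonzero(below & atabove)
    frac = (level - temps[idx]) / (temps[idx + 1] - temps[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def heat_windows(heat: HeatTrace,
                 n_window_s: float = 1.0,
                 steady_window_s: float = 1.0) -> list[HeatTrialWindows]:
    """Locate the S/N windows of every heat trial in a trace.

    Each rising crossing of 45 degC starts one trial.  The S window runs
    from that crossing to the end of the plateau (the first strictly
    decreasing sample afterwards); the return ramp is excluded by
    convention.  The N window is the trailing ``n_window_s`` of the rising
    33-45 degC traversal, and the steady window the ``steady_window_s``
    ending at ramp onset.
    """
    t, T = heat.times, heat.temperatures
    lo, hi = NOXIOUS_RANGE_C
    t45 = _rising_crossings(t, T, lo)
    if t45.size == 0:
        raise StimulusError("no rising 45 degC crossing found in the heat trace")
    t33 = _rising_crossings(t, T, INNOXIOUS_RANGE_C[0])
    dT = np.diff(T)
    out = []
    for k, s0 in enumerate(t45):
        i0 = int(np.searchsorted(t, s0))
        dec = np.flatnonzero(dT[i0:] < -1e-12)
        if dec.size == 0:
            raise StimulusError(f"heat trial {k}: plateau never ends (no return ramp)")
        plateau_end = t[i0 + dec[0]]
        if plateau_end <= s0:
            raise StimulusError(f"heat trial {k}: empty noxious window")
        prior33 = t33[t33 < s0]
        if prior33.size == 0:
            raise StimulusError(f"heat trial {k}: no rising 33 degC crossing")
        n1 = s0
        n0 = max(float(prior33[-1]), s0 - n_window_s)
        # ramp onset = start of the increasing run containing the 45 degC crossing
        inc_start = np.flatnonzero(dT[:i0] <= 1e-12)
        ramp_onset = t[inc_start[-1] + 1] if inc_start.size else t[0]
        out.append(HeatTrialWindows(
            ramp_onset=float(ramp_onset),
            s_window=(float(s0), float(plateau_end)),
            n_window=(float(n0), float(n1)),
            steady_window=(float(ramp_onset - steady_window_s), float(ramp_onset)),
            plateau_end=float(plateau_end)))
    return out


def _count_in(train: SpikeTrain, lo: float, hi: float) -> int:
    t = train.spike_times
    return int(np.searchsorted(t, hi, side="left")
               - np.searchsorted(t, lo, side="left"))


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def compute_psth(train: SpikeTrain, align_times, window: tuple[float, float],
                 bin_width: float) -> PSTH:
    """Trial-pooled PSTH in half-open bins over ``window = (pre_s, post_s)``
    relative to each alignment time.  A spike exactly on a bin edge falls in
    the right-hand bin."""
    align_times = np.atleast_1d(np.asarray(align_times, dtype=float))
    if align_times.size == 0:
        raise ParameterError("need at least one alignment time")
    pre, post = window
    span = post - pre
    if span <= 0 or bin_width <= 0:
        raise ParameterError("window must be nonempty and bin_width > 0")
    n_bins = int(round(span / bin_width))
    if abs(n_bins * bin_width - span) > 1e-9:
        raise ParameterError("bin_width must divide the window span")
    edges = pre + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    for a in align_times:
        rel = train.spike_times - a
        # 1e-9-bin guard keeps spikes that sit bitwise on an edge in the
        # right-hand bin despite float round-off in the division
        idx = np.floor((rel - pre) / bin_width + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts += np.bincount(idx, minlength=n_bins)
    return PSTH(unit_id=train.unit_id, bin_edges=edges, counts=counts,
                n_trials=int(align_times.size))


def psth_matrix(psths: list[PSTH],
                sort_by: list[PSTH] | None = None) -> tuple[np.ndarray, list[str]]:
    """Peak-normalized, peak-time-sorted PSTH matrix.

    Each row is a unit's rate divided by its own maximum (all-zero rows stay
    zero).  Rows are ordered by the argmax bin of the corresponding
    ``sort_by`` PSTH (default: the rows themselves); ties break stably by
    unit_id.  Returns (matrix, row unit_ids).
    """
    if not psths:
        raise ParameterError("empty PSTH list")
    sort_by = sort_by if sort_by is not None else psths
    if len(sort_by) != len(psths):
        raise ParameterError("sort_by must have one PSTH per row")
    edges0 = psths[0].bin_edges
    for p in psths[1:]:
        if p.bin_edges.shape != edges0.shape or not np.allclose(p.bin_edges, edges0):
            raise ParameterError("all PSTHs must share binning")
    rows = []
    for p in psths:
        r = p.rate.astype(float)
        m = r.max()
        rows.append(r / m if m > 0 else r)
    keys = [(int(np.argmax(s.rate)), p.unit_id) for p, s in zip(psths, sort_by)]
    order = sorted(range(len(psths)), key=lambda i: keys[i])
    return np.array([rows[i] for i in order]), [psths[i].unit_id for i in order]


# ---------------------------------------------------------------------------
# S/N statistics
# ---------------------------------------------------------------------------

def snr_heat(train: SpikeTrain, heat: HeatTrace, trial_onsets=None,
             noise_mode: str = "innoxious_ramp",
             epsilon: float = DEFAULT_EPSILON_HZ) -> SNResult:
    """Noxious-heat S/N of one unit, pooled over all heat trials.

    Trials are auto-detected in the trace by thresholding; alternatively
    ``trial_onsets`` gives session-time offsets at which copies of the (one
    detected) template trial start.
    """
    if noise_mode not in ("innoxious_ramp", "steady_state"):
        raise ParameterError(f"unknown noise_mode {noise_mode!r}")
    wins = heat_windows(heat)
    if trial_onsets is not None:
        w0 = wins[0]
        wins = [HeatTrialWindows(
            ramp_onset=w0.ramp_onset + o,
            s_window=(w0.s_window[0] + o, w0.s_window[1] + o),
            n_window=(w0.n_window[0] + o, w0.n_window[1] + o),
            steady_window=(w0.steady_window[0] + o, w0.steady_window[1] + o),
            plateau_end=w0.plateau_end + o) for o in np.atleast_1d(trial_onsets)]
    s_count = s_dur = n_count = n_dur = 0.0
    for w in wins:
        s_count += _count_in(train, *w.s_window)
        s_dur += w.s_window[1] - w.s_window[0]
        nw = w.n_window if noise_mode == "innoxious_ramp" else w.steady_window
        n_count += _count_in(train, *nw)
        n_dur += nw[1] - nw[0]
    s_rate = s_count / s_dur
    n_rate = n_count / n_dur
    return SNResult(unit_id=train.unit_id, modality="noxH", s_rate=s_rate,
                    n_rate=n_rate, ratio=(s_rate + epsilon) / (n_rate + epsilon),
                    noise_mode=noise_mode)


def snr_tactile(train: SpikeTrain, tactile: TactileEvents,
                epsilon: float = DEFAULT_EPSILON_HZ) -> SNResult:
    """Tactile S/N: spikes in the 30 ms after vs the 60 ms before each
    deflection onset, pooled over all deflections.  A spike exactly at the
    onset belongs to the S window."""
    if tactile.n_events == 0:
        raise ParameterError("need at least one deflection onset")
    s_count = n_count = 0
    for o in tactile.onsets:
        s_count += _count_in(train, o, o + TACTILE_S_WINDOW_S)
        n_count += _count_in(train, o - TACTILE_N_WINDOW_S, o)
    n = tactile.n_events
    s_rate = s_count / (TACTILE_S_WINDOW_S * n)
    n_rate = n_count / (TACTILE_N_WINDOW_S * n)
    return SNResult(unit_id=train.unit_id, modality="tactile", s_rate=s_rate,
                    n_rate=n_rate, ratio=(s_rate + epsilon) / (n_rate + epsilon))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def compute_cutoffs(sn_nox, sn_tact) -> tuple[float, float]:
    """Per-modality median S/N over all units pooled across regions and
    layers (even-length medians average the middle pair)."""
    sn_nox = np.asarray(sn_nox, dtype=float)
    sn_tact = np.asarray(sn_tact, dtype=float)
    if sn_nox.size == 0 or sn_tact.size == 0:
        raise ParameterError("S/N lists must be nonempty")
    return float(np.median(sn_nox)), float(np.median(sn_tact))


def classify_unit(sn_nox: float, sn_tact: float,
                  cutoffs: tuple[float, float] = STUDY_CUTOFFS) -> CellClass:
    """Four-way label from the two S/N values: responsive to a modality iff
    its S/N is strictly greater than that modality's cutoff."""
    if not (np.isfinite(sn_nox) and np.isfinite(sn_tact)):
        raise ValidationError("S/N ratios must be finite")
    c_nox, c_tact = cutoffs
    nox = sn_nox > c_nox
    tact = sn_tact > c_tact
    if nox and tact:
        label = "integrative"
    elif nox:
        label = "nociceptive"
    elif tact:
        label = "tactile"
    else:
        label = "none"
    return CellClass(label=label, cutoff_nox=float(c_nox), cutoff_tact=float(c_tact))


# ---------------------------------------------------------------------------
# thermal threshold and onset latency
# ---------------------------------------------------------------------------

def thermal_threshold(train: SpikeTrain, heat: HeatTrace, trial_onsets=None,
                      smoothing_sigma_s: float = 0.1,
                      bin_width_s: float = 0.01,
                      peak_fraction: float = 0.8) -> ThermalThreshold:
    """Thermal tuning threshold: the temperature at which the unit's
    Gaussian-smoothed, trial-pooled rate first reaches ``peak_fraction``
    (80%) of its peak on the rising ramp.

    The rate is estimated over the ramp-onset -> plateau-end epoch of each
    trial; the crossing time maps to a temperature by linear interpolation
    of the trace.  Units silent in the epoch get a NaN (undefined)
    threshold.
    """
    if smoothing_sigma_s < 0 or bin_width_s <= 0:
        raise ParameterError("smoothing_sigma_s must be >= 0 and bin_width_s > 0")
    wins = heat_windows(heat)
    if trial_onsets is not None:
        base = wins[0]
        wins = [HeatTrialWindows(
            ramp_onset=base.ramp_onset + o, s_window=base.s_window,
            n_window=base.n_window, steady_window=base.steady_window,
            plateau_end=base.plateau_end + o) for o in np.atleast_1d(trial_onsets)]
    epoch = min(w.plateau_end - w.ramp_onset for w in wins)
    n_bins = max(1, int(np.floor(epoch / bin_width_s)))
    counts = np.zeros(n_bins)
    for w in wins:
        rel = train.spike_times - w.ramp_onset
        idx = np.floor(rel / bin_width_s + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts += np.bincount(idx, minlength=n_bins)
    rate = counts / (len(wins) * bin_width_s)
    if smoothing_sigma_s > 0:
        rate = gaussian_filter1d(rate, smoothing_sigma_s / bin_width_s,
                                 mode="nearest")
    peak = float(rate.max())
    if counts.sum() == 0 or peak <= 0:
        return ThermalThreshold(unit_id=train.unit_id, threshold_c=float("nan"),
                                peak_rate=0.0)
    first = int(np.argmax(rate >= peak_fraction * peak))
    t_cross = wins[0].ramp_onset + first * bin_width_s   # left bin edge
    temp = float(np.interp(t_cross, heat.times, heat.temperatures))
    return ThermalThreshold(unit_id=train.unit_id, threshold_c=temp,
                            peak_rate=peak)


def onset_latency(train: SpikeTrain, tactile: TactileEvents,
                  bin_width_s: float = 0.001, horizon_s: float = 0.060,
                  baseline_s: float = 0.060, k_sd: float = 2.0,
                  min_consecutive: int = 2) -> float:
    """Tactile onset latency (ms) from the deflection-pooled 1 ms PSTH.

    The rate is averaged over ``min_consecutive``-bin sliding windows (so a
    response must be sustained for at least that long); the latency is the
    start of the first post-onset window whose mean rate exceeds the
    pre-onset baseline mean + ``k_sd`` SD.  NaN when nothing crosses within
    the 60 ms horizon.  This estimator is a package convention — the study
    does not publish its latency algorithm.
    """
    psth = compute_psth(train, tactile.onsets, (-baseline_s, horizon_s),
                        bin_width_s)
    rate = psth.rate
    n_base = int(round(baseline_s / bin_width_s))
    w = max(1, int(min_consecutive))
    smooth = np.convolve(rate, np.ones(w) / w, mode="valid")  # window means
    base = smooth[:n_base - w + 1] if n_base - w + 1 > 0 else smooth[:1]
    thresh = base.mean() + k_sd * base.std()
    post = smooth[n_base:]
    above = np.flatnonzero(post > thresh)
    if above.size == 0:
        return float("nan")
    # within the first sustained window, report the first individually
    # suprathreshold bin (so an isolated sharp response dates from its own bin)
    j0 = n_base + int(above[0])
    for j in range(j0, min(j0 + w, rate.size)):
        if rate[j] > thresh:
            return float((j - n_base) * bin_width_s * 1e3)
    return float(above[0] * bin_width_s * 1e3)


def suppressed_fraction(sn_nox) -> float:
    """Fraction of units whose noxious-heat S/N is strictly below 1 —
    i.e. whose activity was suppressed during the noxious window."""
    sn_nox = np.asarray(sn_nox, dtype=float)
    if sn_nox.size == 0:
        raise ParameterError("S/N list must be nonempty")
    return float(np.mean(sn_nox < 1.0))


# ---------------------------------------------------------------------------
# per-session metric tables
# ---------------------------------------------------------------------------

def unit_metrics_table(session: RecordingSession,
                       cutoffs: tuple[float, float] = STUDY_CUTOFFS,
                       epsilon: float = DEFAULT_EPSILON_HZ,
                       noise_mode: str = "innoxious_ramp",
                       smoothing_sigma_s: float = 0.1) -> pd.DataFrame:
    """Per-unit metrics: S/N for both modalities, class label, thermal
    threshold, tactile onset latency, and the suppression flag."""
    rows = []
    for u in session.units:
        nox = snr_heat(u, session.heat, noise_mode=noise_mode, epsilon=epsilon)
        tact = snr_tactile(u, session.tactile, epsilon=epsilon)
        cls = classify_unit(nox.ratio, tact.ratio, cutoffs)
        thr = thermal_threshold(u, session.heat,
                                smoothing_sigma_s=smoothing_sigma_s)
        lat = onset_latency(u, session.tactile)
        rows.append({
            "unit_id": u.unit_id, "region": u.region, "layer": u.layer,
            "kind": u.kind, "sn_nox": nox.ratio, "sn_tact": tact.ratio,
            "noise_mode": noise_mode, "class": cls.label,
            "threshold_c": thr.threshold_c, "latency_ms": lat,
            "suppressed": bool(nox.ratio < 1.0),
        })
    return pd.DataFrame(rows)


def classification_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Region x layer x class counts and within-stratum proportions."""
    counts = (metrics.groupby(["region", "layer", "class"], observed=True)
              .size().rename("n").reset_index())
    totals = counts.groupby(["region", "layer"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts.sort_values(["region", "layer", "class"]).reset_index(drop=True)
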