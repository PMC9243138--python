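"""Seeded generators with known ground truth.

These stand in for the in-vivo data: a Peltier-style temperature ramp into
the noxious range, piezo whisker-deflection trains, four unit archetypes
(nociceptive, tactile, integrative, non-reactive) spiking as inhomogeneous
Poisson processes, intrinsic-signal image stacks with an activation blob,
and treadmill/von-Frey behaviour traces.

Every generator is a pure function of (parameters, seed).  Units inside a
session draw from independent substreams keyed by (seed, unit index), so
adding units never perturbs the ones already generated.

Rate model
----------
For a unit with archetype parameters ``(b, g_h, theta, k, g_t, tau, s)``::

    r(t) = supp(t) * [ b + g_t * sum_i alpha((t - onset_i) / tau) ]
           + g_h * sigmoid((T(t) - theta) / k)

with ``alpha(u) = u * exp(1 - u)`` the unit-peak alpha kernel,
``sigmoid`` the logistic function, and ``supp(t) = s`` while the skin
temperature exceeds 45 degC (else 1).  Spikes are drawn by Lewis-Shedler
thinning against a ceiling of 1.05x the analytic maximum of ``r``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import BehaviorTrace, BendTrace
from .errors import ParameterError, ValidationError
from .imaging import ImageStack
from .session import (
    LAYERS,
    MIN_DEFLECTION_SPACING_S,
    REGIONS,
    HeatTrace,
    RecordingSession,
    SpikeTrain,
    TactileEvents,
)

NOXIOUS_ONSET_C = 45.0   # skin temperature above which heat is noxious
INNOXIOUS_ONSET_C = 33.0

ARCHETYPE_LABELS = ("nociceptive", "tactile", "integrative", "none")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class UnitArchetype:
    """Generative parameters of one synthetic unit."""

    label: str
    baseline_rate: float            # Hz
    heat_gain: float = 0.0          # Hz added at full sigmoid drive
    heat_threshold: float = 46.0    # degC, sigmoid midpoint
    heat_slope: float = 1.0         # degC, sigmoid scale
    tactile_gain: float = 0.0       # Hz at the alpha-kernel peak
    tactile_tau: float = 0.005      # s
    suppression_factor: float = 1.0  # applied while T > 45 degC

    def __post_init__(self):
        if self.label not in ARCHETYPE_LABELS:
            raise ValidationError(f"unknown archetype label {self.label!r}")
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be > 0")
        if self.heat_gain < 0 or self.tactile_gain < 0:
            raise ValidationError("gains must be >= 0")
        if self.heat_slope <= 0:
            raise ValidationError("heat_slope must be > 0")
        if self.tactile_tau <= 0:
            raise ValidationError("tactile_tau must be > 0")
        if not (0.0 < self.suppression_factor <= 1.0):
            raise ValidationError("suppression_factor must be in (0, 1]")


#: default archetype parameter presets; heat-driven units follow a logistic
#: tuning curve centred in the noxious range, tactile units a fast (5 ms)
#: alpha kernel per deflection
DEFAULT_ARCHETYPES: dict[str, UnitArchetype] = {
    "nociceptive": UnitArchetype("nociceptive", baseline_rate=2.0, heat_gain=20.0,
                                 heat_threshold=46.0, heat_slope=1.0),
    "tactile": UnitArchetype("tactile", baseline_rate=3.0, tactile_gain=30.0,
                             tactile_tau=0.005),
    "integrative": UnitArchetype("integrative", baseline_rate=2.0, heat_gain=20.0,
                                 heat_threshold=46.0, heat_slope=1.0,
                                 tactile_gain=30.0, tactile_tau=0.005),
    "none": UnitArchetype("none", baseline_rate=4.0),
}


# ---------------------------------------------------------------------------
# stimulus generators
# ---------------------------------------------------------------------------

def make_heat_trace(baseline_c: float = 30.0, ramp_rate: float = 12.0,
                    plateau_c: float = 50.0, plateau_s: float = 1.0 / 12.0,
                    sample_rate: float = 1000.0, pre_hold_s: float = 2.0,
                    post_hold_s: float = 1.0) -> HeatTrace:
    """Trapezoidal Peltier temperature trace: hold -> ramp -> plateau ->
    return ramp -> hold.

    Defaults reproduce the study's stimulus windows exactly: at 12 degC/s the
    33->45 degC traversal lasts 1.000 s (the innocuous noise window) and the
    45->50 degC rise (5/12 s) plus the 1/12 s plateau dwell give 0.500 s in
    the noxious 45-50 degC range before the return ramp.
    """
    if sample_rate <= 0 or ramp_rate <= 0 or plateau_s < 0:
        raise ParameterError("sample_rate, ramp_rate must be > 0 and plateau_s >= 0")
    if not (NOXIOUS_ONSET_C < plateau_c <= 50.0):
        raise ParameterError("plateau_c must lie in (45, 50] degC (noxious range)")
    if baseline_c >= INNOXIOUS_ONSET_C:
        raise ParameterError("baseline_c must be below 33 degC or the innocuous "
                             "window is empty")

    rise = (plateau_c - baseline_c) / ramp_rate
    t_break = np.array([
        0.0,
        pre_hold_s,
        pre_hold_s + rise,
        pre_hold_s + rise + plateau_s,
        pre_hold_s + rise + plateau_s + rise,
        pre_hold_s + rise + plateau_s + rise + post_hold_s,
    ])
    T_break = np.array([baseline_c, baseline_c, plateau_c, plateau_c,
                        baseline_c, baseline_c])
    dt = 1.0 / sample_rate
    n = int(round(t_break[-1] / dt))
    times = np.arange(n + 1) * dt
    temps = np.interp(times, t_break, T_break)
    return HeatTrace(times=times, temperatures=temps, sample_rate=float(sample_rate))


def repeat_heat_trace(trace: HeatTrace, n_trials: int,
                      total_duration_s: float | None = None) -> HeatTrace:
    """Tile a single-trial trace ``n_trials`` times back-to-back (each copy
    keeps its own pre/post holds) and optionally pad with the baseline
    temperature out to ``total_duration_s``."""
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    dt = 1.0 / trace.sample_rate
    n_per = trace.times.size - 1             # samples per trial, endpoint shared
    temps = np.concatenate([np.tile(trace.temperatures[:-1], n_trials),
                            trace.temperatures[-1:]])
    if total_duration_s is not None:
        n_total = int(round(total_duration_s / dt))
        if n_total + 1 > temps.size:
            pad = np.full(n_total + 1 - temps.size, trace.temperatures[0])
            temps = np.concatenate([temps, pad])
    times = np.arange(temps.size) * dt
    return HeatTrace(times=times, temperatures=temps, sample_rate=trace.sample_rate)


def make_deflection_train(n_events: int, interval_s: float = 0.2,
                          jitter_s: float = 0.0, seed=0,
                          start_s: float = 0.0) -> TactileEvents:
    """Jittered whisker-deflection onsets: event ``i`` at
    ``start + (i+1)*interval + U(-jitter/2, +jitter/2)``."""
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    if interval_s - jitter_s < MIN_DEFLECTION_SPACING_S:
        raise ParameterError(
            "interval_s - jitter_s must be >= 90 ms so S/N windows never overlap"
        )
    rng = _rng(seed)
    onsets = start_s + np.arange(1, n_events + 1) * interval_s
    if jitter_s > 0:
        onsets = onsets + rng.uniform(-jitter_s / 2.0, jitter_s / 2.0, n_events)
    return TactileEvents(onsets=onsets)


# ---------------------------------------------------------------------------
# spike-train simulation
# ---------------------------------------------------------------------------

def _alpha(u: np.ndarray) -> np.ndarray:
    out = np.where(u > 0, u * np.exp(1.0 - np.minimum(u, 700.0)), 0.0)
    return out


def unit_rate(arch: UnitArchetype, t, heat: HeatTrace | None,
              tactile: TactileEvents | None) -> np.ndarray:
    """Instantaneous firing rate r(t) in Hz of the archetype model."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    drive = np.full(t.shape, arch.baseline_rate)
    if tactile is not None and arch.tactile_gain > 0 and tactile.n_events:
        onsets = tactile.onsets
        gaps = np.diff(onsets)
        min_gap = gaps.min() if gaps.size else np.inf
        k_back = int(min(5, max(1, np.ceil(15.0 * arch.tactile_tau / min_gap))))
        idx = np.searchsorted(onsets, t, side="right")
        kern = np.zeros(t.shape)
        for k in range(1, k_back + 1):
            j = idx - k
            ok = j >= 0
            u = np.zeros(t.shape)
            u[ok] = (t[ok] - onsets[j[ok]]) / arch.tactile_tau
            kern += _alpha(u)
        drive = drive + arch.tactile_gain * kern
    if heat is not None:
        T = heat.temperature_at(t)
        supp = np.where(T > NOXIOUS_ONSET_C, arch.suppression_factor, 1.0)
    else:
        supp = 1.0
    r = supp * drive
    if heat is not None and arch.heat_gain > 0:
        x = (heat.temperature_at(t) - arch.heat_threshold) / arch.heat_slope
        r = r + arch.heat_gain / (1.0 + np.exp(-x))
    return r


def _alpha_sum_bound(arch: UnitArchetype, tactile: TactileEvents | None) -> float:
    """Upper bound on the superposed alpha-kernel amplitude given the
    minimum inter-event gap (kernels have unit peak)."""
    if tactile is None or arch.tactile_gain == 0 or tactile.n_events == 0:
        return 0.0
    gaps = np.diff(tactile.onsets)
    if not gaps.size:
        return 1.0
    g = gaps.min() / arch.tactile_tau
    tail = sum(float(_alpha(np.array([1.0 + j * g]))[0]) for j in range(1, 8))
    return 1.0 + tail


def simulate_unit(arch: UnitArchetype, heat: HeatTrace | None,
                  tactile: TactileEvents | None, duration_s: float, seed,
                  unit_id: str = "u0", region: str = "Dys", layer: str = "L2/3",
                  kind: str = "SUA") -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning against the analytic
    rate ceiling (1.05x the maximum of r)."""
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    r_max = arch.baseline_rate + arch.heat_gain \
        + arch.tactile_gain * _alpha_sum_bound(arch, tactile)
    ceiling = 1.05 * r_max
    if not np.isfinite(ceiling) or ceiling <= 0:
        raise ParameterError("rate ceiling for thinning is not a positive finite "
                             f"number (got {ceiling})")
    rng = _rng(seed)
    n_cand = rng.poisson(ceiling * duration_s)
    t_cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    r = unit_rate(arch, t_cand, heat, tactile)
    if np.any(r > ceiling * (1.0 + 1e-9)):
        raise ParameterError("instantaneous rate exceeds the thinning ceiling")
    keep = rng.uniform(0.0, 1.0, n_cand) < r / ceiling
    return SpikeTrain(unit_id=unit_id, region=region, layer=layer, kind=kind,
                      spike_times=t_cand[keep])


# ---------------------------------------------------------------------------
# whole-session simulation
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Study-condition parameters for one synthetic session.

    The defaults emulate the recording design: paired Dys/BF penetrations
    across L2/3-L5b, repeated noxious-heat trials followed by a long
    whisker-deflection train, and archetype mixtures drawn per unit.
    """

    n_units_per_stratum: int = 50
    regions: tuple = REGIONS
    layers: tuple = LAYERS
    mixture: dict = field(default_factory=lambda: {
        "nociceptive": 0.25, "tactile": 0.25, "integrative": 0.25, "none": 0.25})
    region_mixture: dict = field(default_factory=dict)  # region -> mixture override
    archetypes: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    suppressed_prob: dict = field(default_factory=lambda: {"Dys": 0.0, "BF": 0.0})
    suppression_factor: float = 0.3
    n_heat_trials: int = 10
    heat_kwargs: dict = field(default_factory=dict)
    n_deflections: int = 100
    deflection_interval_s: float = 0.2
    deflection_jitter_s: float = 0.04
    kind: str = "SUA"

    def mixture_for(self, region: str) -> dict:
        mix = self.region_mixture.get(region, self.mixture)
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"mixture for {region} sums to {total}, not 1")
        return mix


@dataclass
class GroundTruth:
    """Per-unit generative parameters of a simulated session."""

    units: pd.DataFrame
    seed: int
    config: SessionConfig


def simulate_session(config: SessionConfig | None = None,
                     seed: int = 0) -> tuple[RecordingSession, GroundTruth]:
    """Simulate a full paired-region session with labelled ground truth.

    Timeline: ``n_heat_trials`` copies of the heat trace back-to-back, a 1 s
    gap, then the deflection train, then a 1 s tail.  Each unit's spikes come
    from an independent substream keyed by (seed, unit index).
    """
    config = config or SessionConfig()
    if config.n_units_per_stratum < 1:
        raise ParameterError("n_units_per_stratum must be >= 1")

    trial = make_heat_trace(**config.heat_kwargs)
    heat_block = trial.duration * config.n_heat_trials
    tact_start = heat_block + 1.0
    tactile = make_deflection_train(
        config.n_deflections, config.deflection_interval_s,
        config.deflection_jitter_s,
        seed=np.random.default_rng([seed, 2**24]), start_s=tact_start)
    duration = float(tactile.onsets[-1] + 1.0)
    heat = repeat_heat_trace(trial, config.n_heat_trials, total_duration_s=duration)

    units: list[SpikeTrain] = []
    records = []
    labels = list(config.mixture.keys())
    idx = 0
    for region, layer in itertools.product(config.regions, config.layers):
        mix = config.mixture_for(region)
        probs = [mix[l] for l in labels]
        for _ in range(config.n_units_per_stratum):
            rng = np.random.default_rng([seed, idx])
            label = labels[rng.choice(len(labels), p=probs)]
            arch = config.archetypes[label]
            suppressed = False
            if label in ("tactile", "none"):
                p = config.suppressed_prob.get(region, 0.0)
                if p > 0 and rng.uniform() < p:
                    arch = replace(arch, suppression_factor=config.suppression_factor)
                    suppressed = True
            uid = f"u{idx:04d}"
            units.append(simulate_unit(arch, heat, tactile, duration, rng,
                                       unit_id=uid, region=region, layer=layer,
                                       kind=config.kind))
            records.append({
                "unit_id": uid, "region": region, "layer": layer, "label": label,
                "baseline_rate": arch.baseline_rate, "heat_gain": arch.heat_gain,
                "heat_threshold": arch.heat_threshold, "heat_slope": arch.heat_slope,
                "tactile_gain": arch.tactile_gain, "tactile_tau": arch.tactile_tau,
                "suppression_factor": arch.suppression_factor,
                "suppressed": suppressed,
            })
            idx += 1

    session = RecordingSession(
        units=units, heat=heat, tactile=tactile,
        metadata={"seed": seed, "n_heat_trials": config.n_heat_trials,
                  "sample_rate": heat.sample_rate},
    )
    truth = GroundTruth(units=pd.DataFrame(records), seed=seed, config=config)
    return session, truth


# ---------------------------------------------------------------------------
# imaging / behaviour generators
# ---------------------------------------------------------------------------

def make_image_stack(height: int = 100, width: int = 120, n_pre: int = 20,
                     n_post: int = 40, blob_center=(40.0, 60.0),
                     blob_sigma: float = 8.0, blob_amplitude: float = -0.01,
                     noise_sd: float = 0.001, seed=0,
                     frame_rate: float = 20.0,
                     base_level: float = 1.0) -> ImageStack:
    """Reflectance stack: flat pre-stimulus frames, then frames carrying a
    Gaussian blob of relative amplitude ``blob_amplitude`` (negative for the
    reflectance decrease of a real intrinsic signal)."""
    if n_pre < 20:
        raise ParameterError("n_pre must be >= 20 (the dR/R baseline uses 20 frames)")
    if n_post < 1:
        raise ParameterError("n_post must be >= 1")
    rng = _rng(seed)
    rr, cc = np.mgrid[0:height, 0:width]
    g = np.exp(-(((rr - blob_center[0]) ** 2 + (cc - blob_center[1]) ** 2)
                 / (2.0 * blob_sigma ** 2)))
    frames = np.empty((n_pre + n_post, height, width))
    noise = rng.normal(0.0, noise_sd, frames.shape) if noise_sd > 0 else 0.0
    frames[:n_pre] = base_level
    frames[n_pre:] = base_level * (1.0 + blob_amplitude * g)
    frames += base_level * noise
    return ImageStack(
        frames=frames, frame_rate=frame_rate, stimulus_onset_index=n_pre,
        truth={"blob_center": tuple(float(x) for x in blob_center),
               "blob_sigma": float(blob_sigma),
               "blob_amplitude": float(blob_amplitude),
               "noise_sd": float(noise_sd), "base_level": float(base_level)},
    )


def make_behavior_trace(duration_s: float = 15.0, sample_rate: float = 30.0,
                        baseline_speed: float = 1.0, escape_onset_s: float = 6.0,
                        escape_peak_speed: float = 5.0, escape_width_s: float = 0.5,
                        noise_sd: float = 0.05, seed=0,
                        stimulus_onset_s: float = 5.0,
                        channel: str = "speed") -> BehaviorTrace:
    """Treadmill-style motion trace: baseline + Gaussian escape bump + noise.

    The bump rises from ``escape_onset_s`` and peaks two widths later; the
    peak time and speed are stored as ground truth.
    """
    if not (0.0 <= escape_onset_s <= duration_s):
        raise ParameterError("escape_onset_s outside the trace")
    rng = _rng(seed)
    times = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    peak_time = escape_onset_s + 2.0 * escape_width_s
    values = baseline_speed + escape_peak_speed * np.exp(
        -((times - peak_time) ** 2) / (2.0 * escape_width_s ** 2))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, times.shape)
    return BehaviorTrace(
        times=times, values=values, stimulus_onset_s=stimulus_onset_s,
        channel=channel,
        truth={"escape_onset_s": float(escape_onset_s),
               "peak_time_s": float(peak_time),
               "peak_speed": float(escape_peak_speed),
               "baseline_speed": float(baseline_speed)},
    )


def make_bend_trace(rise_tau_s: float = 0.1, plateau_level: float = 1.0,
                    noise_sd: float = 0.0, seed=0, duration_s: float = 3.0,
                    sample_rate: float = 200.0, rise_start_s: float = 0.5,
                    shape: str = "exponential",
                    ramp_duration_s: float = 0.5) -> BendTrace:
    """Skin-bending signal under a von Frey filament, sampled at the
    high-speed-camera rate (200 Hz by default).

    ``shape='exponential'``: saturating rise ``plateau*(1-exp(-(t-t0)/tau))``
    whose derivative falls to a fraction f of its maximum at the analytic
    time ``t0 + tau*ln(1/f)`` (stored as truth for f = 0.05).
    ``shape='linear'``: linear ramp reaching the plateau at
    ``t0 + ramp_duration_s`` (stored as truth).
    """
    if duration_s < 1.0:
        raise ParameterError("trace must span at least 1 s")
    if rise_tau_s <= 0 or sample_rate <= 0:
        raise ParameterError("rise_tau_s and sample_rate must be > 0")
    rng = _rng(seed)
    times = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    u = times - rise_start_s
    if shape == "exponential":
        bend = np.where(u > 0, plateau_level * (1.0 - np.exp(-np.maximum(u, 0)
                                                             / rise_tau_s)), 0.0)
        truth = {"rise_start_s": float(rise_start_s), "tau_s": float(rise_tau_s),
                 "saturation_s": float(rise_start_s + rise_tau_s * np.log(1 / 0.05)),
                 "shape": "exponential"}
    elif shape == "linear":
        bend = plateau_level * np.clip(u / ramp_duration_s, 0.0, 1.0)
        truth = {"rise_start_s": float(rise_start_s),
                 "saturation_s": float(rise_start_s + ramp_duration_s),
                 "shape": "linear"}
    else:
        raise ParameterError(f"unknown shape {shape!r}")
    if noise_sd > 0:
        bend = bend + rng.normal(0.0, noise_sd, times.shape)
    return BendTrace(times=times, bend=bend, truth=truth)
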