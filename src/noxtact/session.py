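"""Domain types for extracellular recording sessions and their stimuli.

A session couples spike trains recorded simultaneously from the dysgranular
zone (Dys) and the barrel field (BF) of mouse S1 with the two stimulus
streams used to probe them: a Peltier temperature ramp into the noxious
range and a train of piezo-driven whisker deflections.

Conventions
-----------
* All times are seconds, double precision, on a single session clock whose
  origin is the first sample of the heat trace.  Per-trial analyses
  re-reference to stimulus onset = 0.
* Autocorrelogram bins are half-open ``[left, right)`` and centred on
  integer multiples of the bin width, so the lag-0 bin exists but the
  zero-lag self-pairs are excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

REGIONS = ("Dys", "BF")
LAYERS = ("L2/3", "L4", "L5a", "L5b")
UNIT_KINDS = ("SUA", "MUA")

#: minimum spacing between deflection onsets so that the 30 ms post-onset
#: signal window and the 60 ms pre-onset noise window never overlap a
#: neighbouring event
MIN_DEFLECTION_SPACING_S = 0.090


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one analysis unit (single- or multi-unit)."""

    unit_id: str
    region: str
    layer: str
    kind: str
    spike_times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "spike_times", _as_float_array(self.spike_times))
        if self.region not in REGIONS:
            raise ValidationError(f"unit {self.unit_id!r}: unknown region {self.region!r}")
        if self.layer not in LAYERS:
            raise ValidationError(f"unit {self.unit_id!r}: unknown layer {self.layer!r}")
        if self.kind not in UNIT_KINDS:
            raise ValidationError(f"unit {self.unit_id!r}: unknown kind {self.kind!r}")
        t = self.spike_times
        if t.size:
            if not np.all(np.isfinite(t)):
                raise ValidationError(f"unit {self.unit_id!r}: non-finite spike times")
            if t.min() < 0:
                raise ValidationError(f"unit {self.unit_id!r}: negative spike times")
            if np.any(np.diff(t) < 0):
                raise ValidationError(
                    f"unit {self.unit_id!r}: spike times are not nondecreasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class HeatTrace:
    """Uniformly sampled Peltier surface temperature (deg C) vs time (s)."""

    times: np.ndarray
    temperatures: np.ndarray
    sample_rate: float

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "temperatures", _as_float_array(self.temperatures))
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        if self.times.shape != self.temperatures.shape:
            raise ValidationError("times and temperatures must have equal length")
        T = self.temperatures
        if T.size and (T.min() < 20.0 or T.max() > 60.0):
            raise ValidationError("temperatures outside the physical range [20, 60] degC")

    def temperature_at(self, t) -> np.ndarray:
        """Linear interpolation; the generated trace is piecewise linear, so
        interpolation between samples is exact for it."""
        return np.interp(t, self.times, self.temperatures)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


@dataclass(frozen=True)
class TactileEvents:
    """Whisker-deflection onset times (s)."""

    onsets: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "onsets", _as_float_array(self.onsets))
        d = np.diff(self.onsets)
        if np.any(d <= 0):
            raise ValidationError("deflection onsets must be strictly increasing")
        # small tolerance so exactly-90 ms grids survive float round-off
        if d.size and d.min() < MIN_DEFLECTION_SPACING_S - 1e-9:
            raise ValidationError(
                f"deflection onsets closer than {MIN_DEFLECTION_SPACING_S*1e3:.0f} ms "
                "would overlap the S/N windows of neighbouring events"
            )

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)


@dataclass
class RecordingSession:
    """Simultaneously recorded units plus the stimulus streams of one session."""

    units: list[SpikeTrain]
    heat: HeatTrace
    tactile: TactileEvents
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValidationError("unit_ids must be unique within a session")

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass(frozen=True)
class Autocorrelogram:
    """Histogram of spike-pair lag differences, symmetric about zero lag."""

    lags: np.ndarray      # bin centres, ms
    counts: np.ndarray    # nonnegative integers
    bin_width: float      # ms

    def __post_init__(self):
        object.__setattr__(self, "lags", _as_float_array(self.lags))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if np.any(self.counts < 0):
            raise ValidationError("autocorrelogram counts must be nonnegative")
        if not np.allclose(self.lags, -self.lags[::-1]):
            raise ValidationError("lag axis must be symmetric about 0")


# ---------------------------------------------------------------------------
# session I/O (spikes.csv / heat.csv / events.csv / session.json)
# ---------------------------------------------------------------------------

_SPIKES_COLUMNS = ("unit_id", "region", "layer", "kind", "spike_time_s")
_HEAT_COLUMNS = ("time_s", "temp_c")
_EVENTS_COLUMNS = ("onset_s",)


def _read_table(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing session file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path.name, extra)
    return df


def read_session(path, dialect: dict | None = None) -> RecordingSession:
    """Read a session directory (``spikes.csv``, ``heat.csv``, ``events.csv``,
    optional ``session.json``) written by :func:`write_session`.

    ``dialect`` may override the heat-trace sample rate key (``sample_rate``);
    by default it is inferred from the time axis.
    """
    path = Path(path)
    dialect = dialect or {}

    spikes = _read_table(path / "spikes.csv", _SPIKES_COLUMNS)
    heat = _read_table(path / "heat.csv", _HEAT_COLUMNS)
    events = _read_table(path / "events.csv", _EVENTS_COLUMNS)

    meta_path = path / "session.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    times = heat["time_s"].to_numpy(dtype=float)
    if "sample_rate" in dialect:
        sr = float(dialect["sample_rate"])
    elif "sample_rate" in metadata:
        sr = float(metadata["sample_rate"])
    elif times.size >= 2:
        sr = 1.0 / float(np.median(np.diff(times)))
    else:
        raise FormatError("heat.csv too short to infer sample_rate")

    units: list[SpikeTrain] = []
    if len(spikes):
        for unit_id, grp in spikes.groupby("unit_id", sort=True):
            units.append(
                SpikeTrain(
                    unit_id=str(unit_id),
                    region=str(grp["region"].iloc[0]),
                    layer=str(grp["layer"].iloc[0]),
                    kind=str(grp["kind"].iloc[0]),
                    spike_times=grp["spike_time_s"].to_numpy(dtype=float),
                )
            )

    return RecordingSession(
        units=units,
        heat=HeatTrace(times=times, temperatures=heat["temp_c"].to_numpy(dtype=float),
                       sample_rate=sr),
        tactile=TactileEvents(onsets=events["onset_s"].to_numpy(dtype=float)),
        metadata=metadata,
    )


def write_session(session: RecordingSession, path) -> None:
    """Write a session as the CSV/JSON layout read by :func:`read_session`.

    Floats are serialized with ``repr`` round-trip precision so that
    read(write(s)) reproduces ``s`` exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for u in session.units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.region, u.layer, u.kind, t))
    spikes = pd.DataFrame(rows, columns=list(_SPIKES_COLUMNS))
    spikes.to_csv(path / "spikes.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        {"time_s": session.heat.times, "temp_c": session.heat.temperatures}
    ).to_csv(path / "heat.csv", index=False, float_format="%.17g")
    pd.DataFrame({"onset_s": session.tactile.onsets}).to_csv(
        path / "events.csv", index=False, float_format="%.17g"
    )

    meta = dict(session.metadata)
    meta.setdefault("sample_rate", session.heat.sample_rate)
    (path / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# autocorrelogram / refractory-period QC
# ---------------------------------------------------------------------------

def autocorrelogram(train: SpikeTrain, bin_width: float = 1.0,
                    max_lag: float = 50.0) -> Autocorrelogram:
    """Spike-train autocorrelogram over lags in ``(-max_lag, max_lag)`` ms.

    Zero-lag self-pairs are excluded.  Bins are centred on multiples of
    ``bin_width`` so the histogram is exactly symmetric: positive lags are
    binned and mirrored, and sub-half-bin lags land in the centre bin from
    both signs.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if max_lag < bin_width:
        raise ParameterError("max_lag must be >= bin_width")

    n_pos = int(np.ceil((max_lag - bin_width / 2.0) / bin_width))
    centers = np.arange(-n_pos, n_pos + 1) * bin_width
    counts = np.zeros(centers.size, dtype=np.int64)

    t_ms = train.spike_times * 1e3
    if t_ms.size >= 2:
        pos = []
        for i in range(t_ms.size - 1):
            d = t_ms[i + 1:] - t_ms[i]
            d = d[(d > 0) & (d < max_lag)]
            if d.size:
                pos.append(d)
        if pos:
            d = np.concatenate(pos)
            idx = np.floor(d / bin_width + 0.5).astype(int)  # nearest centre
            idx = idx[idx <= n_pos]
            h = np.bincount(idx, minlength=n_pos + 1)
            counts[n_pos] = 2 * h[0]              # lags in (0, bw/2), both signs
            counts[n_pos + 1:] = h[1:]
            counts[:n_pos] = h[1:][::-1]
    return Autocorrelogram(lags=centers, counts=counts, bin_width=float(bin_width))


def refractory_violation_fraction(acg: Autocorrelogram,
                                  refractory_ms: float = 2.0) -> float:
    """Fraction of autocorrelogram mass at lags within the refractory period.

    Clean single units show a clear gap (>2 ms) around zero lag; multi-unit
    clusters do not.  Returns 0 for an empty histogram.
    """
    if refractory_ms <= 0:
        raise ParameterError("refractory_ms must be > 0")
    total = int(acg.counts.sum())
    if total == 0:
        return 0.0
    inside = acg.counts[np.abs(acg.lags) <= refractory_ms + 1e-12].sum()
    return float(inside) / float(total)
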