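"""End-to-end orchestration: simulate -> metrics -> classify -> imaging ->
behavior -> stats under a single seeded config, with a reproducible manifest.

Every stochastic stage derives its stream from the one config seed, so two
runs of the same config produce byte-identical output tables (verified via
sha256 digests in the run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import escape_metrics, vonfrey_onset
from .ephys import (
    STUDY_CUTOFFS,
    classification_summary,
    compute_cutoffs,
    suppressed_fraction,
    unit_metrics_table,
)
from .errors import NoxtactError, ParameterError
from .imaging import active_region, compute_drr, write_stack, zscore_map
from .session import write_session
from .stats import ansari_bradley, chi_square_2x2, results_table
from .synth import (
    SessionConfig,
    make_behavior_trace,
    make_bend_trace,
    make_image_stack,
    simulate_session,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    epsilon_hz: float = 0.1
    cutoff_source: str = "study_default"    # or "recompute"
    smoothing_sigma_s: float = 0.1
    noise_mode: str = "innoxious_ramp"

    def __post_init__(self):
        if self.epsilon_hz < 0:
            raise ParameterError("epsilon_hz must be >= 0")
        if self.cutoff_source not in ("study_default", "recompute"):
            raise ParameterError(f"unknown cutoff_source {self.cutoff_source!r}")
        if self.noise_mode not in ("innoxious_ramp", "steady_state"):
            raise ParameterError(f"unknown noise_mode {self.noise_mode!r}")


@dataclass
class ImagingParams:
    height: int = 100
    width: int = 120
    n_pre: int = 20
    n_post: int = 40
    blob_center: tuple = (40.0, 60.0)
    blob_sigma: float = 8.0
    blob_amplitude: float = -0.01
    noise_sd: float = 0.001
    z_threshold: float = 2.0
    min_area_px: int = 10


@dataclass
class BehaviorParams:
    duration_s: float = 15.0
    sample_rate: float = 30.0
    baseline_speed: float = 1.0
    escape_onset_s: float = 6.0
    escape_peak_speed: float = 5.0
    escape_width_s: float = 0.5
    noise_sd: float = 0.05
    stimulus_onset_s: float = 5.0
    bend_tau_s: float = 0.2
    bend_noise_sd: float = 0.0


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "out"
    generator: SessionConfig = field(default_factory=SessionConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)


@dataclass
class RunReport:
    out_dir: str
    digests: dict
    class_summary: pd.DataFrame
    tests: pd.DataFrame
    cutoffs: tuple
    agreement: float | None
    version: str = __version__


def _build_section(cls, data: dict, name: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) in {name!r} section: {sorted(unknown)}")
    if name == "generator" and "archetypes" in data:
        from .synth import UnitArchetype
        data = dict(data)
        data["archetypes"] = {k: (v if not isinstance(v, dict)
                                  else UnitArchetype(**v))
                              for k, v in data["archetypes"].items()}
    return cls(**data)


def validate_config(path) -> PipelineConfig:
    """Parse and schema-check a YAML pipeline config; unknown keys are
    rejected by name, defaults fill the rest."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config must be a mapping")
    top_allowed = {"seed", "out_dir", "generator", "analysis", "imaging", "behavior"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ParameterError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "out")),
        generator=_build_section(SessionConfig, raw.get("generator", {}), "generator"),
        analysis=_build_section(AnalysisParams, raw.get("analysis", {}), "analysis"),
        imaging=_build_section(ImagingParams, raw.get("imaging", {}), "imaging"),
        behavior=_build_section(BehaviorParams, raw.get("behavior", {}), "behavior"),
    )
    logger.info("config validated: seed=%d out_dir=%s", cfg.seed, cfg.out_dir)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write the per-stage outputs plus a manifest.

    Outputs (under ``out_dir``): session tables + ground truth, per-unit
    metrics and the region x layer x class summary, dispersion/suppression
    test results, the imaging z-map and activated-region centroid, and the
    behaviour metrics.
    """
    out = Path(config.out_dir)
    stage = "simulate"
    try:
        logger.info("[simulate] seed=%d", config.seed)
        session, truth = simulate_session(config.generator, seed=config.seed)
        write_session(session, out / "session")
        _write_csv(truth.units, out / "session" / "ground_truth.csv")

        stage = "metrics"
        logger.info("[metrics] %d units", len(session.units))
        a = config.analysis
        metrics = unit_metrics_table(
            session, cutoffs=STUDY_CUTOFFS, epsilon=a.epsilon_hz,
            noise_mode=a.noise_mode, smoothing_sigma_s=a.smoothing_sigma_s)
        if a.cutoff_source == "recompute":
            cutoffs = compute_cutoffs(metrics["sn_nox"], metrics["sn_tact"])
            metrics = unit_metrics_table(
                session, cutoffs=cutoffs, epsilon=a.epsilon_hz,
                noise_mode=a.noise_mode, smoothing_sigma_s=a.smoothing_sigma_s)
        else:
            cutoffs = STUDY_CUTOFFS
        _write_csv(metrics, out / "metrics" / "unit_metrics.csv")

        stage = "classify"
        summary = classification_summary(metrics)
        _write_csv(summary, out / "metrics" / "class_summary.csv")
        merged = metrics.merge(truth.units[["unit_id", "label"]], on="unit_id")
        agreement = float((merged["class"] == merged["label"]).mean())
        logger.info("[classify] ground-truth agreement %.1f%%", 100 * agreement)

        stage = "stats"
        results = []
        for layer in sorted(metrics["layer"].unique()):
            sub = metrics[metrics["layer"] == layer]
            thr_d = sub.loc[(sub.region == "Dys") & sub.threshold_c.notna(),
                            "threshold_c"]
            thr_b = sub.loc[(sub.region == "BF") & sub.threshold_c.notna(),
                            "threshold_c"]
            if len(thr_d) >= 2 and len(thr_b) >= 2:
                r = ansari_bradley(thr_d, thr_b)
                results.append((f"threshold_dispersion_{layer}", r))
        supp = metrics.groupby("region")["suppressed"].agg(["sum", "count"])
        if set(supp.index) == {"BF", "Dys"}:
            table = [[int(supp.loc["BF", "sum"]),
                      int(supp.loc["BF", "count"] - supp.loc["BF", "sum"])],
                     [int(supp.loc["Dys", "sum"]),
                      int(supp.loc["Dys", "count"] - supp.loc["Dys", "sum"])]]
            results.append(("suppressed_BF_vs_Dys", chi_square_2x2(table)))
        tests = results_table([r for _, r in results])
        tests.insert(0, "comparison", [name for name, _ in results])
        _write_csv(tests, out / "stats" / "tests.csv")

        stage = "imaging"
        im = config.imaging
        stack = make_image_stack(
            height=im.height, width=im.width, n_pre=im.n_pre, n_post=im.n_post,
            blob_center=tuple(im.blob_center), blob_sigma=im.blob_sigma,
            blob_amplitude=im.blob_amplitude, noise_sd=im.noise_sd,
            seed=np.random.default_rng([config.seed, 1]))
        (out / "imaging").mkdir(parents=True, exist_ok=True)
        zmap = zscore_map(compute_drr(stack))
        write_stack(stack, out / "imaging" / "stack.tif")
        import tifffile
        tifffile.imwrite(out / "imaging" / "zmap.tif",
                         zmap.values.astype(np.float32))
        region = active_region(zmap, im.z_threshold, im.min_area_px)
        _write_csv(pd.DataFrame([{
            "centroid_row": np.nan if region.empty else region.centroid[0],
            "centroid_col": np.nan if region.empty else region.centroid[1],
            "area_px": region.area,
            "truth_row": stack.truth["blob_center"][0],
            "truth_col": stack.truth["blob_center"][1],
        }]), out / "imaging" / "active_region.csv")

        stage = "behavior"
        be = config.behavior
        btrace = make_behavior_trace(
            duration_s=be.duration_s, sample_rate=be.sample_rate,
            baseline_speed=be.baseline_speed, escape_onset_s=be.escape_onset_s,
            escape_peak_speed=be.escape_peak_speed,
            escape_width_s=be.escape_width_s, noise_sd=be.noise_sd,
            seed=np.random.default_rng([config.seed, 2]),
            stimulus_onset_s=be.stimulus_onset_s)
        esc = escape_metrics(btrace)
        bend = make_bend_trace(rise_tau_s=be.bend_tau_s,
                               noise_sd=be.bend_noise_sd,
                               seed=np.random.default_rng([config.seed, 3]))
        onset = vonfrey_onset(bend)
        _write_csv(pd.DataFrame([{
            "channel": btrace.channel, "max_z": esc.max_z,
            "time_of_max_s": esc.time_of_max_s,
            "vonfrey_onset_s": onset,
            "vonfrey_truth_s": bend.truth["saturation_s"],
        }]), out / "behavior" / "metrics.csv")
    except NoxtactError as e:
        raise NoxtactError(f"pipeline stage {stage!r} failed: {e}") from e

    digests = {str(p.relative_to(out)): _sha256(p)
               for p in sorted(out.rglob("*")) if p.is_file() and p.name != "manifest.json"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "cutoffs": list(cutoffs),
        "ground_truth_agreement": agreement,
        "suppressed_fraction": {
            reg: float(suppressed_fraction(
                metrics.loc[metrics.region == reg, "sn_nox"]))
            for reg in sorted(metrics["region"].unique())},
        "digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(out_dir=str(out), digests=digests, class_summary=summary,
                     tests=tests, cutoffs=tuple(cutoffs), agreement=agreement)


def config_to_yaml(config: PipelineConfig) -> str:
    """Serialize a config (e.g. to echo defaults into a run log)."""
    d = json.loads(json.dumps(asdict(config)))   # tuples -> lists for safe YAML
    return yaml.safe_dump(d, sort_keys=False)
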