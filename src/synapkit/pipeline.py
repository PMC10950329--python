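"""End-to-end experiment driver: conditions -> traces -> tau -> statistics.

A condition is either simulated (trace-level, or fully rendered videos put
through bouton detection) or loaded from disk.  Per video, the traces of
all responding boutons are averaged into one video trace, corrected,
peak-normalized and fitted; the per-video decay constants feed the
between-condition statistics, and the condition-averaged trace yields the
condition tau, mirroring the reporting convention of the assay (N =
videos, each averaging >= 20 boutons).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .decay import DecayFitResults, fit_decay
from .detection import (DetectionParams, background_region_mask,
                        detect_responding_boutons, measure_roi_traces)
from .kinetics import (AveragedTrace, FluorescenceTrace, Indicator,
                       NormalizedTrace, average_traces, bleach_correct,
                       peak_normalize)
from .protocols import StimulationProtocol
from .simulate import SimulationConfig, TimeLapseVideo, draw_amplitudes, simulate_trace, simulate_video
from .stats import StatResult, compare_groups, normality_gate

logger = logging.getLogger("synapkit")

__all__ = ["ConditionSpec", "AnalysisOptions", "ExperimentConfig",
           "ConditionResult", "RunReport", "run_pipeline",
           "analyze_video_traces", "run_condition"]


@dataclass
class AnalysisOptions:
    indicator: Indicator = Indicator.PHLUORIN
    bleach_method: str = "ratio"
    detection: DetectionParams = field(default_factory=DetectionParams)
    per_bouton_averaging: bool = False  # opt-in: average boutons, not videos

    def __post_init__(self) -> None:
        self.indicator = Indicator.coerce(self.indicator)


@dataclass
class ConditionSpec:
    label: str
    sim: SimulationConfig | None = None
    video_paths: list[str] = field(default_factory=list)
    n_videos: int = 8
    n_boutons: int = 30
    control: bool = False


@dataclass
class ExperimentConfig:
    conditions: list[ConditionSpec]
    protocol: StimulationProtocol
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    mode: str = "traces"          # "traces" | "video"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if sum(c.control for c in self.conditions) > 1:
            raise ValueError("at most one condition may be the control")
        if self.mode not in ("traces", "video"):
            raise ValueError("mode must be 'traces' or 'video'")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["analysis"]["indicator"] = self.analysis.indicator.value
        for c in d["conditions"]:
            if c["sim"] is not None:
                c["sim"]["indicator"] = c["sim"]["indicator"].value
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        conds = []
        for c in d["conditions"]:
            sim = c.get("sim")
            conds.append(ConditionSpec(
                label=c["label"],
                sim=SimulationConfig(**sim) if sim else None,
                video_paths=list(c.get("video_paths", [])),
                n_videos=int(c.get("n_videos", 8)),
                n_boutons=int(c.get("n_boutons", 30)),
                control=bool(c.get("control", False))))
        ana = d.get("analysis", {})
        det = DetectionParams(**ana.pop("detection", {})) if isinstance(
            ana.get("detection", {}), dict) else DetectionParams()
        ana = {k: v for k, v in ana.items() if k != "detection"}
        return cls(conditions=conds,
                   protocol=StimulationProtocol(**d["protocol"]),
                   analysis=AnalysisOptions(detection=det, **ana),
                   mode=d.get("mode", "traces"), seed=int(d.get("seed", 0)),
                   output_dir=d.get("output_dir"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ConditionResult:
    label: str
    tau: float | None              # fit of the condition-averaged trace
    tau_stderr: float | None
    rss: float | None
    video_taus: list[float]
    n_videos: int
    excluded_videos: list[dict[str, str]]
    excluded: bool = False
    exclusion_reason: str = ""

    def tau_sem(self) -> float | None:
        if len(self.video_taus) < 2:
            return None
        v = np.asarray(self.video_taus)
        return float(v.std(ddof=1) / np.sqrt(len(v)))


@dataclass
class RunReport:
    conditions: list[ConditionResult]
    stats: dict[str, Any]
    seed: int
    config_hash: str
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "conditions": [dataclasses.asdict(c) for c in self.conditions],
            "stats": self.stats,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# per-video analysis
# ---------------------------------------------------------------------------

def analyze_video_traces(traces: list[FluorescenceTrace],
                         options: AnalysisOptions,
                         ) -> tuple[NormalizedTrace, list[NormalizedTrace]]:
    """One video: bouton traces -> corrected, peak-normalized video trace.

    Raw bouton traces are averaged per time point first (the video is the
    averaging unit), then background/bleach-corrected and normalized.
    Per-bouton normalized traces are also returned for the opt-in
    per-bouton averaging mode.
    """
    if not traces:
        raise ValueError("no traces for this video")
    first = traces[0]
    stack = np.vstack([tr.corrected() for tr in traces])
    video_trace = FluorescenceTrace(
        time=first.time, raw_intensity=stack.mean(axis=0),
        indicator=first.indicator, protocol=first.protocol,
        background=0.0, roi_id="video_mean")
    if first.indicator is Indicator.CYPHER:
        video_trace, _ = bleach_correct(video_trace,
                                        method=options.bleach_method)
    norm = peak_normalize(video_trace)
    per_bouton = []
    if options.per_bouton_averaging:
        for tr in traces:
            t = tr
            if t.indicator is Indicator.CYPHER:
                t, _ = bleach_correct(t, method=options.bleach_method)
            per_bouton.append(peak_normalize(t))
    return norm, per_bouton


def _simulate_video_traces(spec: ConditionSpec,
                           protocol: StimulationProtocol,
                           rng: np.random.Generator
                           ) -> list[FluorescenceTrace]:
    """Trace-level simulation of one video's responding boutons."""
    amps = draw_amplitudes(spec.sim, spec.n_boutons, rng)
    return [simulate_trace(spec.sim, protocol, amplitude=a, rng=rng,
                           roi_id=f"sim{i:03d}")
            for i, a in enumerate(amps)]


def run_condition(spec: ConditionSpec,
                  config: ExperimentConfig,
                  rng: np.random.Generator) -> ConditionResult:
    """Analyze one condition end to end; stage errors become exclusions."""
    options = config.analysis
    protocol = config.protocol
    video_norms: list[NormalizedTrace] = []
    excluded: list[dict[str, str]] = []

    for v in range(spec.n_videos):
        vid_id = f"{spec.label}/video{v:02d}"
        try:
            if config.mode == "traces":
                traces = _simulate_video_traces(spec, protocol, rng)
            else:
                seed = int(rng.integers(0, 2**31 - 1))
                sim = dataclasses.replace(spec.sim, seed=seed)
                video, _truth = simulate_video(
                    sim, protocol, n_boutons=spec.n_boutons)
                det = detect_responding_boutons(
                    video, protocol, options.indicator,
                    params=options.detection)
                if det.excluded:
                    excluded.append({"video": vid_id, "reason":
                                     f"below_responder_floor: "
                                     f"{det.exclusion_reason}"})
                    continue
                bg = background_region_mask(video, det)
                traces = measure_roi_traces(video, det, bg,
                                            options.indicator, protocol)
            norm, _ = analyze_video_traces(traces, options)
            video_norms.append(norm)
        except Exception as exc:  # recorded, run continues
            logger.warning("%s failed: %s", vid_id, exc)
            excluded.append({"video": vid_id, "reason": f"stage_error: {exc}"})

    logger.info("condition %s: %d/%d videos analyzed",
                spec.label, len(video_norms), spec.n_videos)
    if not video_norms:
        return ConditionResult(label=spec.label, tau=None, tau_stderr=None,
                               rss=None, video_taus=[], n_videos=0,
                               excluded_videos=excluded, excluded=True,
                               exclusion_reason="no analyzable videos")
    video_taus = [fit_decay(n).tau for n in video_norms]
    avg = average_traces(video_norms)
    fit = fit_decay(avg)
    return ConditionResult(label=spec.label, tau=fit.tau,
                           tau_stderr=fit.tau_stderr, rss=fit.rss,
                           video_taus=video_taus, n_videos=len(video_norms),
                           excluded_videos=excluded)


def run_pipeline(config: ExperimentConfig) -> RunReport:
    """Run every condition, compare their per-video taus, write the report.

    All randomness flows from one seeded generator per condition, spawned
    deterministically from ``config.seed``; rerunning an identical config
    reproduces the report byte for byte.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.conditions))
    results = [run_condition(spec, config, np.random.default_rng(child))
               for spec, child in zip(config.conditions, children)]

    stats: dict[str, Any] = {}
    usable = {r.label: r.video_taus for r in results
              if not r.excluded and len(r.video_taus) >= 2}
    if len(usable) >= 2:
        plan = normality_gate(usable, n_experiments=max(
            len(v) for v in usable.values()))
        try:
            res = compare_groups(usable, plan)
            stats = {
                "test": res.test.value, "statistic": res.statistic,
                "p_value": res.p_value, "branch": plan.branch.value,
                "gate_applied": plan.gate_applied,
                "groups": res.group_labels, "n_per_group": res.n_per_group,
            }
            if res.posthoc is not None:
                stats["posthoc"] = res.posthoc.to_dict(orient="records")
        except ValueError as exc:
            stats = {"error": str(exc)}
    else:
        stats = {"error": "fewer than two analyzable conditions"}

    report = RunReport(conditions=results, stats=stats, seed=config.seed,
                       config_hash=config.config_hash())
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
    return report
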