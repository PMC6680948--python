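"""End-to-end batch pipeline: simulate -> extract -> train -> advise -> evaluate.

A single ``RunConfig`` drives every stage; each stage's output can be
persisted so the pipeline is resumable from intermediates.  Evaluation uses
the pooled out-of-fold (block-wise cross-validated) likelihood series, and
the advisory state in effect during an epoch is computed from the
*preceding* epoch's features (one-epoch latency, as a causal real-time
device would), so an onset can only be credited to a warning raised before
the data containing it were processed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import advisory as adv
from . import features as fb
from . import metrics as mx
from . import synth
from . import train as tr

log = logging.getLogger("seizure_advisory")


@dataclass(frozen=True)
class RunConfig:
    simulation: synth.SimulationConfig
    epoch_length: float = 13.8
    bands: tuple[fb.FilterSpec, ...] | None = None   # None -> scaled to fs
    horizon: float = tr.DEFAULT_HORIZON
    postictal_exclusion: float = tr.DEFAULT_POSTICTAL_EXCLUSION
    k_folds: int = 10
    max_selected: int = tr.MAX_SELECTED
    tolerance: float = tr.DEFAULT_TOLERANCE
    shrinkage: float = tr.DEFAULT_SHRINKAGE
    red_target: float = 0.25
    blue_target: float = 0.45
    min_dwell: int = 1
    red_hold_epochs: int | None = None   # None -> one horizon of epochs
    evaluation_latency_epochs: int = 1
    aed_screen: bool = True
    aed_screen_threshold: float | None = None
    criteria: mx.ValidationCriteria = field(default_factory=mx.ValidationCriteria)

    @classmethod
    def desk_scale(cls, seed: int = 0, effect_size: float = 2.0,
                   **kw) -> "RunConfig":
        """Desk-scale Monte-Carlo preset (see SimulationConfig.desk_scale)."""
        sim = synth.SimulationConfig.desk_scale(seed=seed,
                                                effect_size=effect_size)
        return cls(simulation=sim, epoch_length=240.0, max_selected=8, **kw)

    def red_hold(self) -> int:
        """Warning persistence in epochs (defaults to one pre-ictal horizon).

        A raised warning is a claim that a seizure is likely within the
        horizon, so it stays active for that long after the last
        supra-threshold epoch.
        """
        if self.red_hold_epochs is not None:
            return self.red_hold_epochs
        return int(np.ceil(self.horizon / self.epoch_length))

    def filters(self) -> tuple[fb.FilterSpec, ...]:
        if self.bands is not None:
            return self.bands
        return fb.scaled_filters(self.simulation.sampling_rate)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"] = json.loads(self.simulation.to_json())
        d["criteria"] = dataclasses.asdict(self.criteria)
        if self.bands is not None:
            d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["simulation"] = synth.SimulationConfig.from_json(
            json.dumps(d["simulation"]))
        d["criteria"] = mx.ValidationCriteria(**d.get("criteria", {}))
        if d.get("bands") is not None:
            d["bands"] = tuple(fb.FilterSpec(**b) for b in d["bands"])
        return cls(**d)


@dataclass
class PipelineResult:
    record: synth.SyntheticRecord
    matrix: fb.FeatureMatrix
    retained_ids: np.ndarray
    algorithm: tr.PatientAlgorithm
    oof_likelihood: np.ndarray
    timeline: adv.AdvisoryTimeline
    report: dict


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise StageError(name, e) from e
        return inner
    return wrap


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def build_timeline(likelihood: np.ndarray, epoch_starts: np.ndarray,
                   epoch_length: float, algorithm: tr.PatientAlgorithm,
                   min_dwell: int = 1, latency_epochs: int = 1
                   ) -> adv.AdvisoryTimeline:
    """Advisory timeline from a likelihood series with causal latency.

    The state over epoch ``i`` is derived from ``likelihood[i - latency]``;
    the first ``latency`` epochs get a neutral (white) likelihood.
    """
    lik = np.asarray(likelihood, dtype=float)
    if latency_epochs > 0:
        neutral = 0.5 * (algorithm.theta_high + algorithm.theta_low)
        lik = np.concatenate([np.full(latency_epochs, neutral),
                              lik[:-latency_epochs]])
    return adv.advisory_from_likelihood(lik, epoch_starts, epoch_length,
                                        algorithm.theta_high,
                                        algorithm.theta_low, min_dwell,
                                        red_hold=algorithm.red_hold)


def run_pipeline(config: RunConfig, outdir: Path | str | None = None
                 ) -> PipelineResult:
    """Execute every stage; persist artifacts when ``outdir`` is given."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(config.to_json())

    record = _stage("simulate")(synth.simulate_record)(config.simulation)
    log.info("simulate: %d events over %.1f d", len(record.true_events),
             record.duration / 86400)
    if out is not None:
        synth.write_edf(out / "signals.edf", record.signals,
                        record.sampling_rate)
        synth.write_events_csv(out / "events.csv", record.true_events)
        synth.write_diary_csv(out / "diary.csv", record.diary)
        (out / "sim_config.json").write_text(config.simulation.to_json())
        for p in ("signals.edf", "events.csv", "diary.csv",
                  "sim_config.json"):
            log.info("wrote %s", out / p)

    grid = fb.EpochGrid(epoch_length=config.epoch_length)
    catalog = fb.enumerate_features(config.simulation.n_channels,
                                    config.filters())
    matrix = _stage("extract")(fb.extract_features)(
        record.signals, record.sampling_rate, catalog, grid)
    log.info("extract: %d epochs x %d features", matrix.n_epochs, len(catalog))
    if out is not None:
        matrix.to_csv(out / "features.csv")
        (out / "catalog.json").write_text(catalog.to_json())

    if config.aed_screen:
        levels = synth.aed_level_at(config.simulation, matrix.epoch_starts)
        retained, excluded = _stage("screen")(fb.aed_stability_screen)(
            matrix, levels, threshold=config.aed_screen_threshold)
        log.info("screen: excluded %d AED-sensitive features", len(excluded))
    else:
        retained = np.array([e.id for e in catalog.entries])

    dataset = _stage("train")(tr.make_dataset)(
        matrix, record.true_events, config.horizon,
        config.postictal_exclusion, feature_ids=retained)
    algorithm, oof = _stage("train")(tr.develop_algorithm)(
        dataset, k_folds=config.k_folds, max_size=config.max_selected,
        tolerance=config.tolerance, shrinkage=config.shrinkage,
        red_target=config.red_target, blue_target=config.blue_target,
        red_hold=config.red_hold())
    log.info("train: selected %s", algorithm.selection.feature_ids)
    if out is not None:
        (out / "algorithm.json").write_text(algorithm.to_json())
        (out / "training_log.txt").write_text(
            "\n".join(algorithm.selection.log) + "\n")

    timeline = _stage("advise")(build_timeline)(
        oof, matrix.epoch_starts, matrix.epoch_length, algorithm,
        config.min_dwell, config.evaluation_latency_epochs)
    if out is not None:
        timeline.to_csv(out / "timeline.csv")

    t0, t1 = timeline.span
    ev = record.true_events
    ev = ev[(ev >= t0) & (ev < t1)]
    report = _stage("evaluate")(mx.performance_report)(
        ev, timeline, config.criteria)
    report["seed"] = config.simulation.seed
    if out is not None:
        (out / "evaluation.json").write_text(mx.report_to_json(report))
    return PipelineResult(record=record, matrix=matrix, retained_ids=retained,
                          algorithm=algorithm, oof_likelihood=oof,
                          timeline=timeline, report=report)
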