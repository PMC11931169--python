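"""End-to-end pipeline: simulate -> detect -> train -> score -> curate -> evaluate.

One :class:`PipelineConfig` holds every stage's parameters with the package
defaults; a single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so each stage is independently reproducible.
Every run writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import aemodel, curation, io, metrics, preprocess, synthgen

log = logging.getLogger("aecurate")

_STAGES = ("simulate", "detect", "train", "score", "curate", "evaluate")


@dataclass
class PipelineConfig:
    # simulation
    n_channels: int = 4
    duration: float = 30.0
    sampling_rate: float = 30000.0
    noise_sigma: float = 10.0
    firing_rate: float = 5.0
    n_cells: int = 8
    refractory: float = 0.0025
    type1_fraction: float = 0.10
    type2_fraction: float = 0.10
    # preprocessing / detection
    band_low: float = 300.0
    band_high: float = 6000.0
    target_sigma: float = 10.0
    k_sigma: float = 5.0
    dead_time_ms: float = 1.0
    # model / training
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_train_segments: int = 12000
    # curation / metrics
    msle_threshold: float = 1.5
    neural_cut: float = 0.95
    nonneural_cut: float = 0.50
    isi_window_ms: float = 1.5
    isi_mode: str = "pairwise"
    match_tol_ms: float = 1.0
    # reproducibility
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return int(children[_STAGES.index(stage)].generate_state(1)[0] % (2 ** 31))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and leave a self-describing artifact directory.

    Returns the evaluation summary (also written to ``metrics.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    cfg = config

    log.info("simulate: %d channels, %.0f s", cfg.n_channels, cfg.duration)
    sim = synthgen.SimConfig(
        n_channels=cfg.n_channels, duration=cfg.duration, sampling_rate=cfg.sampling_rate,
        noise_sigma=cfg.noise_sigma, firing_rate=cfg.firing_rate, n_cells=cfg.n_cells,
        refractory=cfg.refractory, type1_fraction=cfg.type1_fraction,
        type2_fraction=cfg.type2_fraction, seed=cfg.stage_seed("simulate"))
    rec = synthgen.assemble_recording(sim)
    io.write_recording(out / "recording.bin", rec)
    io.write_ground_truth(out / "ground_truth.csv", rec)

    log.info("detect")
    buf = preprocess.RecordingBuffer(rec.samples, rec.sampling_rate)
    buf = preprocess.bandpass(buf, cfg.band_low, cfg.band_high)
    buf = preprocess.common_median_reference(buf)
    buf = preprocess.normalize(buf, cfg.target_sigma)
    events = preprocess.detect_events(buf, cfg.k_sigma, cfg.dead_time_ms)
    io.write_events_csv(out / "events.csv", events, buf.sampling_rate)
    segments = [fv for fv in (preprocess.extract_segment(buf, e) for e in events)
                if fv is not None]

    log.info("train: %d segments, %d epochs", cfg.n_train_segments, cfg.epochs)
    train_seed = cfg.stage_seed("train")
    X = training_segments(cfg, train_seed)
    n_val = max(1, len(X) // 10)
    model = aemodel.init_model(seed=train_seed)
    model.target_sigma = cfg.target_sigma
    model.threshold = cfg.msle_threshold
    model, report = aemodel.train(model, X[n_val:], X[:n_val], epochs=cfg.epochs,
                                  learning_rate=cfg.learning_rate,
                                  batch_size=cfg.batch_size, seed=train_seed)
    aemodel.save_model(model, out / "model.h5")
    (out / "training.json").write_text(json.dumps({
        "initial_val_loss": report.initial_val_loss, "val_loss": report.val_loss,
        "train_loss": report.train_loss, "converged": report.converged,
        "seed": train_seed}, indent=1))

    log.info("score: %d events", len(segments))
    scores = aemodel.score_batch(model, segments) if segments else np.empty(0)
    decisions = [aemodel.classify_event(s, cfg.msle_threshold) for s in scores]
    io.write_scores(out / "scores.csv", scores, decisions)

    log.info("curate")
    kept_idx = [i for i, s in enumerate(scores) if s <= cfg.msle_threshold]
    units = _events_to_units(rec, events, segments, buf.sampling_rate)
    curated, cur_report = curation.curate_sorting(
        units, model, cfg.msle_threshold, cfg.neural_cut, cfg.nonneural_cut)
    io.write_sorting(out / "sorting_curated.csv", curated)
    io.write_sorting(out / "sorting_original.csv", units)

    log.info("evaluate")
    match_before = metrics.match_events(rec.true_units, units, cfg.match_tol_ms)
    match_after = metrics.match_events(rec.true_units, curated, cfg.match_tol_ms)
    summary = {
        "n_detected_events": len(events),
        "n_kept_events": len(kept_idx),
        "n_units": len(units),
        "n_units_after_curation": len(curated),
        "sensitivity_before": _safe_sensitivity(match_before),
        "sensitivity_after": _safe_sensitivity(match_after),
        "isi_violation_rates": {
            u.unit_id: metrics.isi_violation_rate(u.event_times,
                                                  cfg.isi_window_ms * 1e-3, cfg.isi_mode)
            for u in curated},
        "unit_classes": {uid: uc.kind.value for uid, uc in cur_report.unit_classes.items()},
        "train_converged": report.converged,
        "seed": cfg.seed,
    }
    (out / "metrics.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def training_segments(cfg: PipelineConfig, seed: int) -> np.ndarray:
    """Clean spike segments for training, extracted from a dedicated
    simulated recording that passes the *same* preprocessing chain as the
    data to be scored.  Segments are cut at ground-truth spike times (the
    training set contains neural spikes only), peak-aligned by the standard
    extraction."""
    n_cells = 20  # diverse template bank for training
    duration = max(10.0, cfg.n_train_segments / (n_cells * cfg.firing_rate))
    sim = synthgen.SimConfig(
        n_channels=cfg.n_channels, duration=duration, sampling_rate=cfg.sampling_rate,
        noise_sigma=cfg.noise_sigma, firing_rate=cfg.firing_rate, n_cells=n_cells,
        refractory=cfg.refractory, type1_fraction=0.0, type2_fraction=0.0, seed=seed)
    rec = synthgen.assemble_recording(sim)
    buf = preprocess.RecordingBuffer(rec.samples, rec.sampling_rate)
    buf = preprocess.bandpass(buf, cfg.band_low, cfg.band_high)
    buf = preprocess.common_median_reference(buf)
    buf = preprocess.normalize(buf, cfg.target_sigma)
    segs = []
    for tid, times in sorted(rec.true_units.items()):
        ch = tid % cfg.n_channels
        for t in times:
            ev = preprocess.DetectedEvent(int(round(t * buf.sampling_rate)), ch, 0.0)
            fv = preprocess.extract_segment(buf, ev)
            if fv is not None:
                segs.append(fv.z)
    rng = np.random.default_rng(seed)
    segs = np.asarray(segs)[rng.permutation(len(segs))]
    return segs[:cfg.n_train_segments]


def _safe_sensitivity(report) -> float | None:
    try:
        return metrics.sensitivity(report)
    except ValueError:
        return None


def _events_to_units(rec, events, segments, fs) -> list:
    """Oracle clustering for the demo pipeline: group detected events by the
    nearest ground-truth unit (within 1 ms), everything else in one noise
    cluster.  Stands in for an external sorter, which is out of scope."""
    from .curation import SortedUnit

    gt_items = sorted(rec.true_units.items())
    times = np.asarray([fv.source.peak_sample / fs for fv in segments])
    assign = np.full(times.size, -1)
    for uid, ut in gt_items:
        if ut.size == 0:
            continue
        pos = np.searchsorted(ut, times)
        pos = np.clip(pos, 1, ut.size - 1) if ut.size > 1 else np.zeros_like(pos)
        nearest = np.where(np.abs(times - ut[np.maximum(pos - 1, 0)])
                           <= np.abs(times - ut[np.minimum(pos, ut.size - 1)]),
                           ut[np.maximum(pos - 1, 0)], ut[np.minimum(pos, ut.size - 1)])
        hit = (np.abs(times - nearest) <= 1e-3) & (assign == -1)
        assign[hit] = uid
    units = []
    seg_arr = np.asarray([fv.z for fv in segments])
    for uid in np.unique(assign):
        mask = assign == uid
        t = times[mask]
        order = np.argsort(t)
        t = t[order]
        keep = np.concatenate([[True], np.diff(t) > 0])
        units.append(SortedUnit(int(uid), t[keep], seg_arr[mask][order][keep]))
    return units
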