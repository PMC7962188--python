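"""End-to-end pipeline: simulate/ingest -> preprocess -> split -> train ->
predict -> extract -> evaluate, with per-stage artifact writing and a
manifest of counts.

:class:`PipelineConfig` aggregates every stage's settings with defaults
matching the reference protocol: 350-sample windows overlapping by 100,
trimmed to 256 at 125 Hz; Adam with learning rate 1e-4 and batch size 4;
patience-5 early stopping; 50% dropout; subject-level 70/15/15 split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bp_extract import window_bp
from .errors import ConfigError
from .evaluate import (CorrelationSummary, ErrorStats, aami_check,
                       average_correlation, bhs_grade, bland_altman,
                       error_histogram, error_stats, per_range_accuracy)
from .io import save_json, save_windows, write_record
from .preprocess import (ArtifactRules, FilterSpec, fit_normalization,
                         preprocess_records)
from .records import SignalRecord
from .synth import SimulationParams, simulate_cohort
from .train import TrainConfig, predict_abp, split_dataset, train_model
from .unet1d import UNetConfig, build_unet, save_checkpoint

__all__ = ["SynthConfig", "WindowConfig", "ExtractionConfig",
           "PipelineConfig", "EvaluationReport", "run_pipeline"]


@dataclass(frozen=True)
class SynthConfig:
    enabled: bool = True
    n_subjects: int = 20
    duration_s: float = 120.0
    noise_sd: float = 0.0
    baseline_wander_amp: float = 0.05
    artifact_rate: float = 0.05


@dataclass(frozen=True)
class WindowConfig:
    length: int = 350
    overlap: int = 100
    out_len: int = 256
    max_lag: int = 125


@dataclass(frozen=True)
class ExtractionConfig:
    min_separation_s: float = 0.27
    prominence_frac: float = 0.25
    aami_statistic: str = "signed"
    bland_altman_clip: float = 30.0
    histogram_bin_mmhg: float = 2.0


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowConfig = field(default_factory=WindowConfig)
    model: UNetConfig = field(default_factory=UNetConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        self.filter.validate()
        self.model.validate()
        self.training.validate()
        if self.window.out_len != self.model.input_len:
            raise ConfigError(
                f"window.out_len={self.window.out_len} does not match "
                f"model.input_len={self.model.input_len}")
        if not self.window.length > self.window.overlap >= 0:
            raise ConfigError("window.length must exceed window.overlap >= 0")
        if self.window.out_len > self.window.length:
            raise ConfigError("window.out_len cannot exceed window.length")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        parts = {"synth": SynthConfig, "filter": FilterSpec,
                 "window": WindowConfig, "model": UNetConfig,
                 "training": TrainConfig, "extraction": ExtractionConfig}
        kwargs = {}
        for key, typ in parts.items():
            if key in d:
                v = d.pop(key)
                if key == "training" and isinstance(v, dict) \
                        and "split_fractions" in v:
                    v = {**v, "split_fractions": tuple(v["split_fractions"])}
                kwargs[key] = typ(**v) if isinstance(v, dict) else v
        kwargs.update(d)
        return cls(**kwargs)


@dataclass
class EvaluationReport:
    """Everything the evaluation stage computes on the held-out test split."""

    waveform: CorrelationSummary
    sbp: ErrorStats
    dbp: ErrorStats
    map: ErrorStats
    bhs: dict          # measurand -> BHSResult
    aami: dict         # measurand -> AAMIResult
    per_range: dict
    bland_altman: dict  # measurand -> {bias, loa, n}
    histograms: dict    # measurand -> {edges, counts}
    counts: dict        # preprocessing window bookkeeping
    split_sizes: dict
    n_test_subjects: int
    n_windows_no_beats: int
    best_epoch: int
    stopped_epoch: int

    def to_dict(self) -> dict:
        out = {}
        for k, v in dataclasses.asdict(self).items():
            out[k] = v
        return out


def _collect_bp(pairs, preds, extraction: ExtractionConfig, fs: float):
    """Window-level BP estimates for reference and predicted ABP."""
    ref_est, pred_est = [], []
    for pair, pred in zip(pairs, preds):
        kw = dict(fs=fs, min_separation_s=extraction.min_separation_s,
                  prominence_frac=extraction.prominence_frac)
        wid = f"{pair.subject_id}:{pair.start_index}"
        ref_est.append(window_bp(pair.abp_w, window_id=wid, **kw))
        pred_est.append(window_bp(pred, window_id=wid, **kw))
    return ref_est, pred_est


def evaluate_predictions(pairs, preds, extraction: ExtractionConfig | None = None,
                         fs: float = 125.0, counts: dict | None = None,
                         split_sizes: dict | None = None,
                         history=None) -> EvaluationReport:
    """Build the full report from test windows and mmHg predictions."""
    extraction = extraction or ExtractionConfig()
    # waveform correlation per window (Pearson r, invariant to affine scale)
    r_values = []
    for pair, pred in zip(pairs, preds):
        ref = pair.abp_w
        if np.std(ref) > 0 and np.std(pred) > 0:
            r_values.append(float(np.corrcoef(ref, pred)[0, 1]))
    waveform = average_correlation(r_values)

    ref_est, pred_est = _collect_bp(pairs, preds, extraction, fs)
    both = [(r, p) for r, p in zip(ref_est, pred_est)
            if r.has_beats and p.has_beats]
    no_beats = len(ref_est) - len(both)
    sbp_ref = np.array([r.sbp for r, _ in both])
    sbp_pred = np.array([p.sbp for _, p in both])
    dbp_ref = np.array([r.dbp for r, _ in both])
    dbp_pred = np.array([p.dbp for _, p in both])
    map_ref = np.array([r.map for r in ref_est])
    map_pred = np.array([p.map for p in pred_est])

    n_subjects = len({p.subject_id for p in pairs})
    bhs = {}
    aami = {}
    ba = {}
    hists = {}
    for name, (pred_v, ref_v) in {
            "sbp": (sbp_pred, sbp_ref), "dbp": (dbp_pred, dbp_ref),
            "map": (map_pred, map_ref)}.items():
        if len(pred_v) == 0:
            continue
        bhs[name] = bhs_grade(np.abs(pred_v - ref_v))
        aami[name] = aami_check(pred_v, ref_v, n_subjects,
                                statistic=extraction.aami_statistic)
        points, bias, loa = bland_altman(pred_v, ref_v,
                                         clip=extraction.bland_altman_clip)
        ba[name] = {"bias": bias, "loa": list(loa), "n": len(points)}
        edges, cnts = error_histogram(pred_v - ref_v,
                                      bin_width=extraction.histogram_bin_mmhg)
        hists[name] = {"edges": edges.tolist(), "counts": cnts.tolist()}

    return EvaluationReport(
        waveform=waveform,
        sbp=error_stats(sbp_pred, sbp_ref) if len(sbp_pred) else None,
        dbp=error_stats(dbp_pred, dbp_ref) if len(dbp_pred) else None,
        map=error_stats(map_pred, map_ref),
        bhs=bhs, aami=aami,
        per_range=per_range_accuracy(list(zip(ref_est, pred_est))),
        bland_altman=ba, histograms=hists,
        counts=counts or {}, split_sizes=split_sizes or {},
        n_test_subjects=n_subjects,
        n_windows_no_beats=no_beats,
        best_epoch=getattr(history, "best_epoch", 0),
        stopped_epoch=getattr(history, "stopped_epoch", 0))


def run_pipeline(config: PipelineConfig | None = None,
                 records: list[SignalRecord] | None = None,
                 verbose: bool = False):
    """Execute the full pipeline; returns ``(report, model, history, norm)``.

    With ``records=None`` the synthetic cohort configured in ``config.synth``
    is generated. When ``config.out_dir`` is set, each stage writes its
    artifacts there along with a manifest of configuration, versions, and
    per-stage window counts.
    """
    config = config or PipelineConfig()
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def log(msg):
        if verbose:
            print(f"[{time.time() - t0:7.1f}s] {msg}", file=sys.stderr)

    if records is None:
        if not config.synth.enabled:
            raise ConfigError("no records given and synth stage disabled")
        base = SimulationParams(
            noise_sd=config.synth.noise_sd,
            baseline_wander_amp=config.synth.baseline_wander_amp,
            artifact_rate=config.synth.artifact_rate)
        records = simulate_cohort(
            config.synth.n_subjects, duration_s=config.synth.duration_s,
            seed=config.seed, base_params=base)
        log(f"simulated {len(records)} subjects x "
            f"{config.synth.duration_s:.0f} s")
        if out_dir:
            rec_dir = out_dir / "records"
            rec_dir.mkdir(exist_ok=True)
            for rec in records:
                write_record(rec_dir / f"{rec.subject_id}.csv", rec)

    pairs, counts = preprocess_records(
        records, filter_spec=config.filter,
        rules=ArtifactRules(fs=config.filter.fs),
        win_len=config.window.length, overlap=config.window.overlap,
        out_len=config.window.out_len, max_lag=config.window.max_lag)
    log(f"preprocessed: {counts}")

    train_pairs, val_pairs, test_pairs = split_dataset(pairs, config.training)
    split_sizes = {"train": len(train_pairs), "val": len(val_pairs),
                   "test": len(test_pairs)}
    log(f"split: {split_sizes}")
    norm = fit_normalization(train_pairs)

    model = build_unet(config.model, seed=config.training.seed)
    model, history = train_model(model, train_pairs, val_pairs,
                                 config.training, norm=norm, verbose=verbose)
    log(f"trained: best epoch {history.best_epoch} "
        f"of {history.stopped_epoch} ({history.stop_reason})")

    preds = [predict_abp(model, p.ppg_w, norm) for p in test_pairs]
    report = evaluate_predictions(
        test_pairs, preds, extraction=config.extraction, fs=config.filter.fs,
        counts=counts, split_sizes=split_sizes, history=history)
    log(f"evaluated {len(test_pairs)} test windows: "
        f"avg r {report.waveform.avg_r:.3f}")

    if out_dir:
        import pandas as pd

        from .bp_extract import classify_bp_range
        ref_est, pred_est = _collect_bp(test_pairs, preds, config.extraction,
                                        config.filter.fs)
        rows = []
        for pair, re_, pe_ in zip(test_pairs, ref_est, pred_est):
            def _label(est):
                if not est.has_beats or not est.sbp > est.dbp:
                    return ""
                return classify_bp_range(est.sbp, est.dbp)
            rows.append({
                "window_id": re_.window_id, "subject_id": pair.subject_id,
                "sbp_ref": re_.sbp, "dbp_ref": re_.dbp, "map_ref": re_.map,
                "sbp_pred": pe_.sbp, "dbp_pred": pe_.dbp, "map_pred": pe_.map,
                "range_ref": _label(re_), "range_pred": _label(pe_)})
        pd.DataFrame(rows).to_csv(out_dir / "test_window_bp.csv", index=False)
        conf = pd.DataFrame(report.per_range["confusion"],
                            index=report.per_range["labels"],
                            columns=report.per_range["labels"])
        conf.to_csv(out_dir / "range_confusion.csv")
        ba_rows = []
        for name in report.bland_altman:
            need_beats = name != "map"  # MAP is defined for every window
            keep = [(r, p) for r, p in zip(ref_est, pred_est)
                    if not need_beats or (r.has_beats and p.has_beats)]
            if not keep:
                continue
            ref_v = [getattr(r, name) for r, _ in keep]
            pred_v = [getattr(p, name) for _, p in keep]
            pts, _, _ = bland_altman(pred_v, ref_v,
                                     clip=config.extraction.bland_altman_clip)
            for mean_, diff_ in pts:
                ba_rows.append({"measurand": name, "mean": mean_,
                                "difference": diff_})
        pd.DataFrame(ba_rows).to_csv(out_dir / "bland_altman.csv", index=False)
        save_windows(out_dir / "windows.npz", pairs, norm=norm,
                     meta={"stage": "preprocess", "counts": counts})
        save_checkpoint(out_dir / "model.npz", model, norm_params=norm,
                        extra={"best_epoch": history.best_epoch})
        save_json(report.to_dict(), out_dir / "report.json")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "counts": counts,
            "split_sizes": split_sizes,
            "history": {"train_loss": history.train_loss,
                        "val_loss": history.val_loss,
                        "best_epoch": history.best_epoch,
                        "stopped_epoch": history.stopped_epoch,
                        "stop_reason": history.stop_reason},
        }
        save_json(manifest, out_dir / "manifest.json")
    return report, model, history, norm
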