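"""End-to-end experiment: simulate -> normalize -> features -> train -> evaluate.

``run_experiment`` reproduces the full study grid on one shared stratified
split: SVM and RF on each requested feature representation, the 1D-CNN on the
normalized concatenated signal, a ranked model comparison, and an LDA map of
the AREA features.  Every artifact is traceable to the seeds recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from .classical import split_dataset, train_rf, train_svm
from .cnn import build_cnn, train_cnn
from .config import PipelineConfig
from .evaluate import (
    EvalReport,
    compare_models,
    lda_fit_project,
    plot_accuracy_bars,
    plot_confusion,
    plot_lda,
    score_predictions,
)
from .features import build_feature_table
from .io import dataset_hash, write_dataset, write_manifest
from .preprocess import apply_normalization, fit_normalization, to_cnn_input
from .simulate import Dataset, simulate_dataset

__all__ = ["run_experiment", "ExperimentResult"]

log = logging.getLogger("etongue")


@dataclasses.dataclass
class ExperimentResult:
    dataset: Dataset
    split: object
    reports: list  # EvalReport per (model, feature kind) + CNN
    comparison: object  # DataFrame
    lda: object  # LDAProjection
    cnn_trace: object | None  # DataFrame


def _stage(name: str, t0: float, path=None) -> None:
    log.info("stage %-12s %6.1f s%s", name, time.perf_counter() - t0,
             f"  -> {path}" if path else "")


def run_experiment(
    cfg: PipelineConfig, outdir=None, dataset: Dataset | None = None
) -> ExperimentResult:
    """Run the full pipeline; writes artifacts under ``outdir`` if given."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if dataset is None:
        dataset = simulate_dataset(cfg.simulation)
    _stage("simulate", t0)

    t0 = time.perf_counter()
    y = dataset.y
    split = split_dataset(y, cfg.split_fraction, cfg.split_seed)
    tr, te = split.train_rows, split.test_rows
    X_raw = dataset.X_concat
    fit_rows = tr if cfg.normalization_scope == "train_only" else np.arange(len(y))
    stats = fit_normalization(X_raw[fit_rows], scope=cfg.normalization_scope)
    _stage("preprocess", t0)

    class_order = tuple(sorted(set(y.tolist())))
    reports: list[EvalReport] = []
    for kind in cfg.feature_kinds:
        t0 = time.perf_counter()
        table = build_feature_table(dataset, kind, stats)
        for name, trainer, mcfg in (
            ("SVM", train_svm, cfg.svm),
            ("RF", train_rf, cfg.rf),
        ):
            clf = trainer(table.matrix[tr], y[tr], mcfg, seed=cfg.model_seed)
            pred = clf.predict(table.matrix[te])
            reports.append(
                score_predictions(y[te], pred, class_order, name, kind)
            )
        _stage(f"features/{kind}", t0)

    cnn_trace = None
    if not cfg.skip_cnn:
        t0 = time.perf_counter()
        Xn = apply_normalization(X_raw, stats)
        batch = to_cnn_input(Xn, cfg.cnn.input_layout, len(dataset.electrode_names))
        ccfg = dataclasses.replace(cfg.cnn, epochs=cfg.effective_cnn_epochs)
        trained = train_cnn(ccfg, batch[tr], y[tr])
        pred = trained.predict(batch[te])
        reports.append(
            score_predictions(y[te], pred, class_order, "1D-CNN", "ORIGINAL")
        )
        cnn_trace = trained.trace
        _stage("cnn", t0)

    t0 = time.perf_counter()
    comparison = compare_models(reports)
    lda = None
    if len(class_order) >= 3:  # a 2-D discriminant map needs >= 3 classes
        area_table = build_feature_table(dataset, "AREA", stats)
        lda = lda_fit_project(area_table.matrix, y)
    _stage("evaluate", t0)

    if outdir is not None:
        t0 = time.perf_counter()
        comparison.to_csv(outdir / "comparison.csv", index=False)
        for r in reports:
            np.savetxt(
                outdir / f"confusion_{r.model_kind}_{r.feature_kind}.csv",
                r.confusion,
                fmt="%d",
                delimiter=",",
            )
        best = max(reports, key=lambda r: r.accuracy)
        plot_confusion(best, outdir / "confusion_best.png")
        if lda is not None:
            plot_lda(lda, outdir / "lda.png")
        plot_accuracy_bars(comparison, outdir / "accuracy_bars.png")
        if cnn_trace is not None:
            cnn_trace.to_csv(outdir / "cnn_trace.csv", index=False)
        write_manifest(
            outdir / "manifest.json",
            seeds=cfg.seeds(),
            n_samples=len(dataset),
            n_features=X_raw.shape[1],
            split={"train": len(tr), "test": len(te)},
            dataset_sha256=dataset_hash(dataset),
            feature_kinds=list(cfg.feature_kinds),
            skip_cnn=cfg.skip_cnn,
            cnn_epochs=cfg.effective_cnn_epochs,
            delta=cfg.simulation.effect.delta,
        )
        _stage("write", t0, outdir)

    return ExperimentResult(
        dataset=dataset,
        split=split,
        reports=reports,
        comparison=comparison,
        lda=lda,
        cnn_trace=cnn_trace,
    )
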