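"""End-to-end experiment driver: tiles → features → reduction → CV → report.

An experiment is a colour-model/descriptor selection, an optional correlation
threshold, a classifier and a fold count.  The driver audits feature counts at
every stage, runs stratified cross-validation and returns a JSON-serializable
report mirroring the per-class metric tables.

Texton vocabularies and the correlation filter are refit inside each training
fold by default; ``paper_mode=True`` fits both once on the full dataset,
following the classical global protocol.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import evaluate as _evaluate
from .features import ExtractionConfig, FeatureTable, build_vocabularies, extract_dataset
from .learn import ClassifierSpec, CVResult, _fit_predict, cross_validate
from .reduce import apply_filter, fit_correlation_filter


# the five colour-model combinations and six descriptor combinations that
# define the study's model/descriptor grid
COLOUR_COMBOS = {
    "hb_luv_sct": ["hbb", "luv", "sct"],
    "cmyk_hb_lb_hsv_lab": ["cmyk", "hbb", "lbb", "hsv", "lab"],
    "cmyk_hb_lb_hsv_luv_sct": ["cmyk", "hbb", "lbb", "hsv", "luv", "sct"],
    "rgb_hb_lb_hsv_luv_sct": ["rgb", "hbb", "lbb", "hsv", "luv", "sct"],
    "all_eight": ["rgb", "cmyk", "hsv", "lab", "luv", "sct", "lbb", "hbb"],
}
DESCRIPTOR_COMBOS = {
    "int_mlbp": ["intensity", "mlbp"],
    "int_stextons": ["intensity", "stextons"],
    "int_mlbp_gabor": ["intensity", "mlbp", "gabor"],
    "int_mlbp_stextons": ["intensity", "mlbp", "stextons"],
    "int_mlbp_gabor_stextons": ["intensity", "mlbp", "gabor", "stextons"],
    "int_mlbp_gabor_wavelet": ["intensity", "mlbp", "gabor", "wavelet"],
}


@dataclass
class ExperimentConfig:
    colour_models: list = field(default_factory=lambda: ["rgb"])
    descriptors: list = field(default_factory=lambda: ["intensity"])
    threshold: float | None = None
    classifier: str = "bagging"
    n_members: int = 50
    folds: int = 10
    seed: int = 0
    paper_mode: bool = False
    k_per_class: int = 60
    max_patches_per_class: int | None = 20_000

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return ExperimentConfig(**raw)


def _extraction_config(cfg: ExperimentConfig, vocabularies=None) -> ExtractionConfig:
    return ExtractionConfig(colour_models=list(cfg.colour_models),
                            descriptors=list(cfg.descriptors),
                            vocabularies=vocabularies or {})


class _StageLog:
    """Structured per-stage log (stage, duration, counts, seed) → JSONL."""

    def __init__(self, seed: int):
        self.seed = seed
        self.records: list[dict] = []
        self._t0 = time.monotonic()

    def stage(self, name: str, **info) -> None:
        now = time.monotonic()
        self.records.append({"stage": name,
                             "duration_s": round(now - self._t0, 4),
                             "seed": self.seed, **info})
        self._t0 = now

    def write(self, path) -> None:
        Path(path).write_text(
            "".join(json.dumps(r) + "\n" for r in self.records))


def run_experiment(cfg: ExperimentConfig, images=None, labels=None,
                   data_dir=None, out_dir=None) -> dict:
    """Execute the staged pipeline and return the evaluation report.

    Tiles come either from ``images``/``labels`` or a ``class_*/`` directory.
    With ``out_dir``, intermediate artifacts are written there: ``report.json``,
    ``cv.json`` and ``log.jsonl`` always; ``features.csv`` (and ``reduced.csv``
    after a global reduction) whenever a single dataset-wide feature table
    exists, i.e. without fold-local texton vocabularies.
    """
    log = _StageLog(cfg.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    if images is None:
        if data_dir is None:
            raise ValueError("provide images/labels or data_dir")
        from .fixtures import load_tiles
        images, labels = load_tiles(data_dir)
    labels = np.asarray(labels)
    log.stage("load", n_tiles=len(images))

    needs_textons = "stextons" in cfg.descriptors
    fold_safe_textons = needs_textons and not cfg.paper_mode

    audit: dict = {}
    if fold_safe_textons:
        result, audit = _run_fold_safe(cfg, images, labels)
        log.stage("cross_validate_fold_safe", **audit, folds=cfg.folds)
    else:
        vocabs = {}
        if needs_textons:
            vocabs = build_vocabularies(images, labels, _extraction_config(cfg),
                                        k_per_class=cfg.k_per_class, seed=cfg.seed,
                                        max_patches_per_class=cfg.max_patches_per_class)
            log.stage("texton_vocabulary",
                      vocabulary_size=sum(len(v) for v in vocabs.values()))
        xcfg = _extraction_config(cfg, vocabs)
        table = extract_dataset(images, labels, xcfg)
        audit["raw_features"] = len(table.feature_names)
        audit["raw_features_closed_form"] = xcfg.n_features()
        log.stage("extract", n_features=audit["raw_features"])
        if out_dir is not None:
            table.to_csv(out_dir / "features.csv")
        if cfg.threshold is not None and cfg.paper_mode:
            model = fit_correlation_filter(table, cfg.threshold)
            table = apply_filter(table, model)
            audit["reduced_features"] = len(table.feature_names)
            log.stage("reduce", threshold=cfg.threshold,
                      n_features=audit["reduced_features"])
            if out_dir is not None:
                table.to_csv(out_dir / "reduced.csv")
        spec = ClassifierSpec(kind=cfg.classifier, n_members=cfg.n_members,
                              reduce_threshold=None if cfg.paper_mode else cfg.threshold,
                              paper_mode=cfg.paper_mode)
        result = cross_validate(table, spec, folds=cfg.folds, seed=cfg.seed)
        log.stage("cross_validate", classifier=cfg.classifier, folds=cfg.folds)

    cm = _evaluate.confusion(result.predictions, result.truth,
                             np.unique(result.truth))
    metrics = _evaluate.ovr_metrics(cm)
    report = {
        "config": asdict(cfg),
        "audit": audit,
        "accuracy": result.accuracy,
        "error": 1.0 - result.accuracy,
        "confusion": cm.counts.tolist(),
        "class_labels": [int(c) for c in cm.class_labels],
        "per_class_metrics": {str(k): v for k, v in
                              metrics.per_class.to_dict(orient="index").items()},
        "macro_metrics": metrics.macro,
        "seed": cfg.seed,
    }
    log.stage("evaluate", accuracy=report["accuracy"])
    if out_dir is not None:
        save_report(report, out_dir / "report.json")
        (out_dir / "cv.json").write_text(json.dumps({
            "predictions": result.predictions.tolist(),
            "truth": result.truth.tolist(),
            "scores": result.scores.tolist(),
            "classes": result.classes.tolist(),
            "fold_assignment": result.fold_assignment.tolist(),
            "seed": cfg.seed, "accuracy": result.accuracy}, indent=2))
        log.write(out_dir / "log.jsonl")
    return report


def _run_fold_safe(cfg: ExperimentConfig, images, labels) -> tuple[CVResult, dict]:
    """Per-fold texton vocabularies (and reduction): no test-set leakage."""
    labels = np.asarray(labels)
    non_tex = [d for d in cfg.descriptors if d != "stextons"]
    base_cfg = ExtractionConfig(colour_models=list(cfg.colour_models),
                                descriptors=non_tex) if non_tex else None
    base_table = (extract_dataset(images, labels, base_cfg)
                  if base_cfg is not None else None)

    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    classes = np.unique(labels)
    pred = np.empty(len(labels), dtype=labels.dtype)
    scores = np.zeros((len(labels), len(classes)))
    fold_assignment = np.empty(len(labels), dtype=int)
    rng = np.random.default_rng(cfg.seed)
    audit: dict = {}
    idx_all = np.arange(len(labels))
    for fold, (tr, te) in enumerate(skf.split(idx_all, labels)):
        fold_assignment[te] = fold
        train_imgs = [images[i] for i in tr]
        vocabs = build_vocabularies(train_imgs, labels[tr],
                                    _extraction_config(cfg),
                                    k_per_class=cfg.k_per_class,
                                    seed=cfg.seed + fold,
                                    max_patches_per_class=cfg.max_patches_per_class)
        tex_cfg = ExtractionConfig(colour_models=list(cfg.colour_models),
                                   descriptors=["stextons"], vocabularies=vocabs)
        tex_table = extract_dataset(images, labels, tex_cfg)
        table = _merge_tables(base_table, tex_table, cfg, labels)
        audit.setdefault("raw_features", len(table.feature_names))
        audit.setdefault("raw_features_closed_form",
                         _extraction_config(cfg, vocabs).n_features())
        sub = table.subset_rows(tr)
        if cfg.threshold is not None:
            model = fit_correlation_filter(sub, cfg.threshold)
            sub = apply_filter(sub, model)
            test = apply_filter(table.subset_rows(te), model)
            audit.setdefault("reduced_features_fold0", len(sub.feature_names))
        else:
            test = table.subset_rows(te)
        spec = ClassifierSpec(kind=cfg.classifier, n_members=cfg.n_members)
        _, p, s = _fit_predict(spec, sub.matrix, labels[tr], test.matrix,
                               int(rng.integers(2**31)))
        pred[te] = p
        fold_classes = np.unique(labels[tr])
        for t, cls in enumerate(classes):
            j = np.flatnonzero(fold_classes == cls)
            if j.size and s.shape[1] == len(fold_classes):
                scores[te, t] = s[:, j[0]]
    return CVResult(pred, labels.copy(), scores, classes, fold_assignment,
                    cfg.seed), audit


def _merge_tables(base: FeatureTable | None, tex: FeatureTable,
                  cfg: ExperimentConfig, labels) -> FeatureTable:
    """Combine non-texton and texton columns in the canonical header order."""
    from .features import feature_columns
    if base is None:
        return tex
    import pandas as pd
    merged = pd.concat([base.frame, tex.frame], axis=1)
    header = feature_columns(ExtractionConfig(colour_models=list(cfg.colour_models),
                                              descriptors=list(cfg.descriptors)))
    return FeatureTable(merged[header], np.asarray(labels))


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
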