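"""End-to-end pipeline: read -> preprocess -> featurize -> split ->
select -> fit logistic forest -> evaluate, plus the ablation and
selector-comparison harnesses.

Every random draw is traceable to the single top-level seed; identical
config + seed yields identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import synthetic
from .ants import HACOSelector
from .baselines import BaselineSelector
from .featurize import (NgramVectorizer, append_similarity_features,
                        attach_context_features)
from .forest import LogisticForestClassifier
from .metrics import MetricsReport, compute_metrics
from .preprocess import (DEFAULT_LEMMAS, DEFAULT_STOPWORDS, load_stoplist,
                         preprocess_record)
from .synthetic import CLASS_NAMES, CorpusSpec, read_corpus_csv

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "run_ablation",
    "compare_selectors",
    "ABLATION_VARIANTS",
]

SELECTOR_METHODS = ("none", "haco", "ga", "pso", "sqa", "aco")


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration; unknown keys rejected."""

    corpus_csv: Optional[str] = None
    synth: Optional[dict] = None          # CorpusSpec kwargs
    preprocess: dict = field(default_factory=dict)
    featurize: dict = field(default_factory=dict)
    selector: dict = field(default_factory=lambda: {"method": "haco"})
    classifier: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, {f.name for f in dataclasses.fields(cls)}, "config")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.corpus_csv is None) == (self.synth is None):
            raise ValueError(
                "exactly one of corpus_csv / synth must be given")
        if self.synth is not None:
            _check_keys(self.synth,
                        {f.name for f in dataclasses.fields(CorpusSpec)},
                        "synth")
        _check_keys(self.preprocess,
                    {"process_side_effects", "process_composition",
                     "stoplist_path"}, "preprocess")
        _check_keys(self.featurize,
                    {"n_range", "min_df", "tfidf", "context_features",
                     "similarity_top_k"}, "featurize")
        _check_keys(self.selector,
                    {"method", "params"}, "selector")
        method = self.selector.get("method", "haco")
        if method not in SELECTOR_METHODS:
            raise ValueError(f"selector.method must be one of "
                             f"{SELECTOR_METHODS}, got {method!r}")
        _check_keys(self.classifier,
                    {"n_subspaces", "n_trees", "m_try", "max_depth",
                     "min_leaf", "mode", "base_weights",
                     "context_weight_map", "decision_threshold"},
                    "classifier")
        _check_keys(self.evaluation,
                    {"test_fraction", "averaging"}, "evaluation")
        frac = self.evaluation.get("test_fraction", 0.2)
        if not (0.0 < frac < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def copy(self, **updates) -> "PipelineConfig":
        return dataclasses.replace(self, **updates)


@dataclass
class PipelineResult:
    report: MetricsReport
    selected_features: list
    n_features_total: int
    config_hash: str
    seed: int
    log: list

    def metrics_dict(self) -> dict:
        d = self.report.to_dict()
        d["n_selected_features"] = len(self.selected_features)
        d["n_features_total"] = self.n_features_total
        d["config_hash"] = self.config_hash
        d["seed"] = self.seed
        return d


def _load_corpus(config: PipelineConfig):
    if config.synth is not None:
        spec_kwargs = dict(config.synth)
        spec_kwargs.setdefault("seed", config.seed)
        records, labels = synthetic.generate_corpus(CorpusSpec(**spec_kwargs))
        return records, labels
    records, labels = read_corpus_csv(config.corpus_csv)
    if labels is None:
        raise ValueError("corpus CSV must carry a complete `label` column")
    return records, labels


def _make_selector(config: PipelineConfig):
    method = config.selector.get("method", "haco")
    params = dict(config.selector.get("params", {}))
    params.setdefault("seed", config.seed)
    if method == "none":
        return None
    if method == "haco":
        return HACOSelector(**params)
    return BaselineSelector(method=method, **params)


def build_features(config: PipelineConfig, records):
    """Preprocess and featurize the corpus; returns the feature matrix."""
    pp = config.preprocess
    stoplist = DEFAULT_STOPWORDS
    if pp.get("stoplist_path"):
        stoplist = load_stoplist(pp["stoplist_path"])
    cleaned = [
        preprocess_record(
            r, stoplist=stoplist, lexicon=DEFAULT_LEMMAS,
            process_side_effects=pp.get("process_side_effects", False),
            process_composition=pp.get("process_composition", False),
        )
        for r in records
    ]
    docs = [r.uses.split() for r in cleaned]
    fz = config.featurize
    vec = NgramVectorizer(
        n_range=tuple(fz.get("n_range", (1, 2))),
        min_df=fz.get("min_df", 1),
        tfidf=fz.get("tfidf", False),
    )
    fm = vec.fit_transform(docs)
    if fz.get("similarity_top_k", 0):
        fm = append_similarity_features(fm, fz["similarity_top_k"])
    if fz.get("context_features", True):
        fm = attach_context_features(fm, cleaned)
    return fm


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[str] = None) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the artifact set:
    metrics.json / metrics.csv / confusion.csv / selected_features.txt /
    model.json / run.log."""
    config.validate()
    log: list = []
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) \
        else None
    try:
        log.append(f"config_hash={config.config_hash()} seed={config.seed}")
        records, labels = _load_corpus(config)
        log.append(f"stage=load n_records={len(records)}")
        fm = build_features(config, records)
        log.append(f"stage=featurize n_features={fm.shape[1]}")
        X, y = fm.values, np.asarray(labels)
        frac = config.evaluation.get("test_fraction", 0.2)
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=frac, stratify=y,
            random_state=config.seed)
        selector = _make_selector(config)
        if selector is None:
            selected = list(range(X.shape[1]))
        else:
            selector.fit(X[idx_train], y[idx_train])
            selected = selector.get_support(indices=True).tolist()
        log.append(f"stage=select n_selected={len(selected)}")
        names = [fm.feature_names[j] for j in selected]
        clf_kwargs = dict(config.classifier)
        clf_kwargs.setdefault("class_names", list(CLASS_NAMES)[: len(np.unique(y))])
        clf = LogisticForestClassifier(seed=config.seed, **clf_kwargs)
        clf.fit(X[idx_train][:, selected], y[idx_train])
        y_pred = clf.predict(X[idx_test][:, selected])
        y_proba = clf.predict_proba(X[idx_test][:, selected])
        report = compute_metrics(
            y[idx_test], y_pred, y_proba,
            averaging=config.evaluation.get("averaging", "macro"),
            classes=clf.classes_)
        log.append(f"stage=evaluate accuracy={report.accuracy:.4f}")
        result = PipelineResult(
            report=report,
            selected_features=names,
            n_features_total=fm.shape[1],
            config_hash=config.config_hash(),
            seed=config.seed,
            log=log,
        )
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            (out / "metrics.json").write_text(
                json.dumps(result.metrics_dict(), indent=2, sort_keys=True))
            flat = {k: v for k, v in result.metrics_dict().items()
                    if isinstance(v, (int, float)) or v is None}
            pd.DataFrame([flat]).to_csv(out / "metrics.csv", index=False)
            pd.DataFrame(report.confusion,
                         index=clf.classes_, columns=clf.classes_
                         ).to_csv(out / "confusion.csv")
            (out / "selected_features.txt").write_text(
                "\n".join(names) + "\n")
            (out / "model.json").write_text(clf.to_json())
            (out / "run.log").write_text("\n".join(log) + "\n")
        return result
    except Exception:
        if out is not None and out.exists():
            shutil.rmtree(out, ignore_errors=True)  # no partial artifacts
        raise


ABLATION_VARIANTS = (
    "full",
    "without_context_aware",
    "without_aco_feature_selection",
    "without_cosine_similarity",
    "random_forest_only",
    "logistic_regression_only",
)


def _variant_config(config: PipelineConfig, variant: str) -> PipelineConfig:
    if variant == "full":
        return config
    if variant == "without_context_aware":
        fz = dict(config.featurize)
        fz["context_features"] = False
        clf = dict(config.classifier)
        clf["context_weight_map"] = {}
        return config.copy(featurize=fz, classifier=clf)
    if variant == "without_aco_feature_selection":
        return config.copy(selector={"method": "none"})
    if variant == "without_cosine_similarity":
        fz = dict(config.featurize)
        fz["similarity_top_k"] = 0
        return config.copy(featurize=fz)
    if variant == "random_forest_only":
        clf = dict(config.classifier)
        clf.update(base_weights=(0.0, 1.0), context_weight_map={})
        return config.copy(selector={"method": "none"}, classifier=clf)
    if variant == "logistic_regression_only":
        clf = dict(config.classifier)
        clf.update(base_weights=(1.0, 0.0), context_weight_map={})
        return config.copy(selector={"method": "none"}, classifier=clf)
    raise ValueError(f"unknown ablation variant {variant!r}")


def run_ablation(config: PipelineConfig) -> pd.DataFrame:
    """Run the six ablation variants on the same corpus, split and seed;
    the full model is the first row."""
    config.validate()
    rows = []
    for variant in ABLATION_VARIANTS:
        res = run_pipeline(_variant_config(config, variant))
        rows.append({
            "variant": variant,
            "accuracy": res.report.accuracy,
            "precision": res.report.precision,
            "recall": res.report.recall,
            "f1": res.report.f1,
        })
    return pd.DataFrame(rows)


def compare_selectors(
    config: PipelineConfig,
    methods=("ga", "pso", "sqa", "aco", "haco"),
) -> pd.DataFrame:
    """Run the pipeline once per selector with the identical downstream
    hybrid classifier; one row per method."""
    config.validate()
    rows = []
    for method in methods:
        sel = dict(config.selector)
        sel["method"] = method
        res = run_pipeline(config.copy(selector=sel))
        rows.append({
            "method": method,
            "accuracy": res.report.accuracy,
            "precision": res.report.precision,
            "recall": res.report.recall,
            "f1": res.report.f1,
            "n_selected": len(res.selected_features),
        })
    return pd.DataFrame(rows)
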