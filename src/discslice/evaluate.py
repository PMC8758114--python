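"""Macro-averaged metrics and the repeat-based benchmark protocol.

Performance of a 4-class slice classifier is summarized by the overall
accuracy A = trace(CM)/N and macro-averaged precision, recall and
F1-score::

    P = (1/C) sum_i P_i        P_i = tp_i / (tp_i + fp_i)
    R = (1/C) sum_i R_i        R_i = tp_i / (tp_i + fn_i)
    F = (2/C) sum_i P_i R_i / (P_i + R_i)

A class with an empty prediction or truth column contributes 0 to the
macro average (with a warning).  The benchmark repeats every method
combination over freshly drawn stratified 80:20 splits (20 by default),
fits DR/FS transforms and hyperparameter searches on training rows only,
and summarizes each combination by the min/max/mean/median of every
metric over the repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import HPOConfig, predict, train_fc, train_learner
from .dataset_io import CLASS_ORDER, make_splits
from .features import FeatureMatrix
from .reduce_select import RankingSelector, Reducer

__all__ = [
    "CombinationSummary",
    "EvalReport",
    "confusion",
    "metrics",
    "run_benchmark",
    "select_best",
]


def confusion(y_true, y_pred, class_order=CLASS_ORDER) -> np.ndarray:
    """Counts matrix: rows = true class, cols = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    cm = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r}/{p!r}")
        cm[index[t], index[p]] += 1
    return cm


@dataclass
class EvalReport:
    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    class_order: tuple
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }


def metrics(cm: np.ndarray, class_order=CLASS_ORDER) -> EvalReport:
    """Overall accuracy plus per-class and macro P/R/F from a counts matrix."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    c = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    if np.any(tp + fp == 0) or np.any(tp + fn == 0):
        warnings.warn("empty predicted or true class; it contributes 0 to "
                      "the macro averages")
    return EvalReport(
        accuracy=float(tp.sum() / total),
        precision_per_class=prec,
        recall_per_class=rec,
        f1_per_class=f1,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float((2.0 / c) * np.sum(prec * rec /
                                          np.where(prec + rec > 0,
                                                   prec + rec, 1.0))),
        class_order=tuple(class_order),
        n_samples=total,
    )


# ---------------------------------------------------------------------------
# Benchmark protocol
# ---------------------------------------------------------------------------

@dataclass
class CombinationSummary:
    backbone: str
    method: str            # "FL", "PCA", "FA", "FastICA", "NCA", "MRMR", "CHI2"
    classifier: str
    reports: list[EvalReport] = field(default_factory=list)
    splits: list = field(default_factory=list)  # (train_ids, test_ids) pairs
    errors: list[str] = field(default_factory=list)

    def stat(self, metric: str, fn) -> float:
        vals = [r.as_dict()[metric] for r in self.reports]
        return float(fn(vals))

    def summary(self) -> dict:
        out = {}
        for metric in ("accuracy", "precision", "recall", "f1"):
            vals = [r.as_dict()[metric] for r in self.reports]
            out[metric] = {
                "min": float(np.min(vals)), "max": float(np.max(vals)),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
        return out


_DR_METHODS = {"pca", "fa", "fastica"}
_FS_METHODS = {"nca", "mrmr", "chi2"}


def _fit_transform_method(method: str, Xtr, ytr, Xte, length, seed):
    m = method.lower()
    if m == "fl":
        return Xtr, Xte
    if m in _DR_METHODS:
        if m == "pca":
            red = Reducer(method="pca", ev_threshold=0.95).fit(Xtr)
        else:
            k = min(length, min(Xtr.shape) - 1)
            red = Reducer(method=m, n_components=k, random_state=seed).fit(Xtr)
        return red.transform(Xtr), red.transform(Xte)
    if m in _FS_METHODS:
        sel = RankingSelector(method=m, k=min(length, Xtr.shape[1])).fit(
            Xtr, ytr)
        return sel.transform(Xtr), sel.transform(Xte)
    raise ValueError(f"unknown DR/FS method {method!r}")


def _train(classifier: str, Xtr, ytr, hpo: HPOConfig):
    if classifier.upper().startswith("FC-"):
        return train_fc(classifier.split("-", 1)[1], Xtr, ytr, hpo)
    return train_learner(classifier, Xtr, ytr, hpo)


def run_benchmark(features_by_backbone: dict[str, FeatureMatrix],
                  methods, classifiers, n_repeats: int = 20,
                  base_seed: int = 0, hpo: HPOConfig | None = None,
                  method_lengths: dict[str, int] | None = None
                  ) -> list[CombinationSummary]:
    """Repeat-protocol benchmark over backbone x DR/FS x classifier combos.

    ``features_by_backbone`` maps backbone names to feature matrices with
    aligned ``labels``.  For every combination and repeat, a stratified
    80:20 split is drawn, the DR/FS transform is fitted on training rows
    only, the classifier is trained (with Bayesian HPO) on the transformed
    training rows, and the held-out rows are scored.  ``method_lengths``
    gives the reduced length per non-PCA method (default: 25% of the full
    dimension).  Stage failures are recorded on the combination and the
    benchmark continues.
    """
    hpo = hpo or HPOConfig()
    method_lengths = method_lengths or {}
    summaries = []
    for backbone, fm in features_by_backbone.items():
        if fm.labels is None:
            raise ValueError(f"features for {backbone} carry no labels")
        X = fm.values
        y = np.asarray(fm.labels)
        plans = make_splits(None, n_repeats=n_repeats, base_seed=base_seed,
                            labels=y)
        for method in methods:
            length = method_lengths.get(
                method, max(1, int(round(0.25 * X.shape[1]))))
            for classifier in classifiers:
                summ = CombinationSummary(backbone=backbone, method=method,
                                          classifier=classifier)
                for plan in plans:
                    tr = np.asarray(plan.train)
                    te = np.asarray(plan.test)
                    try:
                        Xtr, Xte = _fit_transform_method(
                            method, X[tr], y[tr], X[te], length,
                            seed=plan.seed % (2 ** 31))
                        rep_hpo = HPOConfig(
                            budget=hpo.budget, folds=hpo.folds,
                            seed=(hpo.seed + plan.repeat_id) % (2 ** 31),
                            n_initial=hpo.n_initial,
                            n_candidates=hpo.n_candidates,
                        )
                        clf = _train(classifier, Xtr, y[tr], rep_hpo)
                        y_pred = predict(clf, Xte)
                        cm = confusion(y[te], y_pred)
                        summ.reports.append(metrics(cm))
                        summ.splits.append((tuple(tr), tuple(te)))
                    except Exception as exc:  # noqa: BLE001
                        summ.errors.append(
                            f"repeat {plan.repeat_id}: {exc!r}")
                summaries.append(summ)
    return summaries


_CATALOG_ORDER = ("FKNN", "MKNN", "CKNN", "COSKNN", "CUBKNN", "WKNN",
                  "CTREE", "MTREE", "FTREE", "LSVM", "QSVM", "CSVM",
                  "FGSVM", "MGSVM", "CGSVM", "LD", "QD", "BAG", "BOOST",
                  "RUS", "FC-SGDM", "FC-RMSP", "FC-ADAM")


def _catalog_rank(cid: str) -> int:
    cid = cid.upper()
    return _CATALOG_ORDER.index(cid) if cid in _CATALOG_ORDER else 99


def _boxplot_stats(values) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"min": float(np.min(values)), "q1": float(q1),
            "median": float(med), "q3": float(q3),
            "max": float(np.max(values))}


def select_best(summaries: list[CombinationSummary]) -> dict:
    """Pick the best classifier per combination and the global winner.

    Primary key is mean accuracy; ties break by mean macro-F1, then by
    catalog order.  The report carries min/max/mean/median tables for each
    combination, per-metric winners, and per-class boxplot statistics of
    the winning combination's repeats.
    """
    if not summaries:
        raise ValueError("no summaries to select from")
    scored = [s for s in summaries if s.reports]
    if not scored:
        raise ValueError("all combinations failed")

    def key(s: CombinationSummary):
        return (-s.stat("accuracy", np.mean), -s.stat("f1", np.mean),
                _catalog_rank(s.classifier))

    per_combo: dict[tuple, CombinationSummary] = {}
    for s in scored:
        combo = (s.backbone, s.method)
        if combo not in per_combo or key(s) < key(per_combo[combo]):
            per_combo[combo] = s
    best = min(per_combo.values(), key=key)
    tables = {
        f"{bk}|{m}": {
            "classifier": s.classifier,
            **s.summary(),
        }
        for (bk, m), s in per_combo.items()
    }
    per_metric_winners = {
        metric: max(scored,
                    key=lambda s: s.stat(metric, np.mean)).classifier
        for metric in ("accuracy", "precision", "recall", "f1")
    }
    boxplots = {}
    for ci, cname in enumerate(best.reports[0].class_order):
        boxplots[cname] = {
            "precision": _boxplot_stats(
                [r.precision_per_class[ci] for r in best.reports]),
            "recall": _boxplot_stats(
                [r.recall_per_class[ci] for r in best.reports]),
            "f1": _boxplot_stats(
                [r.f1_per_class[ci] for r in best.reports]),
        }
    return {
        "best": {"backbone": best.backbone, "method": best.method,
                 "classifier": best.classifier,
                 "mean_accuracy": best.stat("accuracy", np.mean),
                 "summary": best.summary()},
        "tables": tables,
        "per_metric_winners": per_metric_winners,
        "per_class_boxplots": boxplots,
    }
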