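"""Dimensionality reduction, feature ranking, and feature-length calibration.

Three transforms (PCA at a 0.95 explained-variance threshold, FastICA,
maximum-likelihood Factor Analysis) reduce the CNN feature space; three
rankers (diagonal-weight NCA, greedy MRMR on quantile-binned mutual
information, and a chi-square mass statistic) order the untransformed
features by importance.  ``calibrate_length`` scans candidate lengths of
5-25% of the full feature dimension (5% steps), scores each with a small
classifier panel on a held-out split, and averages each classifier's best
length into one representative length per method.

Reducers and the ranking selector follow the scikit-learn estimator
protocol (``fit`` / ``transform``, fitted attributes with a trailing
underscore) so they compose with sklearn pipelines; ties in every ranking
break by ascending original feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FactorAnalysis, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureRanking",
    "LengthCalibration",
    "Reducer",
    "RankingSelector",
    "calibrate_length",
    "fit_fa",
    "fit_fastica",
    "fit_pca",
    "rank_chi2",
    "rank_mrmr",
    "rank_nca",
]

LENGTH_GRID_PERCENTS = (5, 10, 15, 20, 25)


def _as_matrix(X) -> np.ndarray:
    vals = getattr(X, "values", X)
    return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# Reducers (DR transforms)
# ---------------------------------------------------------------------------

class Reducer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over the three DR transforms.

    ``method`` is one of ``"pca"``, ``"fastica"``, ``"fa"``.  For PCA the
    output dimension is the smallest component count whose cumulative
    explained variance reaches ``ev_threshold``; for the others it is
    ``n_components``.
    """

    def __init__(self, method: str = "pca", n_components: int | None = None,
                 ev_threshold: float = 0.95, max_iter: int = 500,
                 random_state: int = 0):
        self.method = method
        self.n_components = n_components
        self.ev_threshold = ev_threshold
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        method = self.method.lower()
        self.input_dim_ = d
        self.converged_ = True
        if method == "pca":
            full = PCA().fit(X)
            cum = np.cumsum(full.explained_variance_ratio_)
            k = int(np.searchsorted(cum, self.ev_threshold) + 1)
            k = min(k, len(cum))
            if cum[-1] < self.ev_threshold:
                warnings.warn("explained-variance threshold unreachable; "
                              "keeping full rank")
                k = len(cum)
            self.model_ = PCA(n_components=k).fit(X)
            self.explained_variance_curve_ = cum
        elif method == "fastica":
            k = self._k(n, d)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                self.model_ = FastICA(
                    n_components=k, fun="logcosh", whiten="unit-variance",
                    max_iter=self.max_iter, random_state=self.random_state,
                ).fit(X)
                self.converged_ = not any(
                    issubclass(w.category, ConvergenceWarning) for w in caught
                )
        elif method == "fa":
            k = self._k(n, d)
            self.model_ = FactorAnalysis(
                n_components=k, max_iter=max(self.max_iter, 1000),
                random_state=self.random_state,
            ).fit(X)
            self.loglike_ = list(self.model_.loglike_)
        else:
            raise ValueError(f"unknown reducer method {self.method!r}")
        self.output_dim_ = int(self.model_.components_.shape[0])
        return self

    def _k(self, n: int, d: int) -> int:
        if self.n_components is None:
            raise ValueError(f"{self.method} requires n_components")
        if not 1 <= self.n_components <= min(n, d):
            raise ValueError("n_components out of range")
        return int(self.n_components)

    def transform(self, X) -> np.ndarray:
        return self.model_.transform(_as_matrix(X))


def fit_pca(X, ev_threshold: float = 0.95) -> Reducer:
    return Reducer(method="pca", ev_threshold=ev_threshold).fit(X)


def fit_fastica(X, k: int, seed: int = 0) -> Reducer:
    return Reducer(method="fastica", n_components=k, random_state=seed).fit(X)


def fit_fa(X, k: int, seed: int = 0) -> Reducer:
    return Reducer(method="fa", n_components=k, random_state=seed).fit(X)


# ---------------------------------------------------------------------------
# Feature rankings (FS methods)
# ---------------------------------------------------------------------------

@dataclass
class FeatureRanking:
    method: str
    order: np.ndarray   # permutation of feature indices, best first
    scores: np.ndarray  # per-feature scores aligned with the original indexing

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if sorted(self.order.tolist()) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of feature indices")

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def _descending_with_ties(scores: np.ndarray) -> np.ndarray:
    # stable: descending score, ascending index on ties
    idx = np.arange(len(scores))
    return idx[np.lexsort((idx, -scores))]


def rank_chi2(X, y) -> FeatureRanking:
    """Chi-square mass statistic on min-max-shifted nonnegative features.

    Per feature, the observed per-class sums of the rescaled feature mass
    are compared against expectations proportional to class frequencies;
    constant features score 0 and rank last.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    Xn = (X - lo) / span
    with np.errstate(invalid="ignore", divide="ignore"):
        stats, _ = _sk_chi2(Xn, y)
    stats = np.nan_to_num(stats, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureRanking("chi2", _descending_with_ties(stats), stats)


def quantile_bin(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency discretization of a 1-D feature."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def discrete_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2((joint / (pa @ pb))[mask])))


def rank_mrmr(X, y, bins: int = 10) -> FeatureRanking:
    """Greedy minimum-redundancy maximum-relevance forward ordering.

    Relevance is the plug-in mutual information between each
    quantile-binned feature and the class labels; redundancy is the mean
    MI against the already selected features.  The full ordering is
    returned; scores are the greedy criterion values at selection time.
    Criterion ties resolve toward the feature with smaller accumulated
    redundancy (the minimum-redundancy principle), then ascending index.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    n, d = X.shape
    if d < 1:
        raise ValueError("need at least one feature")
    binned = np.column_stack([quantile_bin(X[:, j], bins) for j in range(d)])
    relevance = np.array([discrete_mi(binned[:, j], y) for j in range(d)])
    selected: list[int] = []
    scores = np.zeros(d)
    remaining = list(range(d))
    red_cache = np.zeros(d)
    while remaining:
        if not selected:
            crit = {j: relevance[j] for j in remaining}
        else:
            crit = {j: relevance[j] - red_cache[j] / len(selected)
                    for j in remaining}
        pick = min(remaining, key=lambda j: (-crit[j], red_cache[j], j))
        scores[pick] = float(crit[pick])
        selected.append(pick)
        remaining.remove(pick)
        for j in remaining:
            red_cache[j] += discrete_mi(binned[:, j], binned[:, pick])
    return FeatureRanking("mrmr", np.asarray(selected), scores)


def rank_nca(X, y, regularization: float | None = None,
             max_iter: int = 200, tol: float = 1e-6) -> FeatureRanking:
    """Per-feature NCA weights via regularized stochastic-neighbor ascent.

    Learns one nonnegative-squared weight per feature maximizing the
    expected leave-one-out same-class neighbor probability
    ``(1/n) sum_i sum_{j~i} p_ij`` with an L2 penalty ``lambda sum w^2``
    (default ``lambda = 1/n``), where ``p_ij`` is the softmax over the
    weighted Manhattan distances ``sum_r w_r^2 |x_ir - x_jr|``.  Features
    are standardized internally; ranking is by descending weight magnitude.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    n, d = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    lam = 1.0 / n if regularization is None else float(regularization)
    if lam < 0:
        raise ValueError("regularization must be nonnegative")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    chunk = max(1, min(d, int(4e6 // max(n * n, 1)) or 1))

    def dist_and_terms(w, need_grad: bool):
        w2 = w * w
        dist = np.zeros((n, n))
        for s in range(0, d, chunk):
            g = np.abs(Xs[:, None, s:s + chunk] - Xs[None, :, s:s + chunk])
            dist += g @ w2[s:s + chunk]
        np.fill_diagonal(dist, np.inf)
        logits = -dist
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        p_i = (p * same).sum(axis=1)
        obj = p_i.mean() - lam * np.sum(w2)
        if not need_grad:
            return obj, None
        grad = np.empty(d)
        a = p_i[:, None] * p - same * p  # (n, n) weights on g_ijr
        for s in range(0, d, chunk):
            g = np.abs(Xs[:, None, s:s + chunk] - Xs[None, :, s:s + chunk])
            grad[s:s + chunk] = np.einsum("ij,ijr->r", a, g)
        grad = (2.0 * w) * grad / n - 2.0 * lam * w
        return obj, grad

    w = np.ones(d)
    obj, grad = dist_and_terms(w, True)
    lr = 1.0
    obj_trace = [obj]
    for _ in range(max_iter):
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite NCA gradient")
        improved = False
        for _halving in range(20):
            w_new = w + lr * grad
            obj_new, _ = dist_and_terms(w_new, False)
            if np.isfinite(obj_new) and obj_new > obj:
                improved = True
                break
            lr *= 0.5
        if not improved or obj_new - obj < tol:
            if improved:
                w, obj = w_new, obj_new
                obj_trace.append(obj)
            break
        w, obj = w_new, obj_new
        obj_trace.append(obj)
        _, grad = dist_and_terms(w, True)
        lr *= 1.2
    weights = np.abs(w)
    ranking = FeatureRanking("nca", _descending_with_ties(weights), weights)
    ranking.objective_trace_ = np.asarray(obj_trace)  # accepted-step ascent
    return ranking


_RANKERS = {"chi2": rank_chi2, "mrmr": rank_mrmr, "nca": rank_nca}


class RankingSelector(BaseEstimator, TransformerMixin):
    """Select the top-``k`` features of an FS ranking (sklearn transformer)."""

    def __init__(self, method: str = "mrmr", k: int = 10):
        self.method = method
        self.k = k

    def fit(self, X, y):
        if self.method not in _RANKERS:
            raise ValueError(f"unknown ranking method {self.method!r}")
        self.ranking_ = _RANKERS[self.method](X, y)
        self.support_ = np.sort(self.ranking_.top(self.k))
        return self

    def transform(self, X) -> np.ndarray:
        return _as_matrix(X)[:, self.support_]


# ---------------------------------------------------------------------------
# Feature-length calibration
# ---------------------------------------------------------------------------

@dataclass
class LengthCalibration:
    method: str
    grid_percent: tuple[int, ...]
    candidate_lengths: tuple[int, ...]
    accuracies: dict = field(default_factory=dict)  # (classifier, length) -> acc
    best_per_classifier: dict = field(default_factory=dict)
    chosen_length: int = 0


def candidate_lengths(full_dim: int,
                      grid=LENGTH_GRID_PERCENTS) -> tuple[int, ...]:
    """Grid-induced candidate lengths, e.g. 1920 -> (96, 192, 288, 384, 480)."""
    return tuple(max(1, int(round(full_dim * p / 100.0))) for p in grid)


DEFAULT_CALIBRATION_CLASSIFIERS = ("LSVM", "FGSVM", "FTREE", "WKNN")


def choose_representative_length(best_lengths, lengths) -> int:
    """Average each classifier's best length, snap to the nearest grid length.

    With a single classifier this returns that classifier's best length;
    equidistant averages snap to the smaller grid length.
    """
    mean_len = float(np.mean(list(best_lengths)))
    return min(lengths, key=lambda c: (abs(c - mean_len), c))


def calibrate_length(X, y, method: str,
                     classifiers=DEFAULT_CALIBRATION_CLASSIFIERS,
                     seed: int = 0) -> LengthCalibration:
    """Pick one representative reduced length for a DR/FS method.

    For every grid length the method is fitted on an internal 80:20
    stratified holdout's training part; each panel classifier (with fixed
    mid-range hyperparameters — no HPO at this stage) is scored on the
    holdout, its best length taken, and the classifier-average rounded to
    the nearest grid length.  PCA does not use this procedure (its length
    comes from the explained-variance threshold).
    """
    from .classify import make_estimator

    method = method.lower()
    if method == "pca":
        raise ValueError("PCA length comes from the explained-variance "
                         "threshold; calibrate_length applies to the others")
    if method not in ("fastica", "fa", "nca", "mrmr", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    if not classifiers:
        raise ValueError("need at least one classifier")
    X = _as_matrix(X)
    y = np.asarray(y)
    d = X.shape[1]
    lengths = candidate_lengths(d)
    Xtr, Xho, ytr, yho = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed
    )
    cal = LengthCalibration(method=method, grid_percent=LENGTH_GRID_PERCENTS,
                            candidate_lengths=lengths)
    for length in lengths:
        k = min(length, min(Xtr.shape) - 1)
        if method in ("fastica", "fa"):
            red = Reducer(method=method, n_components=k,
                          random_state=seed).fit(Xtr)
            Ztr, Zho = red.transform(Xtr), red.transform(Xho)
        else:
            sel = RankingSelector(method=method, k=k).fit(Xtr, ytr)
            Ztr, Zho = sel.transform(Xtr), sel.transform(Xho)
        for cid in classifiers:
            clf = make_estimator(cid, random_state=seed)
            clf.fit(Ztr, ytr)
            cal.accuracies[(cid, length)] = float(
                np.mean(clf.predict(Zho) == yho)
            )
    for cid in classifiers:
        accs = [cal.accuracies[(cid, length)] for length in lengths]
        cal.best_per_classifier[cid] = lengths[int(np.argmax(accs))]
    cal.chosen_length = choose_representative_length(
        cal.best_per_classifier.values(), lengths)
    return cal
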