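"""Classifier catalogs and Bayesian hyperparameter optimization.

Twenty machine-learning learner setups (KNN, binary decision tree, SVM,
discriminant analysis and tree-ensemble families) and three fully
connected softmax-head training setups (SGDM / RMSProp / Adam) are
described by declarative hyperparameter spaces.  Hyperparameters are
searched by Bayesian optimization — a Gaussian-process surrogate with an
expected-improvement acquisition and an over-exploitation escape —
minimizing the cross-validated misclassification rate, after which the
winning configuration is refit on the full training split.

Learner ids: FKNN MKNN CKNN COSKNN CUBKNN WKNN CTREE MTREE FTREE LSVM QSVM
CSVM FGSVM MGSVM CGSVM LD QD BAG BOOST RUS; FC optimizer ids: SGDM RMSP
ADAM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsOneClassifier, OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FCSpec",
    "HPOConfig",
    "LearnerSpec",
    "Param",
    "SoftmaxClassifier",
    "TrainedClassifier",
    "bayes_optimize",
    "expected_improvement",
    "fc_catalog",
    "learner_catalog",
    "make_estimator",
    "predict",
    "train_fc",
    "train_learner",
]


# ---------------------------------------------------------------------------
# Hyperparameter space grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Param:
    name: str
    kind: str                     # "int" | "float" | "cat"
    low: float | None = None
    high: float | None = None
    options: tuple = ()
    log: bool = False

    def default(self):
        if self.kind == "cat":
            return self.options[0]
        if self.log:
            mid = math.sqrt(self.low * self.high)
        else:
            mid = 0.5 * (self.low + self.high)
        return int(round(mid)) if self.kind == "int" else float(mid)

    def contains(self, value) -> bool:
        if self.kind == "cat":
            return value in self.options
        return self.low <= value <= self.high


@dataclass(frozen=True)
class LearnerSpec:
    id: str
    family: str
    fixed: dict = field(default_factory=dict)
    space: tuple[Param, ...] = ()


@dataclass(frozen=True)
class FCSpec:
    optimizer: str                 # "SGDM" | "RMSP" | "ADAM"
    fixed: dict = field(default_factory=dict)
    space: tuple[Param, ...] = ()


def _decomp() -> Param:
    return Param("decomposition", "cat", options=("onevsone", "onevsall"))


def _standardize() -> Param:
    return Param("standardize", "cat", options=("yes", "no"))


def _score_transform() -> Param:
    # posterior-score calibration flag: recorded but inert for the argmax
    # prediction, matching its role in the catalog
    return Param("score_transform", "cat", options=("no", "yes"))


def _cost() -> Param:
    return Param("cost", "float", 0.001, 1000.0, log=True)


def learner_catalog() -> list[LearnerSpec]:
    """The 20 ML learner setups with their hyperparameter spaces."""
    knn_fixed = {"distance": "euclidean", "weight": "equal"}
    specs = [
        LearnerSpec("FKNN", "knn", knn_fixed, (
            Param("n_neighbors", "int", 1, 10), _decomp(), _standardize())),
        LearnerSpec("MKNN", "knn", knn_fixed, (
            Param("n_neighbors", "int", 10, 100), _decomp(), _standardize())),
        LearnerSpec("CKNN", "knn", knn_fixed, (
            Param("n_neighbors", "int", 100, 1000), _decomp(), _standardize())),
        LearnerSpec("COSKNN", "knn", {"distance": "cosine", "weight": "equal"}, (
            Param("n_neighbors", "int", 10, 100), _decomp(), _standardize())),
        LearnerSpec("CUBKNN", "knn",
                    {"distance": "minkowski", "exponent": 3, "weight": "equal"},
                    (_score_transform(), Param("n_neighbors", "int", 10, 100),
                     _decomp(), _standardize())),
        LearnerSpec("WKNN", "knn",
                    {"distance": "euclidean", "weight": "squaredinverse"},
                    (_score_transform(), Param("n_neighbors", "int", 10, 100),
                     _decomp(), _standardize())),
        LearnerSpec("CTREE", "tree", {"min_parent_size": 10}, (
            Param("max_splits", "int", 4, 20), _decomp())),
        LearnerSpec("MTREE", "tree", {"min_parent_size": 10}, (
            Param("max_splits", "int", 20, 100), _decomp())),
        LearnerSpec("FTREE", "tree", {"min_parent_size": 10}, (
            Param("max_splits", "int", 100, 1000), _decomp())),
        LearnerSpec("LSVM", "svm", {"kernel": "linear"}, (
            _cost(), _decomp(), _standardize())),
        LearnerSpec("QSVM", "svm", {"kernel": "poly", "degree": 2}, (
            _cost(), _decomp(), _standardize())),
        LearnerSpec("CSVM", "svm", {"kernel": "poly", "degree": 3}, (
            _cost(), _decomp(), _standardize())),
        LearnerSpec("FGSVM", "svm", {"kernel": "rbf"}, (
            Param("kernel_scale", "float", 10.0, 40.0), _cost(),
            _decomp(), _standardize())),
        LearnerSpec("MGSVM", "svm", {"kernel": "rbf"}, (
            Param("kernel_scale", "float", 40.0, 80.0), _cost(),
            _decomp(), _standardize())),
        LearnerSpec("CGSVM", "svm", {"kernel": "rbf"}, (
            Param("kernel_scale", "float", 80.0, 160.0), _cost(),
            _decomp(), _standardize())),
        LearnerSpec("LD", "discriminant", {"type": "pseudolinear"}, (
            Param("delta", "float", 1e-6, 1000.0, log=True),
            Param("gamma", "float", 0.0, 1.0), _decomp())),
        LearnerSpec("QD", "discriminant", {"type": "pseudoquadratic"}, (
            Param("gamma", "float", 0.0, 1.0), _decomp())),
        LearnerSpec("BAG", "ensemble", {"method": "bag", "min_parent_size": 10}, (
            Param("n_cycles", "int", 10, 50),
            Param("max_splits", "int", 3500, 4500))),
        LearnerSpec("BOOST", "ensemble",
                    {"method": "adaboostm2", "min_parent_size": 10}, (
            Param("learning_rate", "float", 0.001, 0.1, log=True),
            Param("n_cycles", "int", 10, 50),
            Param("max_splits", "int", 3500, 4500))),
        LearnerSpec("RUS", "ensemble",
                    {"method": "rusboost", "min_parent_size": 10}, (
            Param("learning_rate", "float", 0.001, 0.1, log=True),
            Param("n_cycles", "int", 10, 50),
            Param("max_splits", "int", 3500, 4500))),
    ]
    assert len(specs) == 20
    return specs


def fc_catalog() -> list[FCSpec]:
    """The 3 fully-connected training setups (one per optimizer)."""
    fixed = {"max_epochs": 30, "shuffle_every_epoch": True,
             "validation_frequency": 3}
    space = (
        Param("batch_size", "int", 10, 20),
        Param("learning_rate", "float", 0.001, 0.1, log=True),
        Param("l2", "float", 1e-10, 1e-2, log=True),
        Param("momentum", "float", 0.8, 0.98),
    )
    return [FCSpec(opt, dict(fixed), space) for opt in ("SGDM", "RMSP", "ADAM")]


def get_learner(spec_id: str) -> LearnerSpec:
    for s in learner_catalog():
        if s.id.lower() == spec_id.lower():
            return s
    raise KeyError(f"unknown learner {spec_id!r}")


# ---------------------------------------------------------------------------
# Custom estimators
# ---------------------------------------------------------------------------

class _ClampedKNN(KNeighborsClassifier):
    """KNN that clamps n_neighbors to the fitted sample count."""

    def fit(self, X, y):
        self._requested_neighbors = self.n_neighbors
        self.n_neighbors = int(min(self.n_neighbors, len(np.asarray(y)) - 1)) or 1
        return super().fit(X, y)


class ThresholdedLDA(LinearDiscriminantAnalysis):
    """LDA with post-fit absolute coefficient thresholding.

    Coefficients with magnitude below ``delta`` are zeroed after fitting,
    the analogue of a linear-coefficient sparsity threshold; ``shrinkage``
    plays the regularization role and the lsqr solver tolerates singular
    within-class covariance.
    """

    def __init__(self, delta: float = 0.0, shrinkage=None):
        super().__init__(solver="lsqr", shrinkage=shrinkage)
        self.delta = delta

    def fit(self, X, y):
        super().fit(X, y)
        if self.delta > 0:
            self.coef_ = np.where(np.abs(self.coef_) < self.delta, 0.0,
                                  self.coef_)
        return self


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """SAMME-style boosting with per-round random undersampling.

    Before each boosting round the majority classes are randomly
    undersampled to the size of the smallest class (sampling within class
    proportional to the current boosting weights), a depth-limited tree is
    fitted on the balanced subsample, and the usual multiclass AdaBoost
    weight update runs on the full training set.
    """

    def __init__(self, n_estimators: int = 30, learning_rate: float = 0.05,
                 max_leaf_nodes: int = 4001, min_samples_split: int = 10,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_leaf_nodes = max_leaf_nodes
        self.min_samples_split = min_samples_split
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        n = len(y)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        counts = np.bincount(yi, minlength=k)
        n_min = int(counts[counts > 0].min())
        self.estimators_: list = []
        self.alphas_: list[float] = []
        for _ in range(self.n_estimators):
            sel: list[int] = []
            for c in range(k):
                members = np.flatnonzero(yi == c)
                if len(members) == 0:
                    continue
                take = min(n_min, len(members))
                p = w[members] / w[members].sum()
                sel.extend(rng.choice(members, size=take, replace=False, p=p)
                           if len(members) > take else members)
            sel = np.asarray(sel)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                min_samples_split=self.min_samples_split,
                random_state=int(rng.integers(2 ** 31)),
            ).fit(X[sel], yi[sel])
            pred = tree.predict(X)
            miss = pred != yi
            err = float(np.sum(w[miss]))
            if err >= 1.0 - 1.0 / k:
                continue  # weak learner no better than chance; resample
            err = max(err, 1e-10)
            alpha = self.learning_rate * (
                math.log((1.0 - err) / err) + math.log(k - 1.0)
            )
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * miss)
            w /= w.sum()
            if err < 1e-9:
                break
        if not self.estimators_:  # degenerate: fall back to one tree
            self.estimators_ = [DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=self.random_state).fit(X, yi)]
            self.alphas_ = [1.0]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            votes[np.arange(X.shape[0]), tree.predict(X)] += alpha
        return self.classes_[np.argmax(votes, axis=1)]


class SoftmaxClassifier(BaseEstimator, ClassifierMixin):
    """Single fully connected softmax layer trained by SGDM/RMSProp/Adam.

    This is the transfer-learning classification head: one dense layer
    from the feature dimension to the classes, cross-entropy loss with an
    L2 penalty on the weights, mini-batches reshuffled every epoch, at most
    ``max_epochs`` epochs, and loss bookkeeping every
    ``validation_frequency`` iterations.  ``momentum`` doubles as the
    momentum (SGDM), squared-gradient decay (RMSProp) or first-moment
    decay (Adam) factor.  Deterministic given ``random_state``.
    """

    def __init__(self, optimizer: str = "ADAM", batch_size: int = 15,
                 learning_rate: float = 0.01, l2: float = 1e-6,
                 momentum: float = 0.9, max_epochs: int = 30,
                 validation_frequency: int = 3, random_state: int = 0):
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.validation_frequency = validation_frequency
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = len(self.classes_)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        rng = np.random.default_rng(self.random_state)
        W = 0.01 * rng.standard_normal((d, k))
        b = np.zeros(k)
        vel_W = np.zeros_like(W)
        vel_b = np.zeros_like(b)
        sq_W = np.zeros_like(W)
        sq_b = np.zeros_like(b)
        opt = self.optimizer.upper()
        if opt not in ("SGDM", "RMSP", "ADAM"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        eps = 1e-8
        beta2 = 0.999
        step = 0
        self.loss_history_ = []
        onehot = np.eye(k)[yi]
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, tb = Xs[idx], onehot[idx]
                logits = xb @ W + b
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                gW = xb.T @ (p - tb) / len(idx) + 2 * self.l2 * W
                gb = (p - tb).mean(axis=0)
                lr = self.learning_rate
                if opt == "SGDM":
                    vel_W = self.momentum * vel_W - lr * gW
                    vel_b = self.momentum * vel_b - lr * gb
                    W, b = W + vel_W, b + vel_b
                elif opt == "RMSP":
                    sq_W = self.momentum * sq_W + (1 - self.momentum) * gW ** 2
                    sq_b = self.momentum * sq_b + (1 - self.momentum) * gb ** 2
                    W = W - lr * gW / (np.sqrt(sq_W) + eps)
                    b = b - lr * gb / (np.sqrt(sq_b) + eps)
                else:  # ADAM
                    step += 1
                    vel_W = self.momentum * vel_W + (1 - self.momentum) * gW
                    vel_b = self.momentum * vel_b + (1 - self.momentum) * gb
                    sq_W = beta2 * sq_W + (1 - beta2) * gW ** 2
                    sq_b = beta2 * sq_b + (1 - beta2) * gb ** 2
                    vw = vel_W / (1 - self.momentum ** step)
                    vb = vel_b / (1 - self.momentum ** step)
                    sw = sq_W / (1 - beta2 ** step)
                    sb = sq_b / (1 - beta2 ** step)
                    W = W - lr * vw / (np.sqrt(sw) + eps)
                    b = b - lr * vb / (np.sqrt(sb) + eps)
                if step % max(self.validation_frequency, 1) == 0:
                    with np.errstate(divide="ignore"):
                        loss = -np.mean(
                            np.log(np.maximum(p[tb.astype(bool)], 1e-300))
                        ) + self.l2 * np.sum(W * W)
                    self.loss_history_.append(float(loss))
                step += 1 if opt != "ADAM" else 0
            if not np.all(np.isfinite(W)):
                raise FloatingPointError("training diverged")
        self.coef_ = W
        self.intercept_ = b
        return self

    def predict(self, X):
        X = (np.asarray(X, dtype=float) - self._mu) / self._sd
        scores = X @ self.coef_ + self.intercept_
        return self.classes_[np.argmax(scores, axis=1)]

    @property
    def weight_norm_(self) -> float:
        return float(np.linalg.norm(self.coef_))


# ---------------------------------------------------------------------------
# Estimator construction from a spec + hyperparameters
# ---------------------------------------------------------------------------

def _space_defaults(space) -> dict:
    return {p.name: p.default() for p in space}


def make_estimator(spec_id: str, params: dict | None = None,
                   random_state: int = 0):
    """Build an unfitted sklearn estimator for a catalog learner.

    ``params`` are hyperparameters from the learner's declared space;
    omitted ones take mid-range defaults.  Standardization and multiclass
    decomposition are realized as a Pipeline scaler and one-vs-one /
    one-vs-rest wrappers.
    """
    spec = get_learner(spec_id)
    hp = _space_defaults(spec.space)
    hp.update(params or {})
    fam = spec.family
    if fam == "knn":
        metric = spec.fixed["distance"]
        kwargs = {"metric": metric}
        if metric == "minkowski":
            kwargs["p"] = spec.fixed["exponent"]
        weights = ("uniform" if spec.fixed["weight"] == "equal"
                   else (lambda d: 1.0 / np.maximum(d, 1e-12) ** 2))
        base = _ClampedKNN(n_neighbors=int(hp["n_neighbors"]),
                           weights=weights, **kwargs)
    elif fam == "tree":
        base = DecisionTreeClassifier(
            max_leaf_nodes=int(hp["max_splits"]) + 1,
            min_samples_split=spec.fixed["min_parent_size"],
            criterion="gini", random_state=random_state,
        )
    elif fam == "svm":
        kwargs = {"kernel": spec.fixed["kernel"], "C": float(hp["cost"])}
        if spec.fixed["kernel"] == "rbf":
            kwargs["gamma"] = 1.0 / float(hp["kernel_scale"]) ** 2
        elif spec.fixed["kernel"] == "poly":
            kwargs.update(degree=spec.fixed["degree"], coef0=1.0,
                          gamma="scale")
        base = SVC(**kwargs)
    elif fam == "discriminant":
        if spec.fixed["type"] == "pseudolinear":
            base = ThresholdedLDA(delta=float(hp["delta"]),
                                  shrinkage=float(hp["gamma"]))
        else:
            base = QuadraticDiscriminantAnalysis(
                reg_param=float(np.clip(hp["gamma"], 1e-6, 1.0)))
    elif fam == "ensemble":
        method = spec.fixed["method"]
        leaf = int(hp["max_splits"]) + 1 if "max_splits" in hp else 4001
        tree = DecisionTreeClassifier(
            max_leaf_nodes=leaf,
            min_samples_split=spec.fixed["min_parent_size"],
            random_state=random_state,
        )
        if method == "bag":
            base = BaggingClassifier(estimator=tree,
                                     n_estimators=int(hp["n_cycles"]),
                                     random_state=random_state)
        elif method == "adaboostm2":
            base = AdaBoostClassifier(
                estimator=tree, n_estimators=int(hp["n_cycles"]),
                learning_rate=float(hp["learning_rate"]),
                random_state=random_state,
            )
        else:
            base = RUSBoostClassifier(
                n_estimators=int(hp["n_cycles"]),
                learning_rate=float(hp["learning_rate"]),
                max_leaf_nodes=leaf,
                min_samples_split=spec.fixed["min_parent_size"],
                random_state=random_state,
            )
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")

    decomp = hp.get("decomposition")
    if decomp == "onevsone":
        base = OneVsOneClassifier(base)
    elif decomp == "onevsall":
        base = OneVsRestClassifier(base)
    steps = []
    if hp.get("standardize") == "yes":
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", base))
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# Expected improvement + Bayesian optimization
# ---------------------------------------------------------------------------

def expected_improvement(mu, sigma, best) -> np.ndarray:
    """Closed-form EI for minimization: E[max(best - f, 0)] under N(mu, sigma^2)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    imp = best - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(sigma > 0,
                      imp * norm.cdf(z) + sigma * norm.pdf(z),
                      np.maximum(imp, 0.0))
    return np.maximum(ei, 0.0)


@dataclass
class HPOConfig:
    budget: int = 30
    folds: int = 5
    seed: int = 0
    n_initial: int = 5
    n_candidates: int = 256

    def __post_init__(self) -> None:
        if self.budget < 5:
            raise ValueError("budget must be at least 5")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")


def _encode(space, params: dict) -> np.ndarray:
    cols = []
    for p in space:
        v = params[p.name]
        if p.kind == "cat":
            cols.extend(1.0 if v == o else 0.0 for o in p.options)
        elif p.log:
            cols.append((math.log(v) - math.log(p.low))
                        / (math.log(p.high) - math.log(p.low)))
        else:
            cols.append((v - p.low) / (p.high - p.low)
                        if p.high > p.low else 0.0)
    return np.asarray(cols)


def _sample(space, rng: np.random.Generator) -> dict:
    out = {}
    for p in space:
        if p.kind == "cat":
            out[p.name] = p.options[rng.integers(len(p.options))]
        elif p.log:
            out[p.name] = float(np.exp(
                rng.uniform(math.log(p.low), math.log(p.high))))
        else:
            v = float(rng.uniform(p.low, p.high))
            if p.kind == "int":
                v = int(np.clip(round(v), p.low, p.high))
            out[p.name] = v
    return out


def bayes_optimize(space, objective, config: HPOConfig | None = None):
    """GP/EI Bayesian minimization over a declarative hyperparameter space.

    Continuous dimensions are normalized (log scale where declared) and
    categoricals one-hot encoded; after a small random initial design, each
    proposal maximizes expected improvement over a random candidate pool.
    When the proposal lands in the incumbent's immediate vicinity twice in
    a row — the over-exploitation signature — the predictive standard
    deviation is inflated tenfold for the next proposal, pushing the search
    back into exploration.  Failed or non-finite evaluations are recorded
    with a large penalty and the search continues.

    Returns ``(best_params, best_value, history)`` with history entries
    ``(params, value)`` in evaluation order.
    """
    config = config or HPOConfig()
    if not space:
        raise ValueError("hyperparameter space is empty")
    rng = np.random.default_rng(config.seed)
    history: list[tuple[dict, float]] = []
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []

    def evaluate(params: dict) -> float:
        try:
            v = float(objective(params))
        except Exception:  # noqa: BLE001
            v = float("nan")
        if not np.isfinite(v):
            v = (max(y_obs) if y_obs else 1.0) + 1.0
        history.append((params, v))
        X_obs.append(_encode(space, params))
        y_obs.append(v)
        return v

    for _ in range(min(config.n_initial, config.budget)):
        evaluate(_sample(space, rng))

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.ones(len(X_obs[0])),
        length_scale_bounds=(1e-2, 1e2), nu=2.5,
    )
    overexploit_count = 0
    sigma_inflation = 1.0
    while len(y_obs) < config.budget:
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-4, normalize_y=True,
            random_state=config.seed, n_restarts_optimizer=0,
        )
        with warnings.catch_warnings():
            # kernel hyperparameters pinned at their bounds are fine here
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(np.vstack(X_obs), np.asarray(y_obs))
        cands = [_sample(space, rng) for _ in range(config.n_candidates)]
        Xc = np.vstack([_encode(space, c) for c in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        ei = expected_improvement(mu, sd * sigma_inflation, min(y_obs))
        pick = cands[int(np.argmax(ei))]
        x_pick = _encode(space, pick)
        x_best = X_obs[int(np.argmin(y_obs))]
        if np.linalg.norm(x_pick - x_best) < 0.05:
            overexploit_count += 1
        else:
            overexploit_count = 0
        sigma_inflation = 10.0 if overexploit_count >= 2 else 1.0
        evaluate(pick)
    i_best = int(np.argmin(y_obs))
    return history[i_best][0], y_obs[i_best], history


# ---------------------------------------------------------------------------
# Training entry points
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    spec_id: str
    hyperparameters: dict
    model: object
    history: list
    classes_: np.ndarray


def _cv_misclassification(build, X, y, folds: int, seed: int) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_splits = min(folds, int(np.min(np.bincount(
        np.unique(y, return_inverse=True)[1]))))
    n_splits = max(n_splits, 2)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    errs = []
    for tr, te in cv.split(X, y):
        model = build()
        model.fit(X[tr], y[tr])
        errs.append(float(np.mean(model.predict(X[te]) != y[te])))
    return float(np.mean(errs))


def train_learner(spec: LearnerSpec | str, X, y,
                  hpo: HPOConfig | None = None) -> TrainedClassifier:
    """Bayesian-optimized training of one catalog ML learner.

    The objective is the stratified k-fold cross-validated
    misclassification rate on the training data; the winning
    hyperparameters are refit on all of it.
    """
    spec = get_learner(spec) if isinstance(spec, str) else spec
    hpo = hpo or HPOConfig()
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    def objective(params: dict) -> float:
        return _cv_misclassification(
            lambda: make_estimator(spec.id, params, random_state=hpo.seed),
            X, y, hpo.folds, hpo.seed,
        )

    best_params, _, history = bayes_optimize(
        spec.space, objective, HPOConfig(
            budget=hpo.budget, folds=hpo.folds, seed=hpo.seed,
            n_initial=hpo.n_initial, n_candidates=hpo.n_candidates,
        ),
    )
    model = make_estimator(spec.id, best_params, random_state=hpo.seed)
    model.fit(X, y)
    return TrainedClassifier(spec.id, best_params, model, history,
                             np.unique(y))


def train_fc(spec: FCSpec | str, X, y,
             hpo: HPOConfig | None = None) -> TrainedClassifier:
    """Bayesian-optimized training of the FC softmax head."""
    if isinstance(spec, str):
        matches = [s for s in fc_catalog()
                   if s.optimizer.lower() == spec.lower()]
        if not matches:
            raise KeyError(f"unknown FC optimizer {spec!r}")
        spec = matches[0]
    hpo = hpo or HPOConfig()
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    def build(params: dict) -> SoftmaxClassifier:
        return SoftmaxClassifier(
            optimizer=spec.optimizer if spec.optimizer != "RMSP" else "RMSP",
            batch_size=int(params["batch_size"]),
            learning_rate=float(params["learning_rate"]),
            l2=float(params["l2"]), momentum=float(params["momentum"]),
            max_epochs=spec.fixed["max_epochs"],
            validation_frequency=spec.fixed["validation_frequency"],
            random_state=hpo.seed,
        )

    def objective(params: dict) -> float:
        return _cv_misclassification(lambda: clone(build(params)),
                                     X, y, hpo.folds, hpo.seed)

    best_params, _, history = bayes_optimize(spec.space, objective, hpo)
    model = build(best_params).fit(X, y)
    return TrainedClassifier(f"FC-{spec.optimizer}", best_params, model,
                             history, np.unique(y))


def predict(clf: TrainedClassifier, X) -> np.ndarray:
    """Predict labels with a trained classifier; one label per row."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.shape[0] == 0:
        return np.asarray([], dtype=clf.classes_.dtype)
    return np.asarray(clf.model.predict(X))
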