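"""The hybrid ensemble: RBF-SVM, fast large-margin linear classifier, and a
random decision tree, combined by majority vote.

The SVM hyperparameters are chosen by an inner cross-validated grid over
gamma in {1e-5, 1e-4, 1e-3} and C in {0.1, 1, 10, 100, 1000, 10000}, with
ties broken toward the smaller C then the smaller gamma.  The fast
large-margin model minimizes the soft-margin objective
tau(w, delta) = 0.5*||w||^2 + C * sum(delta_i) with hinge slack, using a
guarded subgradient descent (a step is only accepted if it lowers the
objective, so the per-epoch objective trace is non-increasing) and early
stopping.  The random tree selects, at every node, the split with the
largest information gain IG = E(parent) - weighted E(children) over a random
feature subset.  Three-way vote ties fall back to the first base model
(the RBF-SVM).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .fixtures_io import FeatureTable, ParameterError

DEFAULT_GAMMA_GRID = (1e-5, 1e-4, 1e-3)
DEFAULT_C_GRID = (0.1, 1, 10, 100, 1000, 10000)

BASE_MODEL_ORDER = ("rbf_svm", "fast_large_margin", "random_tree")


def _as_matrix(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureTable) else np.asarray(X, dtype=float)


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("at least two classes are required")
    return y


# ---------------------------------------------------------------------------
# RBF-SVM with deterministic grid search
# ---------------------------------------------------------------------------

def rbf_kernel_value(x_a, x_b, gamma: float) -> float:
    """k(x_a, x_b) = exp(-gamma * ||x_a - x_b||^2)."""
    d = np.asarray(x_a, dtype=float) - np.asarray(x_b, dtype=float)
    return float(np.exp(-gamma * np.dot(d, d)))


def train_rbf_svm(X, y, C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                  cv_folds: int = 3, seed: int = 0) -> SVC:
    """Soft-margin RBF SVM; (C, gamma) picked by inner-CV accuracy.

    One-vs-one multiclass; the grid is scanned in ascending (C, gamma) order
    and only strict accuracy improvements replace the incumbent, so ties
    resolve to the smaller C then the smaller gamma.
    """
    X, y = _as_matrix(X), _check_labels(y)
    n_splits = min(cv_folds, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    best, best_acc = None, -1.0
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            if n_splits >= 2:
                skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                      random_state=seed)
                accs = []
                for tr, te in skf.split(X, y):
                    m = SVC(C=C, gamma=gamma, kernel="rbf").fit(X[tr], y[tr])
                    accs.append(np.mean(m.predict(X[te]) == y[te]))
                acc = float(np.mean(accs))
            else:
                m = SVC(C=C, gamma=gamma, kernel="rbf").fit(X, y)
                acc = float(np.mean(m.predict(X) == y))
            if acc > best_acc:
                best, best_acc = (C, gamma), acc
    C, gamma = best
    model = SVC(C=C, gamma=gamma, kernel="rbf",
                decision_function_shape="ovr").fit(X, y)
    model.cv_accuracy_ = best_acc
    return model


# ---------------------------------------------------------------------------
# fast large margin (linear soft-margin, guarded subgradient)
# ---------------------------------------------------------------------------

@dataclass
class _BinaryLinear:
    w: np.ndarray
    b: float
    objective_history: list


def _fit_binary_linear(X, y_pm, C, max_iter, tol) -> _BinaryLinear:
    """Minimize 0.5||w||^2 + C sum hinge; accept-only-if-improved steps."""
    n, d = X.shape

    def objective(w, b):
        margins = y_pm * (X @ w + b)
        return 0.5 * np.dot(w, w) + C * np.sum(np.maximum(0.0, 1.0 - margins))

    w = np.zeros(d)
    b = 0.0
    step = 1.0 / (C * n + 1.0)
    obj = objective(w, b)
    history = [obj]
    for _ in range(max_iter):
        margins = y_pm * (X @ w + b)
        viol = margins < 1.0
        gw = w - C * (y_pm[viol] @ X[viol])
        gb = -C * np.sum(y_pm[viol])
        # backtrack until the objective decreases
        improved = False
        t = step
        while t > 1e-14:
            w2, b2 = w - t * gw, b - t * gb
            o2 = objective(w2, b2)
            if o2 < obj:
                w, b, obj = w2, b2, o2
                step = t * 2.0
                improved = True
                break
            t *= 0.5
        history.append(obj)
        if not improved:
            break
        if len(history) > 1 and history[-2] > 0 and \
                (history[-2] - obj) / max(history[-2], 1e-12) < tol:
            break
    return _BinaryLinear(w, b, history)


@dataclass
class FastLargeMargin:
    """One-vs-rest linear large-margin classifier."""

    C: float = 10.0
    max_iter: int = 1000
    tol: float = 1e-6
    classes_: np.ndarray | None = None
    models_: dict = field(default_factory=dict)

    def fit(self, X, y) -> "FastLargeMargin":
        X, y = _as_matrix(X), _check_labels(y)
        self.classes_ = np.unique(y)
        for cls in self.classes_:
            y_pm = np.where(y == cls, 1.0, -1.0)
            self.models_[cls] = _fit_binary_linear(X, y_pm, self.C,
                                                   self.max_iter, self.tol)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return np.column_stack([X @ self.models_[c].w + self.models_[c].b
                                for c in self.classes_])

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def margins(self, X, y) -> np.ndarray:
        """Per-sample margin rho = y * f(x) for the sample's own class model."""
        X = _as_matrix(X)
        y = np.asarray(y)
        out = np.empty(len(y))
        for r in range(len(y)):
            m = self.models_[y[r]]
            out[r] = float(X[r] @ m.w + m.b)
        return out


def train_fast_large_margin(X, y, C: float = 10.0, max_iter: int = 1000,
                            tol: float = 1e-6, seed: int = 0) -> FastLargeMargin:
    """Fit the one-vs-rest fast large-margin classifier (deterministic)."""
    return FastLargeMargin(C=C, max_iter=max_iter, tol=tol).fit(X, y)


# ---------------------------------------------------------------------------
# random decision tree
# ---------------------------------------------------------------------------

def entropy(counts) -> float:
    """Shannon entropy in bits of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def information_gain(parent_counts, child_counts_list) -> float:
    """IG = E(parent) - size-weighted average entropy of the children."""
    parent_counts = np.asarray(parent_counts, dtype=float)
    n = parent_counts.sum()
    child_e = sum(np.sum(c) / n * entropy(c) for c in child_counts_list)
    return entropy(parent_counts) - float(child_e)


class _ConstantModel:
    """Depth-0 tree for single-class training data."""

    def __init__(self, label):
        self.label = label
        self.classes_ = np.array([label])

    def predict(self, X):
        return np.full(len(_as_matrix(X)), self.label)


def train_random_tree(X, y, max_depth: int | None = None,
                      feature_subsample: str | float = "sqrt", seed: int = 0):
    """Single entropy/IG decision tree with per-node random feature subsets.

    A split is only accepted if it increases information gain; single-class
    training data yields a depth-0 constant predictor.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return _ConstantModel(y[0])
    return DecisionTreeClassifier(criterion="entropy", max_depth=max_depth,
                                  max_features=feature_subsample,
                                  random_state=seed).fit(X, y)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def majority_vote(votes) -> object:
    """Modal label of an ordered vote triple; 3-way ties go to the first
    base model's vote."""
    counts = Counter(votes)
    top = counts.most_common(1)[0][1]
    if top == 1:  # all different
        return votes[0]
    # unique winner (3 votes cannot produce a 2-2 tie)
    return counts.most_common(1)[0][0]


@dataclass
class TrainedEnsemble:
    base_models: dict
    label_codebook: list
    seed: int


@dataclass
class Prediction:
    base_votes: tuple
    final_label: object
    vote_fractions: dict


def ensemble_fit(X, y, config: dict | None = None, seed: int = 0) -> TrainedEnsemble:
    """Train all three base models on identical rows."""
    config = config or {}
    X = _as_matrix(X)
    y = _check_labels(y)
    svm = train_rbf_svm(X, y, seed=seed, **config.get("svm", {}))
    flm = train_fast_large_margin(X, y, seed=seed, **config.get("flm", {}))
    tree = train_random_tree(X, y, seed=seed, **config.get("tree", {}))
    return TrainedEnsemble(
        base_models={"rbf_svm": svm, "fast_large_margin": flm,
                     "random_tree": tree},
        label_codebook=sorted(np.unique(y).tolist()),
        seed=seed,
    )


def ensemble_predict(model: TrainedEnsemble, X) -> list:
    """Row-wise majority vote over the three base models."""
    X = _as_matrix(X)
    votes = np.column_stack([model.base_models[name].predict(X)
                             for name in BASE_MODEL_ORDER])
    out = []
    for row in votes:
        counts = Counter(row.tolist())
        final = majority_vote(tuple(row.tolist()))
        fractions = {lab: counts.get(lab, 0) / 3.0
                     for lab in model.label_codebook}
        out.append(Prediction(tuple(row.tolist()), final, fractions))
    return out


def ensemble_scores(model: TrainedEnsemble, X) -> np.ndarray:
    """Continuous per-class scores: vote fractions averaged with a softmax of
    the SVM one-vs-rest decision values (for ROC curves)."""
    X = _as_matrix(X)
    preds = ensemble_predict(model, X)
    frac = np.array([[p.vote_fractions[lab] for lab in model.label_codebook]
                     for p in preds])
    svm = model.base_models["rbf_svm"]
    dec = svm.decision_function(X)
    if dec.ndim == 1:  # binary: expand to two columns
        dec = np.column_stack([-dec, dec])
    # align SVC class order with the codebook
    order = [list(svm.classes_).index(lab) for lab in model.label_codebook]
    dec = dec[:, order]
    e = np.exp(dec - dec.max(axis=1, keepdims=True))
    soft = e / e.sum(axis=1, keepdims=True)
    return 0.5 * frac + 0.5 * soft
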