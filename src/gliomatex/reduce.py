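"""Feature fusion and non-negative matrix factorization (NMF) reduction.

Fusion concatenates the per-family feature blocks column-wise and min-max
scales every column to [0, 1] with statistics frozen on the training split
(NMF needs non-negative input, and test rows must see exactly the training
transform).  The NMF itself is a seeded multiplicative-update solver that
minimizes the Frobenius reconstruction error ||X - WH||_F and records the
error after every iteration; W is the reduced representation, H the loading
of each original feature on the k latent components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .fixtures_io import FeatureTable, ParameterError

_EPS = 1e-12


# ---------------------------------------------------------------------------
# fusion / scaling
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaler:
    """Column-wise min-max to [0, 1]; constant columns map to 0."""

    mins: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.mins = X.min(axis=0)
        rng = X.max(axis=0) - self.mins
        rng[rng == 0] = 1.0
        self.ranges = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise ParameterError("scaler not fitted")
        return np.clip((np.asarray(X, dtype=float) - self.mins) / self.ranges,
                       0.0, 1.0)


def fuse_features(blocks: dict, scaler: MinMaxScaler | None = None):
    """Concatenate named feature blocks and min-max scale to [0, 1].

    ``blocks`` maps family name -> FeatureTable; rows must be aligned across
    blocks.  Returns ``(FeatureTable, scaler)``; pass a fitted ``scaler`` to
    reapply frozen training statistics to new rows.
    """
    names = list(blocks)
    n_rows = {name: blocks[name].n_rows for name in names}
    if len(set(n_rows.values())) != 1:
        bad = ", ".join(f"{k}={v}" for k, v in n_rows.items())
        raise ParameterError(f"blocks are not row-aligned: {bad}")
    cols, mats = [], []
    labels = groups = None
    for name in names:
        t = blocks[name]
        cols.extend(c if c.startswith(name + ".") else f"{name}.{c}"
                    for c in t.column_names)
        mats.append(t.values)
        labels = labels if labels is not None else t.labels
        groups = groups if groups is not None else t.groups
    X = np.hstack(mats)
    if scaler is None:
        scaler = MinMaxScaler().fit(X)
    return FeatureTable(scaler.transform(X), cols, labels=labels,
                        groups=groups), scaler


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

@dataclass
class ReducedBasis:
    """NMF factor pair: X (n x m) ~ W (n x k) @ H (k x m), all non-negative."""

    W: np.ndarray
    H: np.ndarray
    k: int
    fit_error: float
    error_history: list = field(default_factory=list)


def nmf_fit(X, k: int = 32, max_iter: int = 500, tol: float = 1e-4,
            seed: int = 0) -> ReducedBasis:
    """Multiplicative-update NMF minimizing the Frobenius error.

    W and H are initialized uniform on [0, 1] scaled by sqrt(mean(X)/k) with
    a seeded generator, so fits are bitwise reproducible.  Iteration stops at
    ``max_iter`` or when the relative error change drops below ``tol``.  The
    Frobenius error after each full update is recorded in ``error_history``
    (multiplicative updates make it non-increasing).
    """
    X = X.values if isinstance(X, FeatureTable) else np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ParameterError("NMF input must be non-negative")
    n, m = X.shape
    if k < 1:
        raise ParameterError("k must be >= 1")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, (n, k)) * scale
    H = rng.uniform(0.0, 1.0, (k, m)) * scale

    history = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(X - W @ H))
        history.append(err)
        if prev is not None and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err
    return ReducedBasis(W, H, k, history[-1], history)


def nmf_transform(basis: ReducedBasis, x_new) -> np.ndarray:
    """Project new non-negative rows onto the fitted basis.

    Solves the non-negative least squares min ||x - w H||_F per row.
    """
    x_new = x_new.values if isinstance(x_new, FeatureTable) \
        else np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != basis.H.shape[1]:
        raise ParameterError(
            f"row width {x_new.shape[1]} != basis width {basis.H.shape[1]}")
    if np.any(x_new < 0):
        raise ParameterError("NMF input must be non-negative")
    A = basis.H.T  # (m, k)
    W = np.empty((x_new.shape[0], basis.k))
    for r, row in enumerate(x_new):
        W[r], _ = nnls(A, row)
    return W


def reduced_table(basis: ReducedBasis, table: FeatureTable,
                  refit_rows: np.ndarray | None = None) -> FeatureTable:
    """Wrap reduced rows as a FeatureTable with ``nmf.c{j}`` columns."""
    rows = basis.W if refit_rows is None else refit_rows
    return FeatureTable(rows, [f"nmf.c{j}" for j in range(basis.k)],
                        labels=table.labels, groups=table.groups)


def sweep_k(X: FeatureTable, k_grid, cv_folds: int = 5, seed: int = 0,
            max_iter: int = 300) -> tuple:
    """Mean CV accuracy of the downstream ensemble for each NMF rank k.

    Returns ``(table, best_k)`` where ``table`` is a list of
    ``{"k": k, "accuracy": acc}`` rows and ``best_k`` the argmax (first on
    ties).  The NMF and ensemble are refit inside every training fold.
    """
    from sklearn.model_selection import StratifiedKFold

    from .classify import ensemble_fit, ensemble_predict

    if X.labels is None:
        raise ParameterError("sweep_k needs a labeled table")
    y = np.asarray(X.labels)
    rows = []
    for k in k_grid:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X.values, y):
            scaler = MinMaxScaler().fit(X.values[tr])
            Xtr, Xte = scaler.transform(X.values[tr]), scaler.transform(X.values[te])
            basis = nmf_fit(Xtr, k=k, max_iter=max_iter, seed=seed)
            Wtr, Wte = basis.W, nmf_transform(basis, Xte)
            model = ensemble_fit(Wtr, y[tr], seed=seed)
            pred = ensemble_predict(model, Wte)
            accs.append(float(np.mean([p.final_label for p in pred] == y[te])))
        rows.append({"k": int(k), "accuracy": float(np.mean(accs))})
    best = max(rows, key=lambda r: r["accuracy"])["k"]
    return rows, best
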