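"""PLS1 regression engine (NIPALS) and latent-variable selection.

This is the foundation every transfer method in the package builds on.
The calibration model of the master instrument is an ordinary PLS1
regression fit by NIPALS on mean-centered spectra ``X`` and property
``y``::

    X = T P' + E,   y = T q' + f,   beta = W (P' W)^{-1} q'

with unit-norm weight vectors ``W`` and X-deflation only. Channels are
centered but never autoscaled, the NIR convention. Predictions are
``y_mean + (X - x_mean) beta``, and projecting any spectra block through
``W (P' W)^{-1}`` yields its coordinates ("predicted features") in the
model's PLS subspace — the operation the subspace transfer method is
built on.

The number of latent variables is chosen by 10-fold cross-validation
with the Haaland–Thomas PRESS-ratio F-test: the smallest A whose PRESS
is not significantly worse than the global minimum at alpha = 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .exceptions import DegenerateInputError, ParameterError, ShapeError
from .spectra import SpectraSet

__all__ = ["PLS1Model", "fit_pls1", "predict", "project_scores", "select_lv_cv"]


@dataclass
class PLS1Model:
    """A fitted PLS1 calibration model.

    Attributes
    ----------
    A:
        Number of latent variables retained.
    x_mean, y_mean:
        Centering vector/value of the calibration data.
    W, P:
        p x A weight and X-loading matrices (W columns unit-norm).
    q:
        Length-A y-loading vector.
    beta:
        Length-p regression vector, ``W (P' W)^{-1} q'``.
    train_residual_norms:
        ``(||E_a||_F, ||f_a||_2)`` after each component, diagnostic.
    """

    A: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    beta: np.ndarray
    train_residual_norms: list[tuple[float, float]]

    @property
    def p(self) -> int:
        return self.x_mean.size

    def rotation(self, k: int | None = None) -> np.ndarray:
        """``W (P' W)^{-1}``, optionally truncated to the first k columns."""
        k = self.A if k is None else k
        R = np.linalg.solve((self.P.T @ self.W).T, self.W.T).T
        return R[:, :k]

    def predict(self, X) -> np.ndarray:
        return predict(self, X)

    def project_scores(self, X, k: int | None = None) -> np.ndarray:
        return project_scores(self, X, self.A if k is None else k)

    # ------------------------------------------------------------ JSON

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "A": int(self.A),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "beta": self.beta.tolist(),
            "train_residual_norms": [list(t) for t in self.train_residual_norms],
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "PLS1Model":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            A=int(d["A"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            W=np.asarray(d["W"], dtype=float),
            P=np.asarray(d["P"], dtype=float),
            q=np.asarray(d["q"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            train_residual_norms=[tuple(t) for t in d["train_residual_norms"]],
        )


def _as_matrix(X, p: int | None = None) -> np.ndarray:
    """Coerce a SpectraSet, row vector or matrix to (n, p) float array."""
    if isinstance(X, SpectraSet):
        X = X.X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if p is not None and X.shape[1] != p:
        raise ShapeError(f"spectra have {X.shape[1]} channels, model expects {p}")
    return X


def _nipals(Xc: np.ndarray, yc: np.ndarray, A: int, tol: float = 1e-13):
    """Step NIPALS on pre-centered data; may stop early on rank exhaustion.

    Returns (W, P, q, T, residual_norms, n_extracted).
    """
    n, p = Xc.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    norms: list[tuple[float, float]] = []
    E = Xc.copy()
    f = yc.copy()
    x_scale = max(np.linalg.norm(Xc), 1.0)
    y_scale = max(np.linalg.norm(yc), 1.0)
    a = 0
    for a in range(A):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= tol * x_scale * y_scale:
            break  # residual carries no covariance left
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= (tol * x_scale) ** 2:
            break
        P[:, a] = E.T @ t / tt
        q[a] = float(f @ t) / tt
        W[:, a] = w
        T[:, a] = t
        E -= np.outer(t, P[:, a])
        f -= q[a] * t
        norms.append((float(np.linalg.norm(E)), float(np.linalg.norm(f))))
    else:
        a = A
    k = a if a < A else A
    return W[:, :k], P[:, :k], q[:k], T[:, :k], norms, k


def fit_pls1(data: SpectraSet, A: int) -> PLS1Model:
    """Fit a PLS1 model with ``A`` latent variables by NIPALS.

    Raises
    ------
    ParameterError
        If ``A`` is not in ``1..min(n-1, p)``.
    DegenerateInputError
        If X or y has no variance.
    """
    if data.y is None:
        raise ParameterError("fit_pls1 requires reference values y")
    n, p = data.X.shape
    if not (1 <= A <= min(n - 1, p)):
        raise ParameterError(f"A={A} outside 1..min(n-1={n-1}, p={p})")
    x_mean = data.X.mean(axis=0)
    y_mean = float(data.y.mean())
    Xc = data.X - x_mean
    yc = data.y - y_mean
    if np.linalg.norm(Xc) == 0.0:
        raise DegenerateInputError("X has zero variance")
    if np.linalg.norm(yc) == 0.0:
        raise DegenerateInputError("y is constant")
    W, P, q, _, norms, k = _nipals(Xc, yc, A)
    if k == 0:
        raise DegenerateInputError("no PLS component could be extracted")
    if k < A:
        warnings.warn(
            f"rank exhausted after {k} components (requested {A}); model truncated",
            stacklevel=2,
        )
    beta = (np.linalg.solve((P.T @ W).T, W.T).T @ q).ravel()
    return PLS1Model(
        A=k, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q, beta=beta,
        train_residual_norms=norms,
    )


def predict(model: PLS1Model, X) -> np.ndarray:
    """Predicted property values, ``y_mean + (X - x_mean) beta``."""
    Xm = _as_matrix(X, model.p)
    return model.y_mean + (Xm - model.x_mean) @ model.beta


def project_scores(model: PLS1Model, X, k: int) -> np.ndarray:
    """Project spectra into the model's PLS subspace (first k score columns).

    This single operation yields both the predicted features of master
    spectra and the *pseudo* predicted features of slave spectra,
    depending on which block is passed; centering always uses the master
    calibration mean.
    """
    if not (1 <= k <= model.A):
        raise ParameterError(f"k={k} outside 1..A={model.A}")
    Xm = _as_matrix(X, model.p)
    return (Xm - model.x_mean) @ model.rotation(k)


def _press_curve(
    data: SpectraSet, A_max: int, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Cross-validated PRESS for A = 1..A_max with a seeded fold shuffle."""
    n = data.n
    order = rng.permutation(n)
    fold_idx = np.array_split(order, folds)
    press = np.zeros(A_max)
    for val in fold_idx:
        train = np.setdiff1d(order, val)
        cap = min(train.size - 1, data.p)
        if A_max > cap:
            raise ParameterError(
                f"A_max={A_max} exceeds min(train size - 1, p)={cap} for a fold"
            )
        Xt, yt = data.X[train], data.y[train]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, q, _, _, k = _nipals(Xt - xm, yt - ym, A_max)
        Xv = data.X[val] - xm
        yv = data.y[val]
        for A in range(1, A_max + 1):
            a = min(A, k)  # beyond effective rank the fit is flat
            beta = np.linalg.solve((P[:, :a].T @ W[:, :a]).T, W[:, :a].T).T @ q[:a]
            press[A - 1] += float(np.sum((ym + Xv @ beta - yv) ** 2))
    return press


def select_lv_cv(
    data: SpectraSet,
    A_max: int,
    folds: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> int:
    """Select the number of latent variables by k-fold CV plus an F-test.

    Computes PRESS(A) for A = 1..A_max over seeded folds, then returns
    the smallest A whose PRESS ratio to the global minimum passes
    ``F(PRESS(A)/PRESS(A*)) <= F_{1-alpha}(n, n)`` — the parsimonious
    choice that is not significantly worse than the best.
    """
    if data.y is None:
        raise ParameterError("select_lv_cv requires reference values y")
    if not (2 <= folds <= data.n):
        raise ParameterError(f"folds={folds} outside 2..n={data.n}")
    if A_max < 1:
        raise ParameterError("A_max must be >= 1")
    rng = np.random.default_rng(seed)
    press = _press_curve(data, A_max, folds, rng)
    best = float(press.min())
    if best == 0.0:
        return int(np.flatnonzero(press == 0.0)[0]) + 1
    f_crit = scipy.stats.f.ppf(1.0 - alpha, data.n, data.n)
    passing = np.flatnonzero(press / best <= f_crit)
    return int(passing[0]) + 1
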