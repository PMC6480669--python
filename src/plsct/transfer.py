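"""Calibration transfer in the master model's PLS subspace (PLSCT).

The master instrument's PLS1 model defines a low-dimensional feature
space. Both instruments' measurements of the shared standard samples
are projected into it through the master rotation ``W (P' W)^{-1}``:
the master block gives the predicted feature matrix ``T_hat``, the
slave block the *pseudo* predicted feature matrix ``T_til`` (pseudo
because the projection was not built for that instrument). An ordinary
least squares map aligning ``T_til xi + b ~= T_hat`` is then the entire
transfer model; slave spectra are predicted by projecting, transferring
the features and recombining with the master y-loadings:

    y_hat = y_mean + ((X_slave - x_mean) W (P' W)^{-1} xi + b) q'

No reference values of the standard set are used anywhere.

Note on the intercept ``b``: when the feature maps are written on raw
(uncentered) spectra, the constant component of the raw scores gives
the k x k map one effective affine degree of freedom, which is what
lets the transfer absorb additive baseline differences between the
instruments. With centered projections (used throughout this package
so that subspace coordinates compose with the prediction equation),
that same degree of freedom must be carried explicitly as an intercept
vector; dropping it (``intercept=False``) leaves a pure linear map that
cannot correct a baseline offset.

The retained factor count k truncates the projection, ``xi`` and ``q``
consistently (set ``k = master.A`` for the untruncated variant); k is
selected by leave-one-out cross-validation on the standard set against
a pseudo response — the master model's own predictions of the master
standard spectra.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import PairingError, ParameterError
from .pls import PLS1Model, _as_matrix, predict, project_scores

__all__ = [
    "TransferModel", "fit_plsct", "select_k_loocv", "predict_transfer", "fit_plsct_auto",
]


@dataclass
class TransferModel:
    """PLSCT artifact: master model reference, factor count, xi and b.

    ``k_selection_curve`` keeps the LOO RMSECV per candidate k when the
    model came from :func:`fit_plsct_auto` (diagnostic only).
    """

    master: PLS1Model
    k: int
    xi: np.ndarray
    intercept: np.ndarray
    k_selection_curve: np.ndarray | None = field(default=None)

    def predict(self, X_slave) -> np.ndarray:
        return predict_transfer(self, X_slave)

    def to_json(self, path: str | Path | None = None, master_file: str = "") -> dict:
        d = {
            "k": int(self.k),
            "xi": self.xi.ravel().tolist(),
            "xi_shape": list(self.xi.shape),
            "intercept": self.intercept.tolist(),
            "master_file": master_file,
            "k_selection_curve": (
                None if self.k_selection_curve is None else self.k_selection_curve.tolist()
            ),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict, master: PLS1Model) -> "TransferModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        curve = d.get("k_selection_curve")
        return cls(
            master=master,
            k=int(d["k"]),
            xi=np.asarray(d["xi"], dtype=float).reshape(d["xi_shape"]),
            intercept=np.asarray(d["intercept"], dtype=float),
            k_selection_curve=None if curve is None else np.asarray(curve, dtype=float),
        )


def _solve_xi(
    T_til: np.ndarray, T_hat: np.ndarray, intercept: bool, warn: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """OLS solution of T_til xi (+ 1 b') = T_hat; min-norm if rank deficient."""
    k = T_til.shape[1]
    D = np.hstack([T_til, np.ones((T_til.shape[0], 1))]) if intercept else T_til
    sol, _, rank, _ = np.linalg.lstsq(D, T_hat, rcond=None)
    if warn and rank < D.shape[1]:
        warnings.warn(
            f"standard-set scores are rank deficient (rank {rank} < {D.shape[1]}); "
            "using the minimum-norm least-squares solution",
            stacklevel=3,
        )
    if intercept:
        return sol[:-1], sol[-1]
    return sol, np.zeros(k)


def fit_plsct(
    master: PLS1Model, std_master, std_slave, k: int, intercept: bool = True
) -> TransferModel:
    """Estimate the k x k transfer matrix xi from a paired standard set.

    Both blocks are projected into the master PLS subspace (master-mean
    centering); xi (and, by default, the intercept b) is the OLS map
    from slave pseudo features to master features. Reference values are
    never consumed.
    """
    Sm = _as_matrix(std_master, master.p)
    Ss = _as_matrix(std_slave, master.p)
    if Sm.shape[0] != Ss.shape[0]:
        raise PairingError(
            f"standard blocks are not paired: {Sm.shape[0]} master vs {Ss.shape[0]} slave rows"
        )
    if not (1 <= k <= master.A):
        raise ParameterError(f"k={k} outside 1..A={master.A}")
    if Sm.shape[0] < k:
        raise ParameterError(f"need at least k={k} standard samples, got {Sm.shape[0]}")
    T_hat = project_scores(master, Sm, k)
    T_til = project_scores(master, Ss, k)
    xi, b = _solve_xi(T_til, T_hat, intercept)
    return TransferModel(master=master, k=k, xi=xi, intercept=b)


def predict_transfer(tm: TransferModel, X_slave) -> np.ndarray:
    """Predict slave spectra through the transferred subspace features."""
    T = project_scores(tm.master, X_slave, tm.k)
    return tm.master.y_mean + (T @ tm.xi + tm.intercept) @ tm.master.q[: tm.k]


def select_k_loocv(
    master: PLS1Model,
    std_master,
    std_slave,
    k_max: int | None = None,
    intercept: bool = True,
) -> tuple[int, np.ndarray]:
    """Choose the factor count k by leave-one-out CV on the standard set.

    The held-out pseudo response is the master model's (full-A)
    prediction of the held-out MASTER standard spectrum, computed once;
    the master model is never refit. Candidates run from 1 to
    ``min(master.A, n_std - 1)`` (the LOO training size). Returns
    ``(k, rmsecv_curve)`` with the smallest k within 1e-10 relative
    RMSECV of the minimum.
    """
    Sm = _as_matrix(std_master, master.p)
    Ss = _as_matrix(std_slave, master.p)
    if Sm.shape[0] != Ss.shape[0]:
        raise PairingError("standard blocks are not paired")
    n = Sm.shape[0]
    if n < 3:
        raise ParameterError(f"need at least 3 standard samples for LOO selection, got {n}")
    cap = min(master.A, n - 1)
    if k_max is not None:
        cap = min(cap, k_max)
    pseudo = predict(master, Sm)  # fixed full-model pseudo response
    T_hat = project_scores(master, Sm, cap)
    T_til = project_scores(master, Ss, cap)
    rmsecv = np.empty(cap)
    for k in range(1, cap + 1):
        sq = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            xi, b = _solve_xi(T_til[keep, :k], T_hat[keep, :k], intercept, warn=False)
            pred = master.y_mean + (T_til[i, :k] @ xi + b) @ master.q[:k]
            sq += (pred - pseudo[i]) ** 2
        rmsecv[k - 1] = np.sqrt(sq / n)
    best = float(rmsecv.min())
    tol = 1e-10 * max(best, np.finfo(float).tiny)
    k_sel = int(np.flatnonzero(rmsecv <= best + tol)[0]) + 1
    return k_sel, rmsecv


def fit_plsct_auto(
    master: PLS1Model, std_master, std_slave, intercept: bool = True
) -> TransferModel:
    """LOO-select k, then fit; the RMSECV curve is kept on the model."""
    k, curve = select_k_loocv(master, std_master, std_slave, intercept=intercept)
    tm = fit_plsct(master, std_master, std_slave, k, intercept=intercept)
    tm.k_selection_curve = curve
    return tm
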