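"""Classical calibration-transfer comparators.

Five standard methods against which the subspace transfer is
benchmarked, each correcting a different stage of the prediction
pipeline:

* **PDS** (piecewise direct standardization) — corrects slave *spectra*:
  each master channel is regressed on a sliding window of slave
  channels over the standard set, yielding a banded transfer matrix.
  A window spanning the whole axis is classical DS.
* **SBC** (slope and bias correction) — corrects *predicted values* by
  inverting the OLS line fitted between the master model's predictions
  of the slave standards and their reference values. It is the only
  method that consumes standard-set reference values.
* **GLSW** (generalized least squares weighting) — a spectral filter
  built from the master-slave difference matrix of the standard set
  that down-weights inter-instrument variation; the model is refit on
  filtered calibration spectra.
* **CCACT** — canonical correlation analysis between the paired
  standard blocks; slave spectra are mapped through the slave canonical
  variates, rescaled pair-by-pair, and reconstructed in master spectral
  space.
* **MSC** (multiplicative signal correction) — standard-free
  preprocessing: every spectrum is regressed on a reference spectrum
  and corrected as ``(x - b)/a``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DegenerateInputError, PairingError, ParameterError
from .pls import _as_matrix

__all__ = [
    "PDSModel", "SBCModel", "GLSWModel", "CCACTModel",
    "fit_pds", "apply_pds", "fit_sbc", "apply_sbc",
    "fit_glsw", "apply_glsw", "fit_ccact", "transfer_ccact", "msc_correct",
]


def _check_paired(Sm: np.ndarray, Ss: np.ndarray) -> None:
    if Sm.shape[0] != Ss.shape[0]:
        raise PairingError(
            f"standard blocks are not paired: {Sm.shape[0]} vs {Ss.shape[0]} rows"
        )
    if Sm.shape[1] != Ss.shape[1]:
        raise PairingError(
            f"standard blocks differ in channels: {Sm.shape[1]} vs {Ss.shape[1]}"
        )


# --------------------------------------------------------------------- PDS


@dataclass
class PDSModel:
    """Banded spectral transfer matrix with per-channel intercepts."""

    F: np.ndarray  # p x p, zero outside the band
    intercepts: np.ndarray  # length p
    window: int

    def to_json(self, path: str | Path | None = None) -> dict:
        rows, cols = np.nonzero(self.F)
        d = {
            "window": int(self.window),
            "p": int(self.F.shape[0]),
            "band": [
                [int(r), int(c), float(v)]
                for r, c, v in zip(rows, cols, self.F[rows, cols])
            ],
            "intercepts": self.intercepts.tolist(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "PDSModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        F = np.zeros((d["p"], d["p"]))
        for r, c, v in d["band"]:
            F[r, c] = v
        return cls(F=F, intercepts=np.asarray(d["intercepts"], dtype=float),
                   window=int(d["window"]))


def fit_pds(std_master, std_slave, window: int) -> PDSModel:
    """Fit piecewise direct standardization on a paired standard set.

    For each master channel j, OLS (with intercept) of the master
    channel on the slave channels in a width-``window`` band centered on
    j; windows are clipped (asymmetric) at the axis edges rather than
    zero-padded. Rank-deficient local problems take the minimum-norm
    solution.
    """
    Sm = _as_matrix(std_master)
    Ss = _as_matrix(std_slave)
    _check_paired(Sm, Ss)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    n, p = Ss.shape
    half = (window - 1) // 2
    F = np.zeros((p, p))
    b0 = np.zeros(p)
    ones = np.ones((n, 1))
    for j in range(p):
        lo, hi = max(0, j - half), min(p, j + half + 1)
        A = np.hstack([Ss[:, lo:hi], ones])
        coef, _, _, _ = np.linalg.lstsq(A, Sm[:, j], rcond=None)
        F[lo:hi, j] = coef[:-1]
        b0[j] = coef[-1]
    return PDSModel(F=F, intercepts=b0, window=window)


def apply_pds(model: PDSModel, X_slave) -> np.ndarray:
    """Correct slave spectra toward master space: ``X F + intercepts``."""
    X = _as_matrix(X_slave, model.F.shape[0])
    return X @ model.F + model.intercepts


# --------------------------------------------------------------------- SBC


@dataclass
class SBCModel:
    """Slope/bias of master-model predictions versus reference values."""

    slope: float
    bias: float

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {"slope": self.slope, "bias": self.bias}
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SBCModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(slope=float(d["slope"]), bias=float(d["bias"]))


def fit_sbc(yhat_slave_std, y_std) -> SBCModel:
    """OLS fit ``yhat = slope * y + bias`` over the standard samples."""
    yhat = np.asarray(yhat_slave_std, dtype=float).ravel()
    y = np.asarray(y_std, dtype=float).ravel()
    if yhat.size != y.size:
        raise PairingError(f"{yhat.size} predictions vs {y.size} references")
    yc = y - y.mean()
    denom = float(yc @ yc)
    if denom == 0.0:
        raise DegenerateInputError("reference values are constant")
    slope = float(yc @ (yhat - yhat.mean())) / denom
    if slope == 0.0 or not np.isfinite(slope):
        raise DegenerateInputError("degenerate slope in SBC fit")
    bias = float(yhat.mean() - slope * y.mean())
    return SBCModel(slope=slope, bias=bias)


def apply_sbc(model: SBCModel, yhat) -> np.ndarray:
    """Invert the fitted line: corrected = (yhat - bias) / slope."""
    return (np.asarray(yhat, dtype=float) - model.bias) / model.slope


# -------------------------------------------------------------------- GLSW


@dataclass
class GLSWModel:
    """Symmetric PSD spectral filter built from master-slave differences.

    With ``D = std_master - std_slave`` and SVD ``D = U S V'``, the
    filter shrinks each difference direction by ``1/sqrt(s^2/alpha + 1)``
    and is the identity on the orthogonal complement.
    """

    V: np.ndarray  # p x r difference directions
    shrink: np.ndarray  # length r, in (0, 1]
    alpha: float

    @property
    def G(self) -> np.ndarray:
        p = self.V.shape[0]
        return np.eye(p) - self.V @ np.diag(1.0 - self.shrink) @ self.V.T

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {"V": self.V.tolist(), "shrink": self.shrink.tolist(), "alpha": self.alpha}
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "GLSWModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(V=np.asarray(d["V"], dtype=float),
                   shrink=np.asarray(d["shrink"], dtype=float), alpha=float(d["alpha"]))


def fit_glsw(std_master, std_slave, alpha: float = 0.02) -> GLSWModel:
    if alpha <= 0:
        raise ParameterError(f"alpha must be positive, got {alpha}")
    Sm = _as_matrix(std_master)
    Ss = _as_matrix(std_slave)
    _check_paired(Sm, Ss)
    D = Sm - Ss
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    keep = s > 1e-12 * max(s[0] if s.size else 0.0, 1e-300)
    s = s[keep]
    V = Vt[keep].T
    shrink = 1.0 / np.sqrt(s**2 / alpha + 1.0)
    return GLSWModel(V=V, shrink=shrink, alpha=alpha)


def apply_glsw(model: GLSWModel, X) -> np.ndarray:
    """Filter spectra: project out-and-shrink the difference directions."""
    Xm = _as_matrix(X, model.V.shape[0])
    return Xm - (Xm @ model.V) @ np.diag(1.0 - model.shrink) @ model.V.T


# ------------------------------------------------------------------- CCACT


@dataclass
class CCACTModel:
    """Canonical-correlation transfer of slave spectra to master space."""

    mean_master: np.ndarray
    mean_slave: np.ndarray
    W_slave: np.ndarray  # p x c slave canonical weights
    scaling: np.ndarray  # per-pair OLS scaling, length c
    back_map: np.ndarray  # c x p reconstruction to centered master space
    correlations: np.ndarray  # length c, non-increasing in [0, 1]
    c: int

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "mean_master": self.mean_master.tolist(),
            "mean_slave": self.mean_slave.tolist(),
            "W_slave": self.W_slave.tolist(),
            "scaling": self.scaling.tolist(),
            "back_map": self.back_map.tolist(),
            "correlations": self.correlations.tolist(),
            "c": int(self.c),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "CCACTModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            mean_master=np.asarray(d["mean_master"], dtype=float),
            mean_slave=np.asarray(d["mean_slave"], dtype=float),
            W_slave=np.asarray(d["W_slave"], dtype=float),
            scaling=np.asarray(d["scaling"], dtype=float),
            back_map=np.asarray(d["back_map"], dtype=float),
            correlations=np.asarray(d["correlations"], dtype=float),
            c=int(d["c"]),
        )


def _cca_pair(Xa: np.ndarray, Xb: np.ndarray, rank_tol: float = 1e-10):
    """Canonical weights/correlations of two centered blocks (SVD route).

    Rank-truncated SVD of each block replaces the explicit covariance
    inverses, which is what keeps the n << p spectral case well posed.
    """
    Ua, sa, Vat = np.linalg.svd(Xa, full_matrices=False)
    Ub, sb, Vbt = np.linalg.svd(Xb, full_matrices=False)
    ka = int(np.sum(sa > rank_tol * sa[0])) if sa.size and sa[0] > 0 else 0
    kb = int(np.sum(sb > rank_tol * sb[0])) if sb.size and sb[0] > 0 else 0
    if ka == 0 or kb == 0:
        raise DegenerateInputError("a standard block has zero variance")
    Uc, rho, Vct = np.linalg.svd(Ua[:, :ka].T @ Ub[:, :kb], full_matrices=False)
    Wa = Vat[:ka].T @ np.diag(1.0 / sa[:ka]) @ Uc
    Wb = Vbt[:kb].T @ np.diag(1.0 / sb[:kb]) @ Vct.T
    return Wa, Wb, np.clip(rho, 0.0, 1.0)


def fit_ccact(std_master, std_slave, c: int | None = None) -> CCACTModel:
    """Fit the CCA-based transfer on a paired standard set.

    The number of canonical pairs ``c`` defaults to the value minimizing
    leave-one-out reconstruction error of the master standards.
    """
    Sm = _as_matrix(std_master)
    Ss = _as_matrix(std_slave)
    _check_paired(Sm, Ss)
    mm, ms = Sm.mean(axis=0), Ss.mean(axis=0)
    Xm, Xs = Sm - mm, Ss - ms
    Wm, Ws, rho = _cca_pair(Xm, Xs)
    c_max = rho.size
    if c is None:
        c = _select_c_loo(Sm, Ss) if Sm.shape[0] >= 3 else c_max
    if not (1 <= c <= c_max):
        raise ParameterError(f"c={c} outside 1..{c_max}")
    Zs = Xs @ Ws[:, :c]
    Zm = Xm @ Wm[:, :c]
    denom = np.einsum("ij,ij->j", Zs, Zs)
    denom[denom == 0.0] = 1.0
    lam = np.einsum("ij,ij->j", Zs, Zm) / denom
    back, _, _, _ = np.linalg.lstsq(Zs * lam, Xm, rcond=None)
    return CCACTModel(
        mean_master=mm, mean_slave=ms, W_slave=Ws[:, :c], scaling=lam,
        back_map=back, correlations=rho[:c], c=int(c),
    )


def _select_c_loo(Sm: np.ndarray, Ss: np.ndarray) -> int:
    """c minimizing LOO master-standard reconstruction RMSE."""
    n = Sm.shape[0]
    c_cap = max(1, n - 2)
    errs = np.full(c_cap, np.inf)
    for c in range(1, c_cap + 1):
        sq, ok = 0.0, True
        for i in range(n):
            keep = np.arange(n) != i
            try:
                m = fit_ccact(Sm[keep], Ss[keep], c=min(c, keep.sum() - 1))
            except (ParameterError, DegenerateInputError):
                ok = False
                break
            sq += float(np.sum((transfer_ccact(m, Ss[i]) - Sm[i]) ** 2))
        if ok:
            errs[c - 1] = sq
    return int(np.argmin(errs)) + 1


def transfer_ccact(model: CCACTModel, X_slave) -> np.ndarray:
    """Map slave spectra to master spectral space through canonical variates."""
    X = _as_matrix(X_slave, model.mean_slave.size)
    Z = (X - model.mean_slave) @ model.W_slave * model.scaling
    return Z @ model.back_map + model.mean_master


# --------------------------------------------------------------------- MSC


def msc_correct(X, reference) -> np.ndarray:
    """Multiplicative signal correction against a reference spectrum.

    Each spectrum is OLS-regressed on the reference, ``x ~ a*ref + b``,
    and returned as ``(x - b)/a``. Row-wise and batch application agree.
    """
    Xm = _as_matrix(X)
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != Xm.shape[1]:
        raise PairingError(f"reference has {ref.size} channels, spectra {Xm.shape[1]}")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0.0:
        raise DegenerateInputError("MSC reference spectrum is constant")
    a = (Xm - Xm.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(a == 0.0):
        raise DegenerateInputError("a spectrum is orthogonal to the MSC reference")
    b = Xm.mean(axis=1) - a * ref.mean()
    return (Xm - b[:, None]) / a[:, None]
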