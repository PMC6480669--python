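"""Performance metrics, statistical comparison, and the benchmark harness.

Prediction quality is the root mean square error of prediction,
``RMSEP = sqrt(sum (y_i - yhat_i)^2 / n)`` on the common test set. Two
methods are contrasted by the relative improvement
``h = (1 - RMSEP_plsct / RMSEP_other) * 100%`` and by a two-sided
Wilcoxon signed-rank test on paired per-sample absolute prediction
errors (zero differences dropped, exact distribution for n <= 25,
normal approximation with tie correction beyond) — no significant
difference when p > 0.05.

``run_benchmark`` executes the full protocol on one paired dataset:
Kennard-Stone division, master model with CV-selected latent
variables, then, for each standard-set size, every requested transfer
method evaluated on the common slave test set, alongside the reference
fits (Calibration, Direct transfer, Recalibration on the slave
calibration set, Recalibration2 on the slave standards alone).
Standard subsets are nested across sizes by Kennard-Stone order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import baselines
from .exceptions import PairingError, ParameterError
from .pls import PLS1Model, fit_pls1, predict, select_lv_cv
from .sampling import SplitPlan, split_dataset
from .spectra import SpectraSet
from .transfer import fit_plsct_auto, predict_transfer, project_scores

__all__ = [
    "rmsep", "improvement", "wilcoxon_compare",
    "EvaluationReport", "run_benchmark", "reports_to_csv", "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("plsct", "pds:3", "pds:5", "pds:7", "sbc", "ccact", "glsw", "msc")
REFERENCE_METHODS = ("calibration", "direct", "recalibration", "recalibration2")


def rmsep(y, yhat) -> float:
    """Root mean square error of prediction."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ParameterError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 1:
        raise ParameterError("need at least one sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def improvement(rmsep_plsct: float, rmsep_other: float) -> float:
    """Relative RMSEP improvement in percent (negative if worse)."""
    if rmsep_other <= 0:
        raise ParameterError("rmsep_other must be positive")
    return (1.0 - rmsep_plsct / rmsep_other) * 100.0


def wilcoxon_compare(errors_a, errors_b) -> float:
    """Two-sided Wilcoxon signed-rank p on paired per-sample errors.

    Zero differences are dropped (Wilcoxon's original treatment). If
    every difference is zero the comparison is degenerate and p = 1 is
    returned with a warning.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size != b.size:
        raise PairingError(f"length mismatch: {a.size} vs {b.size}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    if d.size < 5:
        raise ParameterError(
            f"only {d.size} nonzero differences; need at least 5 for the signed-rank test"
        )
    ranks = scipy.stats.rankdata(np.abs(d))
    has_ties = np.unique(ranks).size < ranks.size
    if d.size <= 25 and not has_ties:
        method = "exact"  # classical lattice distribution
    elif d.size <= 13 and has_ties:
        # enumerate all 2^n sign assignments; exact even with midranks
        method = scipy.stats.PermutationMethod()
    else:
        method = "approx"  # normal approximation with tie correction
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", correction=False, method=method
    )
    return float(res.pvalue)


@dataclass
class EvaluationReport:
    """Per-method results for one dataset at one standard-set size."""

    dataset: str
    n_standards: int
    seed: int
    master_lv: int
    plsct_k: int | None
    rmsep: dict[str, float]
    improvement_vs_plsct: dict[str, float]
    p_vs_plsct: dict[str, float]
    errors: dict[str, np.ndarray] = field(repr=False)

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "dataset": self.dataset,
            "n_standards": self.n_standards,
            "seed": self.seed,
            "master_lv": self.master_lv,
            "plsct_k": self.plsct_k,
            "rmsep": self.rmsep,
            "improvement_vs_plsct": self.improvement_vs_plsct,
            "p_vs_plsct": self.p_vs_plsct,
            "errors": {k: v.tolist() for k, v in self.errors.items()},
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "EvaluationReport":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            dataset=d["dataset"],
            n_standards=int(d["n_standards"]),
            seed=int(d["seed"]),
            master_lv=int(d["master_lv"]),
            plsct_k=None if d["plsct_k"] is None else int(d["plsct_k"]),
            rmsep={k: float(v) for k, v in d["rmsep"].items()},
            improvement_vs_plsct={k: float(v) for k, v in d["improvement_vs_plsct"].items()},
            p_vs_plsct={k: float(v) for k, v in d["p_vs_plsct"].items()},
            errors={k: np.asarray(v, dtype=float) for k, v in d["errors"].items()},
        )


def reports_to_csv(reports: list[EvaluationReport], path: str | Path | None = None) -> pd.DataFrame:
    """Long-format table: dataset, method, n_standards, RMSEP, h, p."""
    rows = []
    for r in reports:
        for method, val in r.rmsep.items():
            rows.append({
                "dataset": r.dataset,
                "method": method,
                "n_standards": r.n_standards,
                "rmsep": val,
                "h_vs_plsct": r.improvement_vs_plsct.get(method, np.nan),
                "p_vs_plsct": r.p_vs_plsct.get(method, np.nan),
            })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def _fit_auto(data: SpectraSet, a_max: int, seed: int, folds: int = 10) -> PLS1Model:
    """Fit with CV + F-test LV selection, capping A_max at feasibility."""
    folds = min(folds, data.n)
    largest_fold = int(np.ceil(data.n / folds))
    cap = min(a_max, data.n - largest_fold - 1, data.p)
    cap = max(cap, 1)
    A = select_lv_cv(data, cap, folds=folds, seed=seed)
    return fit_pls1(data, A)


def run_benchmark(
    master: SpectraSet,
    slave: SpectraSet,
    standard_sizes=(5, 10, 15, 20, 25, 30),
    methods=DEFAULT_METHODS,
    *,
    test_fraction: float = 0.2,
    a_max: int = 15,
    seed: int = 0,
    dataset: str = "synthetic",
    glsw_alpha: float = 0.02,
    plan: SplitPlan | None = None,
) -> list[EvaluationReport]:
    """Run the full standard-set-size x method comparison protocol."""
    sizes = sorted(set(int(s) for s in standard_sizes))
    if plan is None:
        plan = split_dataset(master, slave, test_fraction, max(sizes))
    cal_m = master.subset(plan.calibration_indices)
    cal_s = slave.subset(plan.calibration_indices)
    test_m = master.subset(plan.test_indices)
    test_s = slave.subset(plan.test_indices)
    y_test = test_m.y

    master_model = _fit_auto(cal_m, a_max, seed)
    yhat_cal = predict(master_model, test_m)      # Calibration reference
    yhat_direct = predict(master_model, test_s)   # Direct transfer
    recal_model = _fit_auto(cal_s, a_max, seed)
    yhat_recal = predict(recal_model, test_s)

    reports: list[EvaluationReport] = []
    for m in sizes:
        std_idx = plan.standards(m)
        std_m = master.subset(std_idx)
        std_s = slave.subset(std_idx)
        preds: dict[str, np.ndarray] = {
            "calibration": yhat_cal,
            "direct": yhat_direct,
            "recalibration": yhat_recal,
        }
        try:
            recal2 = _fit_auto(std_s, a_max, seed, folds=min(10, std_s.n))
            preds["recalibration2"] = predict(recal2, test_s)
        except Exception:
            pass  # too few standards for a standalone slave model
        plsct_k = None
        for method in methods:
            name, _, arg = method.partition(":")
            if name == "plsct":
                tm = fit_plsct_auto(master_model, std_m, std_s)
                plsct_k = tm.k
                preds["plsct"] = predict_transfer(tm, test_s)
            elif name == "pds":
                w = int(arg) if arg else 5
                pds = baselines.fit_pds(std_m, std_s, w)
                preds[f"pds:{w}"] = predict(master_model, baselines.apply_pds(pds, test_s))
            elif name == "sbc":
                sbc = baselines.fit_sbc(predict(master_model, std_s), std_s.y)
                preds["sbc"] = baselines.apply_sbc(sbc, yhat_direct)
            elif name == "ccact":
                cca = baselines.fit_ccact(std_m, std_s)
                preds["ccact"] = predict(master_model, baselines.transfer_ccact(cca, test_s))
            elif name == "glsw":
                glsw = baselines.fit_glsw(std_m, std_s, glsw_alpha)
                cal_f = SpectraSet(
                    X=baselines.apply_glsw(glsw, cal_m),
                    wavelengths=cal_m.wavelengths, y=cal_m.y, ids=list(cal_m.ids),
                )
                gm = fit_pls1(cal_f, master_model.A)
                preds["glsw"] = predict(gm, baselines.apply_glsw(glsw, test_s))
            elif name == "msc":
                ref = cal_m.X.mean(axis=0)
                cal_c = SpectraSet(
                    X=baselines.msc_correct(cal_m.X, ref),
                    wavelengths=cal_m.wavelengths, y=cal_m.y, ids=list(cal_m.ids),
                )
                mm = _fit_auto(cal_c, a_max, seed)
                preds["msc"] = predict(mm, baselines.msc_correct(test_s.X, ref))
                preds["msc_master"] = predict(mm, baselines.msc_correct(test_m.X, ref))
            else:
                raise ParameterError(f"unknown method {method!r}")
        errors = {k: np.abs(y_test - v) for k, v in preds.items()}
        rms = {k: rmsep(y_test, v) for k, v in preds.items()}
        h: dict[str, float] = {}
        p: dict[str, float] = {}
        if "plsct" in rms:
            for k, v in rms.items():
                if k == "plsct":
                    continue
                if v > 0:
                    h[k] = improvement(rms["plsct"], v)
                try:
                    p[k] = wilcoxon_compare(errors["plsct"], errors[k])
                except (ParameterError, PairingError):
                    pass
        reports.append(EvaluationReport(
            dataset=dataset, n_standards=m, seed=seed,
            master_lv=master_model.A, plsct_k=plsct_k,
            rmsep=rms, improvement_vs_plsct=h, p_vs_plsct=p, errors=errors,
        ))
    return reports


def feature_gap(master_model: PLS1Model, tm, std_or_test_master, std_or_test_slave) -> tuple[float, float]:
    """Mean feature distance before and after transfer, ``(before, after)``.

    The distance is the root-mean-square per-sample feature gap on the
    first k score columns, ``||T_til - T_hat||_F / sqrt(n)`` before and
    ``||T_til xi - T_hat||_F / sqrt(n)`` after; least-squares
    optimality guarantees after <= before on the standard set the
    transfer was fit on.
    """
    k = tm.k
    T_hat = project_scores(master_model, std_or_test_master, k)
    T_til = project_scores(master_model, std_or_test_slave, k)
    n = T_hat.shape[0]
    before = float(np.linalg.norm(T_til - T_hat) / np.sqrt(n))
    after = float(np.linalg.norm(T_til @ tm.xi + tm.intercept - T_hat) / np.sqrt(n))
    return before, after
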