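"""Kennard-Stone sample selection and the calibration/test/standard split.

The Kennard-Stone design picks samples that cover spectral space: the
first two picks are the most distant pair, each later pick maximizes
its minimum Euclidean distance to everything already selected. It is
fully deterministic; distance ties break toward the lowest index.

The dataset division protocol: Kennard-Stone on the MASTER spectra
selects the calibration set (the remainder, 20% by default, is the
test set, size round-half-up), then Kennard-Stone on the SLAVE
calibration spectra orders the standard-set candidates. Because the
selection is incremental, the first m entries of ``standard_order`` are
exactly the m-standard subset — nested across standard-set sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import PairingError, ParameterError
from .pls import _as_matrix
from .spectra import SpectraSet

__all__ = ["SplitPlan", "kennard_stone", "split_dataset"]


@dataclass
class SplitPlan:
    """Index bookkeeping for one dataset division.

    ``standard_order`` holds original-dataset indices in Kennard-Stone
    selection order; standards are always a subset of the calibration
    set. ``provenance`` records which instrument's spectra drove each
    selection.
    """

    calibration_indices: np.ndarray
    test_indices: np.ndarray
    standard_order: np.ndarray
    provenance: dict[str, str] = field(
        default_factory=lambda: {"split": "master", "standards": "slave"}
    )

    def standards(self, m: int | None = None) -> np.ndarray:
        m = self.standard_order.size if m is None else m
        if m > self.standard_order.size:
            raise ParameterError(
                f"{m} standards requested, only {self.standard_order.size} ordered"
            )
        return self.standard_order[:m]

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "calibration_indices": self.calibration_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "standard_order": self.standard_order.tolist(),
            "provenance": dict(self.provenance),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SplitPlan":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            calibration_indices=np.asarray(d["calibration_indices"], dtype=int),
            test_indices=np.asarray(d["test_indices"], dtype=int),
            standard_order=np.asarray(d["standard_order"], dtype=int),
            provenance=dict(d["provenance"]),
        )


def kennard_stone(X, m: int) -> np.ndarray:
    """Select m max-min-distance samples; deterministic, ties to low index."""
    Xm = _as_matrix(X)
    n = Xm.shape[0]
    if not (2 <= m <= n):
        raise ParameterError(f"m={m} outside 2..n={n}")
    D = squareform(pdist(Xm))
    # first occurrence in row-major order = lowest (i, j) pair on ties
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    for _ in range(m - 2):
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return np.asarray(selected, dtype=int)


def split_dataset(
    master: SpectraSet,
    slave: SpectraSet,
    test_fraction: float = 0.2,
    n_standards: int = 30,
) -> SplitPlan:
    """Divide paired datasets into calibration/test and order standards.

    The test set holds ``round(test_fraction * n)`` samples
    (round-half-up); Kennard-Stone on the master spectra fills the
    calibration set and the remainder is the test set. Standards are
    then ordered by Kennard-Stone over the slave calibration spectra.
    """
    if master.n != slave.n or master.ids != slave.ids:
        raise PairingError("master and slave must hold the same samples in the same order")
    if not (0.0 < test_fraction < 1.0):
        raise ParameterError(f"test_fraction={test_fraction} outside (0, 1)")
    n = master.n
    n_test = int(np.floor(test_fraction * n + 0.5))
    n_cal = n - n_test
    if n_cal < 2:
        raise ParameterError("calibration set would have fewer than 2 samples")
    if n_standards > n_cal:
        raise ParameterError(f"n_standards={n_standards} exceeds calibration size {n_cal}")
    cal = np.sort(kennard_stone(master.X, n_cal))
    test = np.setdiff1d(np.arange(n), cal)
    std_local = kennard_stone(slave.X[cal], n_standards)
    return SplitPlan(
        calibration_indices=cal,
        test_indices=test,
        standard_order=cal[std_local],
    )
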