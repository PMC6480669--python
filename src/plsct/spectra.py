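"""The :class:`SpectraSet` container and its delimited-text serialization.

A ``SpectraSet`` is the universal I/O unit of the package: a block of
absorbance spectra (n samples x p wavelength channels) together with the
wavelength axis in nm, sample identifiers, and an optional reference
property vector ``y`` (e.g. % moisture or % protein).

The on-disk format is a plain CSV whose header row is
``id,<wavelength_1>,...,<wavelength_p>[,y]`` with one sample per row.
Floats are written with shortest round-trip repr, so a write/read cycle
is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ShapeError

__all__ = ["SpectraSet"]


@dataclass
class SpectraSet:
    """A block of spectra sharing one wavelength axis.

    Parameters
    ----------
    X:
        Absorbance matrix, shape ``(n, p)``. All entries must be finite.
    wavelengths:
        Strictly increasing axis of length ``p``, in nm.
    y:
        Optional reference property values, length ``n``.
    ids:
        Sample labels, length ``n``. Auto-generated if omitted.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ShapeError("spectra block must have at least one sample and one channel")
        if not np.all(np.isfinite(self.X)):
            raise ShapeError("non-finite absorbance values in X")
        if self.wavelengths.size != p:
            raise ShapeError(
                f"wavelength axis length {self.wavelengths.size} != {p} channels"
            )
        if p > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ShapeError("wavelength axis must be strictly increasing")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
            if self.y.size != n:
                raise ShapeError(f"y length {self.y.size} != {n} samples")
        if not self.ids:
            self.ids = [f"s{i:05d}" for i in range(n)]
        else:
            self.ids = [str(i) for i in self.ids]
            if len(self.ids) != n:
                raise ShapeError(f"{len(self.ids)} ids != {n} samples")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row-subset (copy) preserving wavelength axis, ids and y."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            X=self.X[idx].copy(),
            y=None if self.y is None else self.y[idx].copy(),
            ids=[self.ids[i] for i in idx],
        )

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path: str | Path) -> None:
        """Write ``id,<wl_1>,...,<wl_p>[,y]`` CSV, losslessly."""
        header = ["id"] + [repr(float(w)) for w in self.wavelengths]
        if self.y is not None:
            header.append("y")
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for i in range(self.n):
                row = [self.ids[i]] + [repr(float(v)) for v in self.X[i]]
                if self.y is not None:
                    row.append(repr(float(self.y[i])))
                fh.write(",".join(row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
        if df.columns[0] != "id":
            raise ShapeError(f"{path}: first column must be 'id'")
        has_y = df.columns[-1] == "y"
        wl_cols = list(df.columns[1 : -1 if has_y else None])
        return cls(
            X=df[wl_cols].to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            y=df["y"].to_numpy(dtype=float) if has_y else None,
            ids=list(df["id"]),
        )
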