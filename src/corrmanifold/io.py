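"""Readers/writers for correlation-matrix collections and time series.

Collections are stored either as a directory of per-matrix CSV files
(comma-separated, header-free, full square matrix) or as a single stacked
text file whose first line is ``N n`` followed by N blocks of n rows.
Values are written with 17 significant digits so a save/load round trip is
bit-stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry

__all__ = [
    "MatrixCollection",
    "load_collection",
    "save_collection",
    "load_labels",
    "save_labels",
    "timeseries_to_corr",
]

logger = logging.getLogger("corrmanifold")

_SYMMETRIZE_TOL = 1e-8


@dataclass
class MatrixCollection:
    """A list of same-dimension correlation matrices with optional labels."""

    matrices: np.ndarray  # N x n x n
    names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be a stack of square matrices")
        N = self.matrices.shape[0]
        if not self.names:
            self.names = [f"matrix_{i:04d}" for i in range(N)]
        if len(self.names) != N:
            raise ValueError("names length must match number of matrices")
        if self.labels is not None and len(self.labels) != N:
            raise ValueError("labels length must match number of matrices")

    def __len__(self) -> int:
        return self.matrices.shape[0]

    @property
    def dim(self) -> int:
        return self.matrices.shape[1]


def _clean_matrix(M: np.ndarray, name: str, validate: bool) -> np.ndarray:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name}: not a square matrix (shape {M.shape})")
    asym = np.max(np.abs(M - M.T)) if M.size else 0.0
    if asym > _SYMMETRIZE_TOL:
        raise geometry.InvalidMatrixError(
            f"{name}: asymmetry {asym:.3e} exceeds {_SYMMETRIZE_TOL:g}"
        )
    if asym > 0:
        logger.info("%s: symmetrized input (asymmetry %.3e)", name, asym)
        M = 0.5 * (M + M.T)
    if validate:
        M = geometry.validate_correlation(M, name)
    return M


def load_collection(path, validate: bool = True) -> MatrixCollection:
    """Load a collection from a CSV directory or a stacked text file."""
    path = Path(path)
    mats: list[np.ndarray] = []
    names: list[str] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
        if not files:
            raise FileNotFoundError(f"no CSV files in {path}")
        for f in files:
            M = np.atleast_2d(np.loadtxt(f, delimiter=","))
            mats.append(_clean_matrix(M, f.name, validate))
            names.append(f.stem)
    else:
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(
                    f"{path}: stacked file must start with a 'N n' header line"
                )
            N, n = int(header[0]), int(header[1])
            body = np.loadtxt(fh, delimiter=",", ndmin=2)
        if body.shape != (N * n, n):
            raise ValueError(
                f"{path}: expected {N * n} rows of {n} values, got {body.shape}"
            )
        for i in range(N):
            name = f"{path.stem}_{i:04d}"
            mats.append(_clean_matrix(body[i * n:(i + 1) * n], name, validate))
            names.append(name)
    dims = {m.shape[0] for m in mats}
    if len(dims) > 1:
        raise ValueError(f"mixed matrix dimensions in {path}: {sorted(dims)}")
    return MatrixCollection(
        matrices=np.array(mats), names=names, source=str(path)
    )


def save_collection(path, matrices, names=None, stacked: bool = False) -> None:
    """Write matrices as per-matrix CSVs (default) or one stacked file."""
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    N, n, _ = mats.shape
    path = Path(path)
    if stacked:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"{N} {n}\n")
            for M in mats:
                np.savetxt(fh, M, delimiter=",", fmt="%.17g")
    else:
        path.mkdir(parents=True, exist_ok=True)
        names = names or [f"matrix_{i:04d}" for i in range(N)]
        for name, M in zip(names, mats):
            np.savetxt(path / f"{name}.csv", M, delimiter=",", fmt="%.17g")


def load_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a name,label CSV; returns (names, integer labels)."""
    names, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, label = line.split(",")
            names.append(name)
            labels.append(int(label))
    return names, np.array(labels, dtype=int)


def save_labels(path, names, labels) -> None:
    with open(path, "w") as fh:
        for name, label in zip(names, labels):
            fh.write(f"{name},{int(label)}\n")


def timeseries_to_corr(ts, validate: bool = True) -> np.ndarray:
    """Pearson correlation matrix of a samples-by-channels table.

    Rejects constant channels by name (index); warns on rank deficiency
    when there are fewer samples than channels, and — under strict
    validation — rejects the resulting singular matrix.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D samples x channels array")
    n_samples, n_channels = ts.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples to form a correlation")
    sd = ts.std(axis=0)
    if (sd == 0).any():
        const = np.nonzero(sd == 0)[0]
        raise ValueError(f"constant channel(s) at index {const.tolist()}")
    if n_channels == 1:
        return np.ones((1, 1))
    if n_samples < n_channels:
        warnings.warn(
            f"{n_samples} samples < {n_channels} channels: correlation "
            "matrix is rank-deficient", RuntimeWarning, stacklevel=2,
        )
    C = np.corrcoef(ts, rowvar=False)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    if validate:
        C = geometry.validate_correlation(C, "time-series correlation")
    return C
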