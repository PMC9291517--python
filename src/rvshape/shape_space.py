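"""PCA shape space over correspondence coordinates.

Each subject's M correspondence particles, flattened to a 3M vector, fully
parameterize its shape. A centered PCA of the K x 3M matrix yields the
orthonormal modes of shape variation, the per-mode variances, and each
subject's loading vector s_i — the low-dimensional shape representation
used by the classifier and the group statistics.

Numerical route: thin SVD of the centered matrix (K << 3M), sample
covariance normalized by K - 1, and a deterministic sign convention (each
mode's largest-magnitude component is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ShapeMatrix:
    """K x 3M flattened correspondence matrix with subject metadata."""

    X: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    group3: np.ndarray | None = None  # healthy / control / tr
    subgroup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("shape matrix must be 2-D (subjects x 3M)")
        if self.X.shape[1] % 3 != 0:
            raise ValueError("column count must be a multiple of 3")
        if np.isnan(self.X).any():
            raise ValueError("shape matrix contains missing values")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(len(self.X))]
        if self.group3 is not None:
            self.group3 = np.asarray(self.group3)
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_particles(self) -> int:
        return self.X.shape[1] // 3

    @classmethod
    def from_particles(cls, system, group3=None, subgroup=None):
        return cls(system.flatten(), list(system.subject_ids), group3,
                   subgroup)

    def group_mask(self, group) -> np.ndarray:
        if isinstance(group, str):
            if self.group3 is None:
                raise ValueError("no group labels attached")
            return self.group3 == group
        mask = np.asarray(group, dtype=bool)
        if mask.shape != (self.n_subjects,):
            raise ValueError("group mask has wrong length")
        return mask


@dataclass
class PCAModel:
    mean: np.ndarray          # (3M,)
    modes: np.ndarray         # (n_modes, 3M), orthonormal rows
    eigenvalues: np.ndarray   # (n_modes,), descending, mm^2
    loadings: np.ndarray      # (K, n_modes)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def fit_pca(matrix: ShapeMatrix) -> PCAModel:
    """Centered PCA by thin SVD; retains min(K-1, 3M) modes."""
    k = matrix.n_subjects
    if k < 2:
        raise ValueError("PCA requires at least two subjects")
    mean = matrix.X.mean(axis=0)
    y = matrix.X - mean
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    n_keep = min(k - 1, matrix.X.shape[1])
    s = s[:n_keep]
    vt = vt[:n_keep]
    # deterministic sign: largest-|.| component of each mode positive
    flip = np.sign(vt[np.arange(n_keep), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    eigenvalues = s ** 2 / (k - 1)
    loadings = y @ vt.T
    return PCAModel(mean, vt, eigenvalues, loadings,
                    list(matrix.subject_ids))


def num_modes_for_variance(model: PCAModel, fraction: float = 0.99) -> int:
    """Smallest mode count whose cumulative variance share >= fraction."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    total = model.eigenvalues.sum()
    if total == 0:
        return 0
    cum = np.cumsum(model.eigenvalues) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def mean_shape(matrix: ShapeMatrix, group) -> np.ndarray:
    """Arithmetic mean of the group's rows (the group mean shape)."""
    mask = matrix.group_mask(group)
    if mask.sum() == 0:
        raise ValueError(f"group {group!r} has no members")
    return matrix.X[mask].mean(axis=0)


def reconstruct(model: PCAModel, loading: np.ndarray) -> np.ndarray:
    """Inverse map: mean + sum_j loading_j * mode_j."""
    loading = np.asarray(loading, dtype=float).ravel()
    if len(loading) > model.n_modes:
        raise ValueError(
            f"loading has {len(loading)} coefficients but the model has "
            f"{model.n_modes} modes"
        )
    return model.mean + loading @ model.modes[: len(loading)]


def loadings_frame(model: PCAModel, matrix: ShapeMatrix) -> pd.DataFrame:
    """Loadings as a table with subject metadata, ready for CSV export."""
    df = pd.DataFrame(
        model.loadings,
        columns=[f"mode{j + 1}" for j in range(model.n_modes)],
    )
    df.insert(0, "subject_id", matrix.subject_ids)
    if matrix.group3 is not None:
        df["group"] = matrix.group3
    if matrix.subgroup is not None:
        df["subgroup"] = matrix.subgroup
    return df


def mode_extremes(model: PCAModel, mode: int, n_sd: float = 2.0):
    """Shapes at mean +/- n_sd standard deviations along one mode."""
    sd = float(np.sqrt(model.eigenvalues[mode]))
    lo = np.zeros(mode + 1)
    hi = np.zeros(mode + 1)
    lo[mode] = -n_sd * sd
    hi[mode] = +n_sd * sd
    return reconstruct(model, lo), reconstruct(model, hi)
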