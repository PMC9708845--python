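"""Dimensionality reduction: standardized PCA with varimax rotation.

The feature table is z-scored (sd with the n−1 denominator), the
correlation matrix is eigen-decomposed, components with eigenvalue > 1 are
retained (Kaiser criterion), and the retained loadings are varimax-rotated
with Kaiser normalization.  Component scores use the regression (Thomson)
method from the rotated loadings.  Signs are fixed deterministically: each
component's largest-|loading| feature loads positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: |loading| must strictly exceed this to count as salient.
DEFAULT_LOADING_THRESHOLD = 0.50

VARIMAX_TOL = 1e-6
VARIMAX_MAX_SWEEPS = 100


class ReductionError(ValueError):
    """Degenerate input to the reduction stage."""


@dataclass(frozen=True)
class PCAModel:
    feature_names: tuple[str, ...]
    eigenvalues: np.ndarray          # all p, descending
    retained_m: int
    rotated_loadings: np.ndarray     # p × m
    explained_fractions: np.ndarray  # m, eigenvalue_j / p
    rotation: np.ndarray             # m × m orthogonal
    center: np.ndarray
    scale: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "eigenvalues": self.eigenvalues.tolist(),
            "retained_m": self.retained_m,
            "rotated_loadings": self.rotated_loadings.tolist(),
            "explained_fractions": self.explained_fractions.tolist(),
            "rotation": self.rotation.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            feature_names=tuple(d["feature_names"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            retained_m=int(d["retained_m"]),
            rotated_loadings=np.asarray(d["rotated_loadings"]),
            explained_fractions=np.asarray(d["explained_fractions"]),
            rotation=np.asarray(d["rotation"]),
            center=np.asarray(d["center"]),
            scale=np.asarray(d["scale"]),
        )


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Z-score each column (mean 0, sd 1 with ddof=1).

    Missing values must be handled upstream; a zero-variance column cannot
    be standardized and raises.
    """
    if matrix.isna().any().any():
        bad = matrix.columns[matrix.isna().any()].tolist()
        raise ReductionError(f"missing values in columns {bad}; impute or drop upstream")
    center = matrix.mean(axis=0).to_numpy()
    scale = matrix.std(axis=0, ddof=1).to_numpy()
    zero = matrix.columns[scale == 0].tolist()
    if zero:
        raise ReductionError(f"zero-variance columns {zero}")
    std = (matrix - center) / scale
    return std, center, scale


def kaiser_retained(eigenvalues: np.ndarray) -> int:
    """Number of components with eigenvalue strictly greater than 1."""
    return int(np.sum(np.asarray(eigenvalues) > 1.0))


def varimax_rotation(
    loadings: np.ndarray,
    tol: float = VARIMAX_TOL,
    max_sweeps: int = VARIMAX_MAX_SWEEPS,
    kaiser_normalize: bool = True,
) -> np.ndarray:
    """Orthogonal rotation maximizing the variance of squared loadings.

    Returns the m × m rotation matrix R such that ``loadings @ R`` is the
    rotated pattern.  Rows are Kaiser-normalized (divided by their
    communality) during optimization, the standard companion of varimax.
    """
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return np.eye(m)
    if kaiser_normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(m)
    d = 0.0
    for _ in range(max_sweeps):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d_old, d = d, float(np.sum(s))
        if d_old != 0 and d < d_old * (1 + tol):
            break
    return R


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Diagonal ±1 matrix making each component's largest-|loading| feature
    load positive (eigenvectors are sign-ambiguous)."""
    signs = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            signs[j] = -1.0
    return np.diag(signs)


def fit_pca_varimax(matrix: pd.DataFrame) -> tuple[PCAModel, pd.DataFrame]:
    """Fit the rotated PCA and return (model, per-participant scores).

    ``matrix`` is the raw feature table; standardization happens here so
    the model carries its own center/scale.  Scores are regression-method
    scores from the rotated loadings; columns are named PC1..PCm.
    """
    n, p = matrix.shape
    if n < 10:
        raise ReductionError(f"need at least 10 participants, got {n}")
    std, center, scale = standardize(matrix)
    Z = std.to_numpy()
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    m = kaiser_retained(eigvals)
    if m < 1:
        raise ReductionError("no component with eigenvalue > 1; degenerate input")
    loadings = eigvecs[:, :m] * np.sqrt(eigvals[:m])
    R = varimax_rotation(loadings)
    rotated = loadings @ R
    # order rotated components by decreasing explained variance (sum of
    # squared loadings), then fix signs deterministically
    ssq = np.sum(rotated**2, axis=0)
    perm = np.argsort(ssq)[::-1]
    rotated = rotated[:, perm]
    R = R[:, perm]
    S = _fix_signs(rotated)
    rotated = rotated @ S
    R = R @ S

    # regression-method scores: W = corr^{-1} L, scores = Z W
    W = np.linalg.solve(corr, rotated)
    scores = Z @ W
    score_df = pd.DataFrame(
        scores,
        index=matrix.index,
        columns=[f"PC{j + 1}" for j in range(m)],
    )
    model = PCAModel(
        feature_names=tuple(matrix.columns),
        eigenvalues=eigvals,
        retained_m=m,
        rotated_loadings=rotated,
        explained_fractions=eigvals[:m] / p,
        rotation=R,
        center=center,
        scale=scale,
    )
    return model, score_df


def flag_salient_loadings(
    model: PCAModel,
    threshold: float = DEFAULT_LOADING_THRESHOLD,
) -> list[tuple[str, ...]]:
    """Per-component feature sets with |loading| strictly above threshold."""
    flagged: list[tuple[str, ...]] = []
    for j in range(model.retained_m):
        feats = tuple(
            name
            for name, load in zip(model.feature_names, model.rotated_loadings[:, j])
            if abs(load) > threshold
        )
        if not feats:
            warnings.warn(
                f"component {j + 1}: no loading exceeds |{threshold}|", stacklevel=2
            )
        flagged.append(feats)
    return flagged
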