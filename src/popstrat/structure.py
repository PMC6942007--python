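"""Detecting and representing population structure.

Genotype PCA with out-of-sample projection, a sample-size detectability
criterion, a Hudson-type FST estimator, SVD of a reference sharing matrix
with cohort projection, variance explained by ancestry scores, and
radius-masked 2-D kernel smoothing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.utils.extmath import randomized_svd

from .simulate import SharingMatrix

__all__ = [
    "PCBasis",
    "ReferenceBasis",
    "compute_pcs",
    "project_pcs",
    "detectability",
    "empirical_fst",
    "fit_reference_basis",
    "project_cohort",
    "variance_explained",
    "kernel_smooth_2d",
]


@dataclass
class PCBasis:
    """Principal components of a column-standardized genotype matrix."""

    loadings: np.ndarray       # L_kept x k, orthonormal columns
    scores: np.ndarray         # N x k
    eigenvalues: np.ndarray    # k, descending
    snp_means: np.ndarray      # per kept SNP
    snp_scales: np.ndarray     # per kept SNP, > 0
    kept_snps: np.ndarray      # indices into the original SNP axis


@dataclass
class ReferenceBasis:
    """SVD of a centered/standardized reference sharing matrix."""

    center: np.ndarray          # K
    scale: np.ndarray           # K, > 0
    right_vectors: np.ndarray   # K_kept x r, orthonormal columns
    singular_values: np.ndarray # r, descending
    labels: Sequence[str]
    kept_columns: np.ndarray


def _fix_signs(loadings: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Deterministic sign convention: largest-|.| loading positive per column."""
    flips = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            flips[j] = -1.0
    out = [loadings * flips]
    for o in others:
        out.append(o * flips)
    return tuple(out)


def compute_pcs(X: np.ndarray, k: int = 20, random_state: int = 0) -> PCBasis:
    """Top-k PCs of the column-standardized genotype matrix.

    Monomorphic SNPs are dropped (with a warning) and recorded in
    ``kept_snps``.  Uses randomized SVD for large matrices, exact SVD for
    small ones; column signs are fixed deterministically.
    """
    X = np.asarray(X, dtype=float)
    n, L = X.shape
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(scales > 0)
    if kept.size == 0:
        raise ValueError("all SNPs are monomorphic; no structure to compute")
    if kept.size < L:
        warnings.warn(
            f"dropped {L - kept.size} monomorphic SNPs before PCA", stacklevel=2
        )
    if k > min(n - 1, kept.size):
        raise ValueError(
            f"k={k} exceeds the rank bound min(n-1, kept SNPs) = {min(n - 1, kept.size)}"
        )
    Z = (X[:, kept] - means[kept]) / scales[kept]
    if min(n, kept.size) <= max(200, 5 * k):
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
    else:
        U, S, Vt = randomized_svd(Z, n_components=k, n_iter=7, random_state=random_state)
    loadings, U = _fix_signs(Vt.T, U)
    scores = U * S
    eigenvalues = S**2 / (n - 1)
    return PCBasis(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        snp_means=means[kept],
        snp_scales=scales[kept],
        kept_snps=kept,
    )


def project_pcs(basis: PCBasis, X_new: np.ndarray) -> np.ndarray:
    """Project new individuals into an existing PC space.

    Standardizes ``X_new`` with the training means/scales over the training
    ``kept_snps`` (monomorphic-in-training SNPs are ignored).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] < basis.kept_snps.max() + 1:
        raise ValueError(
            "X_new must have the training SNP set (at least "
            f"{basis.kept_snps.max() + 1} columns)"
        )
    Z = (X_new[:, basis.kept_snps] - basis.snp_means) / basis.snp_scales
    return Z @ basis.loadings


def detectability(n: int, L: int, fst: float) -> dict:
    """Phase-transition criterion for whether structure of size ``fst`` is
    visible in a sample of ``n`` individuals at ``L`` SNPs.

    The statistic is D = fst * sqrt(n * L); structure is detectable when
    D > 1, and n_required = ceil(1 / (fst^2 * L)) is the sample size at
    which the threshold is crossed.
    """
    if fst < 0:
        raise ValueError("fst must be >= 0")
    if n < 1 or L < 1:
        raise ValueError("n and L must be >= 1")
    if fst == 0:
        return {"detectable": False, "statistic": 0.0, "n_required": math.inf}
    stat = fst * math.sqrt(n * L)
    n_req = max(1, math.ceil(1.0 / (fst**2 * L)))
    return {"detectable": stat > 1.0, "statistic": stat, "n_required": n_req}


def empirical_fst(X: np.ndarray, groups: np.ndarray) -> float:
    """Hudson-type ratio-of-averages FST between two groups of haploid genotypes.

    SNPs monomorphic in both groups are excluded; the estimate is clamped
    at 0.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"groups must contain exactly 2 labels, got {labels.size}")
    X1 = X[groups == labels[0]]
    X2 = X[groups == labels[1]]
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group must have at least 2 individuals")
    p1 = X1.mean(axis=0)
    p2 = X2.mean(axis=0)
    poly = ~((p1 == 0) & (p2 == 0)) & ~((p1 == 1) & (p2 == 1))
    if not np.any(poly):
        raise ValueError("all SNPs monomorphic in both groups")
    p1, p2 = p1[poly], p2[poly]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(max(0.0, num.sum() / den.sum()))


def fit_reference_basis(ref: SharingMatrix) -> ReferenceBasis:
    """SVD of the reference sharing matrix after per-column center/scale.

    Zero-variance columns are dropped with a warning; signs follow the same
    convention as :func:`compute_pcs`.
    """
    Z0 = ref.values
    center = Z0.mean(axis=0)
    scale = Z0.std(axis=0, ddof=1)
    kept = np.flatnonzero(scale > 0)
    if kept.size < 2:
        raise ValueError("fewer than 2 usable (non-constant) reference columns")
    if kept.size < Z0.shape[1]:
        warnings.warn(
            f"dropped {Z0.shape[1] - kept.size} zero-variance reference columns",
            stacklevel=2,
        )
    Z = (Z0[:, kept] - center[kept]) / scale[kept]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    (right,) = _fix_signs(Vt.T)
    return ReferenceBasis(
        center=center[kept],
        scale=scale[kept],
        right_vectors=right,
        singular_values=S,
        labels=[ref.labels[i] for i in kept],
        kept_columns=kept,
    )


def project_cohort(basis: ReferenceBasis, cohort_sharing: SharingMatrix) -> np.ndarray:
    """Map cohort sharing rows into the reference SVD space."""
    if cohort_sharing.n_populations <= basis.kept_columns.max():
        raise ValueError("cohort sharing matrix has too few columns for this basis")
    cohort_labels = [cohort_sharing.labels[i] for i in basis.kept_columns]
    if cohort_labels != list(basis.labels):
        raise ValueError("cohort sharing labels do not match the reference basis")
    Z = (cohort_sharing.values[:, basis.kept_columns] - basis.center) / basis.scale
    return Z @ basis.right_vectors


def variance_explained(scores: np.ndarray, phenotype: np.ndarray) -> dict:
    """Multiple R^2 of phenotype ~ intercept + all score columns.

    Also returns each column's marginal (single-covariate) R^2.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[0] == 1 and np.asarray(phenotype).size != 1:
        S = S.T
    y = np.asarray(phenotype, dtype=float)
    n, k = S.shape
    if y.size != n:
        raise ValueError("scores and phenotype lengths differ")
    if n < k + 2:
        raise ValueError(f"need at least k+2 = {k + 2} observations, got {n}")

    def _r2(design: np.ndarray) -> float:
        A = np.column_stack([np.ones(design.shape[0]), design])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            return 0.0
        return float(max(0.0, min(1.0, 1.0 - np.sum(resid**2) / tss)))

    return {
        "r2": _r2(S),
        "per_component": np.array([_r2(S[:, [j]]) for j in range(k)]),
    }


def kernel_smooth_2d(
    points: np.ndarray,
    values: np.ndarray,
    grid: int = 50,
    bandwidth: float = 0.02,
    max_dist: float = 0.03,
) -> dict:
    """Gaussian-kernel smoothing of ``values`` over a 2-D score plane.

    Grid nodes farther than ``max_dist`` from every observation are masked.
    Returns grid axes, the smoothed surface, and the boolean mask.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if pts.shape[0] != vals.size or pts.shape[0] < 1:
        raise ValueError("points and values must have equal, positive length")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    nodes = np.column_stack([XX.ravel(), YY.ravel()])
    tree = cKDTree(pts)
    nearest, _ = tree.query(nodes, k=1)
    mask = nearest <= max_dist
    surface = np.full(nodes.shape[0], np.nan)
    idx = np.flatnonzero(mask)
    if idx.size:
        d2 = ((nodes[idx, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-0.5 * d2 / bandwidth**2)
        surface[idx] = (w @ vals) / w.sum(axis=1)
    return {
        "x": gx,
        "y": gy,
        "surface": surface.reshape(grid, grid),
        "mask": mask.reshape(grid, grid),
    }
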