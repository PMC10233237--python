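"""Singular value decomposition of the subject-by-voxel matrix, component
retention, and score utilities.

The decomposition X ~ scores @ eigenbrains factors the subject matrix
into orthonormal voxel-loading maps (rows of ``eigenbrains``) and
per-subject scores.  With far more voxels than subjects the dual
(subject-by-subject Gram matrix) route is used; both routes agree to
numerical precision and are cross-checked in the test suite.

Component retention follows the latent-root criterion: component
variances are rescaled so a random spectrum would average 1, and
components with a root > 1 are kept.  A Monte-Carlo parallel analysis
against random normal matrices of identical dimensions is available as
a stricter alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from eigenbrains.image_io import SubjectMatrix, robust_scale_row

__all__ = [
    "EigenDecomposition",
    "RetentionResult",
    "decompose",
    "variance_explained",
    "latent_roots_from_singular_values",
    "latent_root_retention",
    "parallel_analysis",
    "project",
    "rescale_scores_percentile",
]

# singular values below this relative cutoff are treated as zero rank
_RANK_RTOL = 1e-10


@dataclass
class EigenDecomposition:
    """Orthonormal voxel-loading maps with per-subject scores.

    ``eigenbrains`` is K x n_voxels with orthonormal rows; ``scores`` is
    n_subjects x K with mutually orthogonal columns; the input matrix is
    recovered as ``scores @ eigenbrains`` up to the discarded spectrum.
    ``latent_roots`` are component variances rescaled so the mean over
    the full min(n_subjects - 1, n_voxels) spectrum is 1.
    """

    eigenbrains: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    variance_fraction: np.ndarray
    latent_roots: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenbrains.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.eigenbrains.shape[1]


@dataclass
class RetentionResult:
    n_retained: int
    rule: str  # "latent_root_gt1" | "parallel_analysis"
    null_roots: np.ndarray | None = None
    seed: int | None = None


def _svd_direct(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    return u, s, vt


def _svd_dual(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD via the n x n Gram matrix; exact when n_subjects << n_voxels."""
    gram = values @ values.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    u = evecs[:, order]
    s = np.sqrt(evals)
    vt = np.zeros((s.size, values.shape[1]))
    nonzero = s > (s[0] * _RANK_RTOL if s.size and s[0] > 0 else 0)
    if nonzero.any():
        vt[nonzero] = (u[:, nonzero].T @ values) / s[nonzero, None]
    return u, s, vt


def _orient_signs(scores: np.ndarray, eigenbrains: np.ndarray) -> None:
    """Flip each component so its maximum-|loading| voxel is positive (in place)."""
    for k in range(eigenbrains.shape[0]):
        j = int(np.argmax(np.abs(eigenbrains[k])))
        if eigenbrains[k, j] < 0:
            eigenbrains[k] *= -1.0
            scores[:, k] *= -1.0


def decompose(matrix: SubjectMatrix | np.ndarray, k_max: int | None = None,
              method: str = "auto") -> EigenDecomposition:
    """Factor the subject matrix into spatial components and subject scores.

    Parameters
    ----------
    matrix
        Subjects x voxels matrix (rows already preprocessed/scaled).
    k_max
        Number of components to keep; capped at the numerical rank.
        Default: min(n_subjects, n_voxels).
    method
        "direct", "dual", or "auto" (dual when n_voxels >= 4 * n_subjects).

    The sign of each component is fixed deterministically: the voxel with
    the largest absolute loading is made positive.
    """
    values = matrix.values if isinstance(matrix, SubjectMatrix) else np.asarray(matrix, dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if k_max is None:
        k_max = min(n, p)
    if k_max > min(n, p):
        raise ValueError(f"k_max={k_max} exceeds min(n_subjects, n_voxels)={min(n, p)}")

    if method == "auto":
        method = "dual" if p >= 4 * n else "direct"
    if method == "dual":
        u, s, vt = _svd_dual(values)
        # eigh of the Gram matrix floors singular values near s[0]*sqrt(eps)
        rank_rtol = 1e-6
    elif method == "direct":
        u, s, vt = _svd_direct(values)
        rank_rtol = _RANK_RTOL
    else:
        raise ValueError(f"unknown method {method!r}")

    # variance fractions and latent roots use the full computed spectrum
    total_var = float(np.sum(s**2))
    if total_var == 0:
        raise ValueError("all-zero input matrix")
    rank = int(np.sum(s > s[0] * rank_rtol))
    k = min(k_max, rank)

    scores = u[:, :k] * s[:k]
    eigenbrains = vt[:k].copy()
    _orient_signs(scores, eigenbrains)

    variance_fraction = s[:k] ** 2 / total_var
    m = min(n - 1, p)
    latent_roots = s[:k] ** 2 * m / total_var
    return EigenDecomposition(
        eigenbrains=eigenbrains,
        scores=scores,
        singular_values=s[:k].copy(),
        variance_fraction=variance_fraction,
        latent_roots=latent_roots,
    )


def variance_explained(singular_values: np.ndarray) -> np.ndarray:
    """Fraction of covariance per component: s_i^2 / sum_j s_j^2."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0) or np.any(np.diff(s) > 0):
        raise ValueError("singular values must be nonnegative and descending")
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("all singular values are zero")
    return s**2 / total


def latent_roots_from_singular_values(singular_values: np.ndarray, n_subjects: int,
                                      n_voxels: int) -> np.ndarray:
    """Rescale component variances so a random spectrum averages 1."""
    s = np.asarray(singular_values, dtype=float)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("all singular values are zero")
    return s**2 * min(n_subjects - 1, n_voxels) / total


def latent_root_retention(decomp: EigenDecomposition) -> RetentionResult:
    """Keep the prefix of components whose latent root exceeds 1 (strict)."""
    roots = np.asarray(decomp.latent_roots, dtype=float)
    above = roots > 1.0
    n_retained = int(np.argmin(above)) if not above.all() else int(above.size)
    return RetentionResult(n_retained=n_retained, rule="latent_root_gt1")


def parallel_analysis(matrix: SubjectMatrix | np.ndarray, n_iter: int = 500,
                      percentile: float = 95.0, seed: int = 0) -> RetentionResult:
    """Monte-Carlo parallel analysis against random normal matrices.

    Latent roots of the observed matrix are compared component-wise with
    the given percentile of roots from ``n_iter`` standard-normal
    matrices of identical dimensions.  If the observed matrix was
    robustly scaled, each null matrix is scaled the same way so the null
    is exchangeable with the data under H0.  Retained components are the
    longest prefix exceeding their null threshold.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (50, 100)")
    scaled = isinstance(matrix, SubjectMatrix) and matrix.scaled
    values = matrix.values if isinstance(matrix, SubjectMatrix) else np.asarray(matrix, dtype=float)
    n, p = values.shape
    m = min(n, p)

    decomp = decompose(values)
    observed = np.zeros(m)
    observed[: decomp.latent_roots.size] = decomp.latent_roots

    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, m))
    for it in range(n_iter):
        noise = rng.standard_normal((n, p))
        if scaled:
            for i in range(n):
                noise[i] = robust_scale_row(noise[i])[0]
        gram = noise @ noise.T if p >= n else noise.T @ noise
        evals = np.sort(np.clip(np.linalg.eigvalsh(gram), 0.0, None))[::-1][:m]
        null[it] = evals * min(n - 1, p) / evals.sum()
    thresholds = np.percentile(null, percentile, axis=0)

    above = observed > thresholds
    n_retained = int(np.argmin(above)) if not above.all() else int(above.size)
    return RetentionResult(n_retained=n_retained, rule="parallel_analysis",
                           null_roots=thresholds, seed=seed)


def project(decomp: EigenDecomposition, new_rows: np.ndarray) -> np.ndarray:
    """Score new subjects (rows preprocessed identically) on the components."""
    new_rows = np.atleast_2d(np.asarray(new_rows, dtype=float))
    if new_rows.shape[1] != decomp.n_voxels:
        raise ValueError(
            f"column count {new_rows.shape[1]} != n_voxels {decomp.n_voxels}"
        )
    return new_rows @ decomp.eigenbrains.T


def rescale_scores_percentile(scores: np.ndarray) -> np.ndarray:
    """Map each score column to 0-100 by rank (min -> 0, max -> 100, ties averaged)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    out = np.empty_like(scores)
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if np.ptp(col) == 0:
            raise ValueError(f"score column {k} is constant")
        out[:, k] = (rankdata(col, method="average") - 1.0) / (n - 1) * 100.0
    return out
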