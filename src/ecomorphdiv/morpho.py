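"""Landmark geometric morphometrics and meristic analyses.

Generalized Procrustes analysis (GPA) removes translation, scale, and
rotation from 2-D landmark configurations; PCA of the Procrustes residuals
yields shape axes, which are compared between ecomorphs with Welch
two-tailed t-tests on every PC capturing at least 5% of total variance.
Also here: PCA of standardized radula ratio meristics and the substrate x
morph abundance chi-squared test (Pearson, no continuity correction).

Semi-landmarks are treated as fixed landmarks (no sliding).  Rotations are
proper (no reflection): the optimal rotation's determinant is forced +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProcrustesResult:
    """Aligned configurations (n, k, 2), mean shape, centroid sizes."""

    aligned: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def residuals(self) -> np.ndarray:
        return self.aligned - self.mean_shape


@dataclass
class ShapePca:
    scores: np.ndarray  # (n, r)
    variance_fraction: np.ndarray  # (r,)
    loadings: np.ndarray  # (r, p) rows are orthonormal axes
    mean: np.ndarray  # (p,) mean of the flattened input


def _center_and_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return centered / size, size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper 2-D rotation R minimizing ||source @ R - target||_F.

    Via SVD of the cross-covariance; reflections are disallowed by sign
    correction of the last singular vector.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def procrustes_gpa(
    configs: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> ProcrustesResult:
    """Generalized Procrustes superimposition of (n, k, 2) configurations.

    Iterates: center each configuration, scale to unit centroid size,
    rotate to the current mean, update the mean and renormalize it to unit
    size, until the mean shape moves less than ``tol`` or ``max_iter`` is
    reached.
    """
    configs = np.asarray(configs, dtype=float)
    n, k, _ = configs.shape
    if k < 3:
        raise ValueError("need >= 3 landmarks")
    if n < 2:
        raise ValueError("need >= 2 specimens")
    aligned = np.empty_like(configs)
    sizes = np.empty(n)
    for i in range(n):
        aligned[i], sizes[i] = _center_and_scale(configs[i])
    mean = _center_and_scale(aligned[0])[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], mean)
        new_mean = aligned.mean(axis=0)
        new_mean = _center_and_scale(new_mean)[0]
        # anchor orientation to the previous mean: without this the mean
        # can rotate indefinitely on high-variance data
        new_mean = new_mean @ optimal_rotation(new_mean, mean)
        delta = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if delta < tol:
            converged = True
            break
    return ProcrustesResult(aligned, mean, sizes, it, converged)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (after
    centering, unit scaling, and optimal rotation)."""
    a_, _ = _center_and_scale(np.asarray(a, dtype=float))
    b_, _ = _center_and_scale(np.asarray(b, dtype=float))
    rot = optimal_rotation(a_, b_)
    return float(np.sqrt(((a_ @ rot - b_) ** 2).sum()))


def shape_pca(result: ProcrustesResult) -> ShapePca:
    """PCA of the flattened Procrustes residuals (SVD of centered data)."""
    x = result.residuals.reshape(result.aligned.shape[0], -1)
    return pca(x)


def pca(x: np.ndarray) -> ShapePca:
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # drop numerically null axes
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    s, vt, u = s[keep], vt[keep], u[:, keep]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else var
    scores = u * s
    return ShapePca(scores=scores, variance_fraction=frac, loadings=vt, mean=mean)


def pc_group_tests(
    pca_result: ShapePca,
    labels: np.ndarray | list[str],
    min_var: float = 0.05,
) -> pd.DataFrame:
    """Welch two-tailed t-tests per PC with variance fraction >= min_var.

    PCs below the variance gate appear with ``tested=False`` and NaN
    statistics.  Exactly two label groups, each with n >= 2, are required.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    mask_a = labels == groups[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for i, frac in enumerate(pca_result.variance_fraction):
        if frac >= min_var:
            t, p = stats.ttest_ind(
                pca_result.scores[mask_a, i],
                pca_result.scores[~mask_a, i],
                equal_var=False,
            )
            rows.append((i + 1, float(frac), True, float(t), float(p)))
        else:
            rows.append((i + 1, float(frac), False, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["pc", "variance_fraction", "tested", "t", "p"])


def radula_meristics_pca(
    measurements: pd.DataFrame,
    labels: np.ndarray | list[str],
    min_var: float = 0.05,
) -> tuple[ShapePca, pd.DataFrame]:
    """PCA of radula ratio meristics (unit-variance standardized) + tests.

    Constant variables are dropped with a warning.  Columns are the
    meristic variables (e.g. denticle width / total height ratio, rachis
    width ratio, denticle count).
    """
    import warnings

    x = measurements.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(measurements.columns[~keep])
        warnings.warn(f"constant variables dropped: {dropped}")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    result = pca(x)
    return result, pc_group_tests(result, labels, min_var=min_var)


def habitat_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on the 2x2
    substrate x morph abundance table."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must be non-negative integers")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
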