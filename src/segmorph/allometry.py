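"""Morphological allometry: multivariate regression of superimposed shape
coordinates on centroid size.

The fit reports the percentage of total shape variation explained, Wilks'
lambda (computed on the reduced-rank PC basis, since Procrustes coordinates
are rank-deficient), and a permutation p-value obtained by shuffling the
size labels.  Size enters untransformed by default; a log-size option
exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .procrustes_core import AlignedDataset

__all__ = ["AllometryFit", "fit_allometry", "predict_shape_at_size", "size_adjust"]


@dataclass
class AllometryFit:
    slope: np.ndarray                  # shape change per unit size, (d,)
    intercept: np.ndarray              # (d,)
    pct_variance_explained: float
    wilks_lambda: float
    p_value: float | None
    predicted_extremes: tuple[np.ndarray, np.ndarray]
    sizes: np.ndarray
    mean_shape: np.ndarray
    log_size: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def size_range(self) -> tuple[float, float]:
        return float(self.sizes.min()), float(self.sizes.max())


def _as_matrix(shapes) -> np.ndarray:
    if isinstance(shapes, AlignedDataset):
        return shapes.flat()
    arr = np.asarray(shapes, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    return arr


def fit_allometry(
    shapes,
    sizes: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    log_size: bool = False,
    rank_tol: float = 1e-9,
) -> AllometryFit:
    """Multivariate least-squares regression of shape on centroid size.

    ``shapes`` is an :class:`AlignedDataset` (sizes taken from it unless
    given) or an (n, d) / (n, k, 2) array.  Wilks' lambda is evaluated on the
    scores of all PCs with nonzero variance; its significance comes from
    ``n_perm`` random permutations of the sizes with
    p = (#{lambda_perm <= lambda_obs} + 1) / (n_perm + 1).
    """
    Y = _as_matrix(shapes)
    if sizes is None:
        if not isinstance(shapes, AlignedDataset):
            raise ValueError("sizes are required unless shapes is an AlignedDataset")
        sizes = shapes.centroid_sizes
    x = np.asarray(sizes, dtype=float)
    if log_size:
        x = np.log(x)
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 configurations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: sizes are constant")
    if n_perm > 0 and seed is None:
        raise ValueError("a seed is required for the permutation test")

    n = Y.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    mean_shape = Y.mean(axis=0)
    Yc = Y - mean_shape
    slope = (xc @ Yc) / sxx
    intercept = mean_shape - slope * x.mean()
    fitted = np.outer(xc, slope)
    ss_total = float((Yc ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    pct = 100.0 * ss_fit / ss_total if ss_total > 0 else 0.0

    # Wilks' lambda on the nonzero-variance PC basis: with one predictor,
    # lambda = det(E)/det(E + H) = 1 - h' T^{-1} h, T the (diagonal) total
    # SSCP of the PC scores and h the score/size cross-moment.
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    keep = s > (s[0] * rank_tol if s[0] > 0 else np.inf)
    scores = Yc @ vt[keep].T          # (n, m), columns orthogonal
    w = (scores ** 2).sum(axis=0)     # diagonal of total SSCP
    sx = np.sqrt(sxx)

    def wilks(xcv: np.ndarray) -> float:
        h = scores.T @ xcv / sx
        return float(1.0 - np.sum(h * h / w))

    lam = wilks(xc)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            lam_p = wilks(xc[rng.permutation(n)])
            if lam_p <= lam + 1e-15:
                hits += 1
        p = (hits + 1.0) / (n_perm + 1.0)

    lo, hi = float(x.min()), float(x.max())
    extremes = (intercept + slope * lo, intercept + slope * hi)
    return AllometryFit(
        slope=slope, intercept=intercept,
        pct_variance_explained=pct, wilks_lambda=lam, p_value=p,
        predicted_extremes=extremes, sizes=np.asarray(sizes, dtype=float),
        mean_shape=mean_shape, log_size=log_size,
        meta={"n": n, "n_perm": n_perm, "seed": seed},
    )


def predict_shape_at_size(fit: AllometryFit, size: float) -> np.ndarray:
    """Predicted (flattened) shape at a given centroid size; warns when
    extrapolating outside the observed size range."""
    x = np.log(size) if fit.log_size else float(size)
    lo, hi = fit.size_range
    raw = np.log((lo, hi)) if fit.log_size else (lo, hi)
    if not (min(raw) <= x <= max(raw)):
        warnings.warn(f"size {size} outside the observed range [{lo}, {hi}]",
                      UserWarning)
    return fit.intercept + fit.slope * x


def size_adjust(shapes, sizes: np.ndarray | None = None,
                log_size: bool = False) -> tuple[np.ndarray, AllometryFit]:
    """Remove the allometric subspace: return (mean shape + residuals) of the
    shape-on-size regression, suitable as input to the nested ANOVA, together
    with the fit used."""
    fit = fit_allometry(shapes, sizes=sizes, n_perm=0, log_size=log_size)
    Y = _as_matrix(shapes)
    x = np.asarray(sizes if sizes is not None else shapes.centroid_sizes, dtype=float)
    if log_size:
        x = np.log(x)
    fitted = fit.intercept + np.outer(x, fit.slope)
    residuals = Y - fitted
    return fit.mean_shape + residuals, fit
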