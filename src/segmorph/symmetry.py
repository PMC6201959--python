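"""Object-symmetry machinery.

A bilaterally symmetric outline is analyzed by pairing each configuration
with its reflected, relabeled copy: x-coordinates are negated and the
left/right landmark labels swapped so the copy is a valid configuration of
the same scheme.  Originals and copies are jointly superimposed and a PCA of
the superimposed coordinates then splits exactly into *symmetric* axes (on
which original and copy score identically) and *asymmetric* axes (on which
their scores are sign-opposite).  Per-object total shape asymmetry is the
size of the score vector restricted to the asymmetric axes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import LandmarkScheme, OutlineConfiguration
from .procrustes_core import AlignedDataset, gpa

logger = logging.getLogger(__name__)

__all__ = [
    "reflect_relabel",
    "SymmetryDecomposition",
    "build_symmetry_dataset",
    "symmetric_and_asymmetric_components",
    "total_asymmetry",
]

CLASSIFICATION_TOL = 0.99


def reflect_relabel(config: OutlineConfiguration,
                    scheme: LandmarkScheme) -> OutlineConfiguration:
    """Reflect a configuration across the vertical symmetry axis and relabel
    paired landmarks so point order stays consistent with the original.

    On-axis landmarks keep their labels; applying the operation twice is the
    identity.  The ``reflected`` flag is toggled.
    """
    pts = config.points
    if pts.shape[0] != scheme.n_points:
        raise ValueError("configuration size does not match scheme")
    mirrored = pts.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    perm = scheme.swap_permutation()
    return config.copy(points=mirrored[perm], reflected=not config.reflected)


def reflect_points(points: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Array version of :func:`reflect_relabel` (negate x, swap pairs)."""
    out = points.copy()
    out[:, 0] = -out[:, 0]
    return out[scheme.swap_permutation()]


@dataclass
class SymmetryDecomposition:
    """Joint alignment of originals + reflected copies with a classified PCA.

    The first ``n_originals`` rows of the alignment are the originals, the
    following ``n_originals`` rows their reflected/relabeled copies in the
    same order.  ``axis_class`` holds "symmetric"/"asymmetric" per PC.
    """

    alignment: AlignedDataset
    scheme: LandmarkScheme
    n_originals: int
    mean_flat: np.ndarray
    pc_vectors: np.ndarray          # (d, m) columns are eigenvectors
    variances: np.ndarray           # (m,) eigenvalues
    variance_fractions: np.ndarray  # (m,) sums to 1
    axis_class: np.ndarray          # (m,) strings
    scores: np.ndarray              # (2n, m)
    score_mirror_correlations: np.ndarray = field(default=None)

    @property
    def symmetric_axes(self) -> np.ndarray:
        return np.where(self.axis_class == "symmetric")[0]

    @property
    def asymmetric_axes(self) -> np.ndarray:
        return np.where(self.axis_class == "asymmetric")[0]


def build_symmetry_dataset(
    configs,
    scheme: LandmarkScheme,
    treatment: str = "unslid",
    n_slide_iter: int = 3,
    rank_tol: float = 1e-9,
) -> SymmetryDecomposition:
    """Jointly superimpose originals and their reflected/relabeled copies
    (one GPA under the chosen semilandmark treatment), run a covariance PCA
    of the superimposed coordinates, and classify each axis as symmetric or
    asymmetric via the score-mirroring criterion.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("need at least 2 original configurations")
    reflected = [reflect_relabel(c, scheme) for c in configs]
    combined = configs + reflected
    aligned = gpa(combined, scheme=scheme, treatment=treatment,
                  n_slide_iter=n_slide_iter)

    X = aligned.flat()
    mean = X.mean(axis=0)
    Xc = X - mean
    # covariance PCA via SVD; axes with numerically zero variance dropped
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * rank_tol if s[0] > 0 else np.zeros_like(s, dtype=bool)
    s = s[keep]
    V = vt[keep].T
    variances = s ** 2 / (X.shape[0] - 1)
    fractions = variances / variances.sum()
    scores = Xc @ V

    n = len(configs)
    so, sr = scores[:n], scores[n:]
    classes = np.empty(len(s), dtype=object)
    corrs = np.empty(len(s))
    for j in range(len(s)):
        a, b = so[:, j], sr[:, j]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        c = float(a @ b / denom) if denom > 0 else 1.0
        corrs[j] = c
        if c >= CLASSIFICATION_TOL:
            classes[j] = "symmetric"
        elif c <= -CLASSIFICATION_TOL:
            classes[j] = "asymmetric"
        else:
            warnings.warn(
                f"PC{j + 1}: ambiguous symmetry classification (corr = {c:.3f}); "
                "possibly tied eigenvalues", UserWarning)
            classes[j] = "symmetric" if c >= 0 else "asymmetric"

    return SymmetryDecomposition(
        alignment=aligned,
        scheme=scheme,
        n_originals=n,
        mean_flat=mean,
        pc_vectors=V,
        variances=variances,
        variance_fractions=fractions,
        axis_class=classes,
        scores=scores,
        score_mirror_correlations=corrs,
    )


def symmetric_and_asymmetric_components(decomp: SymmetryDecomposition
                                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-object symmetric and asymmetric shape components.

    The symmetric component is the mean of an aligned original and its
    reflected copy; the asymmetric component is half their difference.  Their
    sum reconstructs the aligned original exactly.
    Returns two (n, d) arrays (flattened coordinates).
    """
    X = decomp.alignment.flat()
    n = decomp.n_originals
    orig, refl = X[:n], X[n:]
    return (orig + refl) / 2.0, (orig - refl) / 2.0


def total_asymmetry(decomp: SymmetryDecomposition,
                    statistic: str = "norm") -> np.ndarray:
    """Total shape asymmetry per original object from asymmetric PC scores.

    ``statistic="norm"`` (default): Euclidean norm of the score vector over
    the asymmetric axes.  ``statistic="sum_abs"``: sum of per-axis absolute
    scores.  Both are invariant to the original/reflected choice, and zero
    for an exactly symmetric object.
    """
    axes = decomp.asymmetric_axes
    s = decomp.scores[:decomp.n_originals][:, axes]
    if statistic == "norm":
        return np.linalg.norm(s, axis=1) if s.size else np.zeros(decomp.n_originals)
    if statistic == "sum_abs":
        return np.abs(s).sum(axis=1) if s.size else np.zeros(decomp.n_originals)
    raise ValueError(f"unknown statistic {statistic!r}")
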