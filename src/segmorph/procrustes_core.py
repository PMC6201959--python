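"""Procrustes geometry: centroid size, pairwise alignment, generalized
Procrustes analysis (GPA), and tangent-space Procrustes distances.

Conventions
-----------
Partial Procrustes superimposition: every configuration is translated to the
origin and scaled to unit centroid size; rotations are proper (det +1) —
reflections are never introduced by alignment (the symmetry machinery adds
reflected copies explicitly).  The consensus is the iterated mean, re-scaled
to unit centroid size, and its orientation is made reproducible by rotating
the symmetry axis (fixed landmark at the bottom) to the vertical when a
scheme is supplied.

Distances are tangent-space ("tangent PD"): aligned configurations are
orthogonally projected onto the tangent plane at the consensus pole and
Euclidean distances taken there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import LandmarkScheme, OutlineConfiguration

logger = logging.getLogger(__name__)

__all__ = [
    "centroid_size",
    "center_and_scale",
    "align_pair",
    "optimal_rotation",
    "gpa",
    "AlignedDataset",
    "procrustes_distance",
    "tangent_coordinates",
    "riemannian_distance",
]

GPA_TOL = 1e-7
GPA_MAX_ITER = 100


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distances of points from their centroid.

    The standard geometric-morphometric size measure; scales linearly under
    isotropic scaling.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points identical")
    return cs


def center_and_scale(points: np.ndarray) -> np.ndarray:
    """Translate centroid to origin and scale to unit centroid size."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    return centered / centroid_size(pts)


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper 2D rotation matrix minimizing ||source @ R - target||_F.

    Reflections are excluded: if the SVD solution has det -1 the sign of the
    smallest singular direction is flipped.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


def align_pair(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Full partial-Procrustes fit of one configuration onto a reference.

    Translates to the origin, scales to unit centroid size, and applies the
    optimal proper rotation toward ``reference`` (itself assumed centered).
    """
    pts = np.asarray(points, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pts.shape != ref.shape:
        raise ValueError(f"dimension mismatch: {pts.shape} vs {ref.shape}")
    x = center_and_scale(pts)
    return x @ optimal_rotation(x, ref - ref.mean(axis=0))


@dataclass
class AlignedDataset:
    """A superimposed set of configurations.

    ``coords`` has shape (n, k, 2); each slice is centered with unit centroid
    size.  ``centroid_sizes`` are those of the raw inputs.  ``configs`` keeps
    the input metadata in the same order.
    """

    coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    treatment: str
    configs: list[OutlineConfiguration] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.coords.shape[0])

    @property
    def k(self) -> int:
        return int(self.coords.shape[1])

    def flat(self) -> np.ndarray:
        """(n, 2k) view of the aligned coordinates."""
        return self.coords.reshape(self.n, -1)

    def mean_distance_to_consensus(self) -> float:
        t = tangent_coordinates(self.coords, self.consensus)
        tc = tangent_coordinates(self.consensus[None], self.consensus)
        return float(np.linalg.norm(t - tc, axis=1).mean())

    def max_distance_to_consensus(self) -> float:
        t = tangent_coordinates(self.coords, self.consensus)
        tc = tangent_coordinates(self.consensus[None], self.consensus)
        return float(np.linalg.norm(t - tc, axis=1).max())

    def mean_pairwise_distance(self) -> float:
        """Mean tangent distance over all configuration pairs (alternative
        summary to the default distance-to-consensus)."""
        t = tangent_coordinates(self.coords, self.consensus)
        d = np.linalg.norm(t[:, None] - t[None], axis=2)
        iu = np.triu_indices(self.n, k=1)
        return float(d[iu].mean())


def _orient_to_axis(consensus: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Rotation placing the scheme's symmetry axis vertical, fixed point down."""
    a, b = scheme.axis0
    v = consensus[b] - consensus[a]
    angle = np.arctan2(v[0], v[1])  # rotate v onto +y
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def _superimpose_to(coords: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Rotate every (already centered, unit-size) slice onto the consensus."""
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        out[i] = coords[i] @ optimal_rotation(coords[i], consensus)
    return out


def gpa(
    configs: Sequence[OutlineConfiguration] | np.ndarray,
    scheme: LandmarkScheme | None = None,
    treatment: str = "unslid",
    n_slide_iter: int = 3,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
    refresh_consensus: bool = True,
) -> AlignedDataset:
    """Generalized Procrustes analysis with optional semilandmark sliding.

    ``treatment`` selects how semilandmarks are handled: ``"unslid"`` treats
    them as fixed points; ``"min_be"`` and ``"min_pd"`` interleave a sliding
    step (minimum bending energy / minimum Procrustes distance, delegated to
    :mod:`segmorph.semilandmark_tools`) with re-superimposition.

    Iterates align-to-mean until the consensus moves less than ``tol``; if
    ``max_iter`` is exceeded a warning is issued and the best iterate
    returned with ``converged=False``.
    """
    if treatment not in ("unslid", "min_be", "min_pd"):
        raise ValueError(f"unknown treatment {treatment!r}")
    if treatment != "unslid" and scheme is None:
        raise ValueError("sliding treatments require a landmark scheme")

    if isinstance(configs, np.ndarray):
        raw = np.asarray(configs, dtype=float)
        meta = []
    else:
        meta = list(configs)
        raw = np.stack([c.points for c in meta]).astype(float)
    n, k, _ = raw.shape
    if n < 2:
        raise ValueError("GPA needs at least two configurations")

    sizes = np.array([centroid_size(raw[i]) for i in range(n)])
    coords = np.stack([center_and_scale(raw[i]) for i in range(n)])

    consensus = center_and_scale(coords[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        coords = _superimpose_to(coords, consensus)
        new_consensus = center_and_scale(coords.mean(axis=0))
        shift = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", RuntimeWarning)

    diagnostics: dict = {}
    if treatment != "unslid":
        from . import semilandmark_tools as slt

        slide = slt.slide_min_be if treatment == "min_be" else slt.slide_min_pd
        for cycle in range(n_slide_iter):
            coords, diag = slide(coords, consensus, scheme)
            # renormalize and re-superimpose after sliding
            coords = np.stack([center_and_scale(c) for c in coords])
            for _ in range(max_iter):
                coords = _superimpose_to(coords, consensus)
                new_consensus = center_and_scale(coords.mean(axis=0))
                shift = np.linalg.norm(new_consensus - consensus)
                if refresh_consensus:
                    consensus = new_consensus
                if shift < tol or not refresh_consensus:
                    break
            diagnostics.setdefault("slide_cycles", []).append(diag)

    if scheme is not None:
        rot = _orient_to_axis(consensus, scheme)
        consensus = consensus @ rot
        coords = coords @ rot

    ds = AlignedDataset(
        coords=coords,
        consensus=consensus,
        centroid_sizes=sizes,
        treatment=treatment,
        configs=meta,
        converged=converged,
        n_iterations=it,
        diagnostics=diagnostics,
    )
    ds.diagnostics["mean_pd"] = ds.mean_distance_to_consensus()
    ds.diagnostics["max_pd"] = ds.max_distance_to_consensus()
    return ds


def tangent_coordinates(coords: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent plane at the
    consensus pole.

    ``coords`` may be (n, k, 2) or (k, 2); returns flattened (n, 2k) tangent
    vectors: x_t = x - (x . c) c with c the unit consensus vector.
    """
    arr = np.asarray(coords, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    n = arr.shape[0]
    x = arr.reshape(n, -1)
    c = consensus.ravel()
    c = c / np.linalg.norm(c)
    t = x - np.outer(x @ c, c)
    return t[0] if single else t


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, consensus: np.ndarray | None = None
) -> float:
    """Tangent-space Procrustes distance between two configurations of one
    alignment.

    If ``consensus`` is None the two shapes are aligned pairwise first and
    the distance taken in the tangent plane at ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations differ in shape; not from one alignment")
    if consensus is None:
        a0 = center_and_scale(a)
        b0 = align_pair(b, a0)
        consensus = a0
        a, b = a0, b0
    ta = tangent_coordinates(a, consensus)
    tb = tangent_coordinates(b, consensus)
    return float(np.linalg.norm(ta - tb))


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full (non-linearized) Procrustes distance rho = arccos of the matched
    inner product between unit-size shapes, reflections excluded."""
    a0 = center_and_scale(np.asarray(a, dtype=float))
    b0 = align_pair(np.asarray(b, dtype=float), a0)
    inner = float(np.clip((a0 * b0).sum(), -1.0, 1.0))
    return float(np.arccos(inner))
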