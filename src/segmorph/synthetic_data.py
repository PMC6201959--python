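"""Synthetic hierarchical populations of bilaterally symmetric outlines.

The generator emulates the statistical structure the nested analyses assume:
two localities, plants nested in localities, segments nested in plants, two
digitization replicates per segment, with

* a mirror-symmetric bean-shaped base outline (radial cosine series),
* size-coupled (allometric) symmetric shape variation,
* plant-level directional asymmetry (a fixed antisymmetric deformation per
  plant),
* segment-level fluctuating asymmetry (i.i.d. antisymmetric noise), and
* replicate-level digitization noise on every coordinate.

Asymmetric perturbations are built in an explicitly antisymmetric basis —
radial sine fields, which apply +delta to a left-side point and the mirrored
-delta to its pair — so injected DA/FA lie exactly in the asymmetric
subspace of the landmark scheme and variance bookkeeping is exact.  FA and
digitization noise are applied in absolute coordinate units, so after
Procrustes rescaling smaller segments carry relatively larger asymmetry —
the size-to-asymmetry coupling seen in real outline data.

All randomness flows from one seed through per-level child streams, so
changing segment counts does not shift plant-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import LandmarkScheme, OutlineConfiguration, study_scheme
from .semilandmark_tools import resample_equidistant

__all__ = ["SyntheticSpec", "base_outline", "generate", "study_like_preset"]

# bean / reniform base: gentle top-bottom eccentricity plus lateral bulge
DEFAULT_HARMONICS = {1: -0.10, 2: 0.15, 3: 0.04}
_SYM_MODES = (1, 2, 3, 4)
_ASYM_MODES = (1, 2, 3)


@dataclass
class SyntheticSpec:
    """All generator parameters.  Magnitudes are displacement scales on the
    unit-radius base outline unless noted; ``fa_sd`` and ``me_sd`` are in
    absolute coordinate units (the same units as the scaled outlines)."""

    n_localities: int = 2
    plants_per_locality: int = 8
    segments_per_plant: int | tuple[int, int] | Sequence[int] = (6, 12)
    n_points: int = 90
    locality_median_sizes: tuple[float, ...] = (1.0, 1.22)
    plant_size_log_sd: float = 0.15
    segment_size_log_sd: float = 0.10
    allometry_slope: float = 0.35
    plant_symmetric_sd: float = 0.02
    symmetric_sd: float = 0.035
    da_magnitude: float = 0.005
    fa_sd: float = 0.015
    me_sd: float = 0.004
    base_harmonics: dict = field(default_factory=lambda: dict(DEFAULT_HARMONICS))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plant_size_log_sd", "segment_size_log_sd", "plant_symmetric_sd",
                     "symmetric_sd", "da_magnitude", "fa_sd", "me_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_points % 2 != 0 or self.n_points < 6:
            raise ValueError("n_points must be even and >= 6")
        if len(self.locality_median_sizes) != self.n_localities:
            raise ValueError("one median size per locality is required")

    def scheme(self) -> LandmarkScheme:
        return study_scheme(self.n_points)


def base_outline(harmonics: dict | None = None, n_points: int = 90,
                 r0: float = 1.0, n_dense: int = 4096) -> np.ndarray:
    """Mirror-symmetric closed base curve r(phi) = r0 (1 + sum a_m cos m phi),
    sampled at arc-length equidistant positions with point 1 at the basal
    pole (phi = 0, pointing down).

    The cosine-only series guarantees exact mirror symmetry; after numeric
    resampling the point set is re-symmetrized so paired points are exact
    mirror images under the scheme pairing.
    """
    if harmonics is None:
        harmonics = dict(DEFAULT_HARMONICS)
    phi = np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
    r = np.full_like(phi, r0, dtype=float)
    for m, a in harmonics.items():
        r = r + r0 * a * np.cos(m * phi)
    if np.any(r <= 0):
        raise ValueError("harmonics produce non-positive radius")
    dense = np.column_stack([r * np.sin(phi), -r * np.cos(phi)])
    pts = resample_equidistant(dense, n_points, fixed_start=0)
    # exact symmetrization under the scheme pairing
    scheme = study_scheme(n_points)
    perm = scheme.swap_permutation()
    mirror = pts[perm].copy()
    mirror[:, 0] = -mirror[:, 0]
    return (pts + mirror) / 2.0


def _radial_directions(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    v = points - c
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _symmetric_fields(n_points: int, radial: np.ndarray) -> np.ndarray:
    """(len(_SYM_MODES), k, 2) radial cosine displacement fields."""
    t = np.arange(n_points) / n_points
    return np.stack([np.cos(2 * np.pi * m * t)[:, None] * radial for m in _SYM_MODES])


def _antisymmetric_fields(n_points: int, radial: np.ndarray) -> np.ndarray:
    """(len(_ASYM_MODES), k, 2) radial sine displacement fields; exactly
    antisymmetric under the scheme pairing (zero on the axis points)."""
    t = np.arange(n_points) / n_points
    return np.stack([np.sin(2 * np.pi * m * t)[:, None] * radial for m in _ASYM_MODES])


def _resolve_counts(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n_plants = spec.n_localities * spec.plants_per_locality
    s = spec.segments_per_plant
    if isinstance(s, int):
        return np.full(n_plants, s)
    if isinstance(s, tuple) and len(s) == 2 and all(isinstance(v, (int, np.integer)) for v in s):
        return rng.integers(s[0], s[1] + 1, size=n_plants)
    counts = np.asarray(list(s), dtype=int)
    if len(counts) != n_plants:
        raise ValueError("explicit segment counts must list every plant")
    return counts


def generate(spec: SyntheticSpec):
    """Draw a full hierarchical dataset.

    Returns ``(configs, metadata, truth)``: a list of
    :class:`OutlineConfiguration` (two replicates per segment, file order =
    metadata order), the sidecar metadata DataFrame, and a truth record
    holding every drawn effect for parameter-recovery tests.  Identical seed,
    identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_design, ss_plants, ss_segments, ss_reps = root.spawn(4)
    rng_design = np.random.default_rng(ss_design)

    base = base_outline(spec.base_harmonics, spec.n_points)
    base_cs = float(np.sqrt(((base - base.mean(axis=0)) ** 2).sum()))
    radial = _radial_directions(base)
    sym_fields = _symmetric_fields(spec.n_points, radial)
    asym_fields = _antisymmetric_fields(spec.n_points, radial)
    # allometric direction: a fixed symmetric field combination
    allo_field = sym_fields[0] + 0.5 * sym_fields[1]

    counts = _resolve_counts(spec, rng_design)
    n_plants = len(counts)

    plant_streams = ss_plants.spawn(n_plants)
    seg_streams = ss_segments.spawn(n_plants)
    rep_streams = ss_reps.spawn(n_plants)

    configs: list[OutlineConfiguration] = []
    meta_rows = []
    truth = {
        "spec": asdict(spec),
        "base_outline": base,
        "base_centroid_size": base_cs,
        "allometry_field": allo_field,
        "plant_da_fields": {},
        "plant_da_fields_tangent": {},
        "segment_sizes": {},
        "segment_fa_fields": {},
        "segment_symmetric_fields": {},
        "mean_log_size": None,
    }

    # pass 1: sizes, so the allometric term can center on the mean log size
    plant_sizes = []
    seg_sizes_all = []
    for p in range(n_plants):
        loc = p // spec.plants_per_locality
        rng_p = np.random.default_rng(plant_streams[p])
        plant_median = spec.locality_median_sizes[loc] * np.exp(
            rng_p.normal(0.0, spec.plant_size_log_sd))
        plant_sizes.append(plant_median)
        rng_s = np.random.default_rng(seg_streams[p])
        sizes = plant_median * np.exp(
            rng_s.normal(0.0, spec.segment_size_log_sd, size=counts[p]))
        seg_sizes_all.append(sizes)
    mean_log_size = float(np.mean(np.log(np.concatenate(seg_sizes_all))))
    truth["mean_log_size"] = mean_log_size

    cfg_index = 0
    for p in range(n_plants):
        loc = p // spec.plants_per_locality
        loc_name = chr(ord("A") + loc)
        plant_name = f"{loc_name}P{p % spec.plants_per_locality + 1:02d}"
        rng_p = np.random.default_rng(plant_streams[p])
        rng_p.normal()  # advance past the size draw
        da_coef = rng_p.normal(0.0, 1.0, size=len(_ASYM_MODES))
        nrm = np.linalg.norm(da_coef)
        da_coef = da_coef / nrm if nrm > 0 else da_coef
        da_field = spec.da_magnitude * np.tensordot(da_coef, asym_fields, axes=1)
        plant_sym = spec.plant_symmetric_sd * np.tensordot(
            rng_p.normal(0.0, 1.0, size=len(_SYM_MODES)), sym_fields, axes=1)
        truth["plant_da_fields"][plant_name] = da_field
        truth["plant_da_fields_tangent"][plant_name] = da_field / base_cs

        rng_s = np.random.default_rng(seg_streams[p])
        rng_s.normal(size=counts[p])  # advance past the size draws
        rng_r = np.random.default_rng(rep_streams[p])
        sizes = seg_sizes_all[p]

        for si in range(counts[p]):
            seg_name = f"{plant_name}S{si + 1:02d}"
            size = float(sizes[si])
            sym_noise = spec.symmetric_sd * np.tensordot(
                rng_s.normal(0.0, 1.0, size=len(_SYM_MODES)), sym_fields, axes=1)
            fa_coef = rng_s.normal(0.0, 1.0, size=len(_ASYM_MODES))
            # fa_sd is absolute: divide by size so the scaled field has the
            # requested absolute magnitude
            fa_field = (spec.fa_sd / size) * np.tensordot(fa_coef, asym_fields, axes=1)
            allo = spec.allometry_slope * (np.log(size) - mean_log_size) * allo_field

            unit_shape = base + allo + plant_sym + sym_noise + da_field + fa_field
            shape = size * unit_shape
            truth["segment_sizes"][seg_name] = size
            truth["segment_fa_fields"][seg_name] = fa_field
            truth["segment_symmetric_fields"][seg_name] = allo + plant_sym + sym_noise

            for rep in (1, 2):
                noisy = shape + rng_r.normal(0.0, spec.me_sd, size=shape.shape)
                configs.append(OutlineConfiguration(
                    points=noisy, segment_id=seg_name, plant_id=plant_name,
                    locality=loc_name, replicate=rep))
                cfg_index += 1
                meta_rows.append({"config_index": cfg_index, "locality": loc_name,
                                  "plant": plant_name, "segment": seg_name,
                                  "replicate": rep})

    metadata = pd.DataFrame(meta_rows)
    return configs, metadata, truth


# counts for the study-like preset: 96 plants, 982 segments in total, and a
# median per-plant count of 9.5 (48th/49th sorted values are 9 and 10)
_STUDY_COUNTS = [9] * 48 + [10] * 14 + [12] * 32 + [13] * 2


def study_like_preset(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """A spec mirroring the field study's design: 2 localities x 48 plants,
    982 segments with median count 9.5, locality A median size 18% below
    locality B, and nonzero allometry/DA/FA defaults.

    ``scale`` < 1 shrinks the design proportionally (plants and segment
    counts) for quick runs while keeping the same effect magnitudes.
    """
    if scale >= 1.0:
        ppl = 48
        counts = sorted(_STUDY_COUNTS)
    else:
        ppl = max(2, int(round(48 * scale)))
        n_plants = 2 * ppl
        reps = int(np.ceil(n_plants / len(_STUDY_COUNTS)))
        counts = sorted((_STUDY_COUNTS * reps)[:n_plants])
    # deal the sorted counts alternately to the two localities so both get
    # the same count distribution (plants are laid out locality-major)
    loc_a = counts[0::2]
    loc_b = counts[1::2]
    return SyntheticSpec(
        n_localities=2,
        plants_per_locality=ppl,
        segments_per_plant=list(loc_a + loc_b),
        n_points=90,
        locality_median_sizes=(0.82, 1.0),
        seed=seed,
    )
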