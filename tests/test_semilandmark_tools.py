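import numpy as np
import pytest

from segmorph.io_formats import OutlineConfiguration, study_scheme
from segmorph.procrustes_core import centroid_size, gpa
from segmorph.semilandmark_tools import (
    bending_energy,
    build_bending_kernel,
    resample_equidistant,
    slide_min_be,
    slide_min_pd,
    tangent_directions,
    treatment_effect_anova,
)
from segmorph.symmetry import reflect_points
from tests.conftest import random_outline


def polyline_arclengths(curve: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Arc positions of pts along the closed input polyline (independent
    re-measurement used as the resampling oracle)."""
    closed = np.vstack([curve, curve[:1]])
    seglen = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    out = []
    for p in pts:
        best = None
        for i in range(len(seglen)):
            v = closed[i + 1] - closed[i]
            t = np.clip(v @ (p - closed[i]) / (v @ v), 0, 1)
            proj = closed[i] + t * v
            d = np.linalg.norm(p - proj)
            s = cum[i] + t * seglen[i]
            if best is None or d < best[0]:
                best = (d, s)
        out.append(best[1])
    return np.array(out)


class TestResample:
    def test_square_to_corners_and_midpoints(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        out = resample_equidistant(square, 8)
        expected = np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5],
                             [1, 1], [0.5, 1], [0, 1], [0, 0.5]], dtype=float)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_idempotence_on_equidistant_curve(self):
        phi = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        circle = np.column_stack([np.cos(phi), np.sin(phi)])
        out = resample_equidistant(circle, 40)
        np.testing.assert_allclose(out, circle, atol=1e-12)

    def test_spacing_uniform_along_input(self, rng):
        curve = random_outline(rng, n_points=400, wobble=0.15)
        out = resample_equidistant(curve, 90)
        s = polyline_arclengths(curve, out)
        spacing = np.diff(s)
        closed = np.vstack([curve, curve[:1]])
        perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert np.abs(spacing - perimeter / 90).max() < 1e-9

    def test_fixed_start_retained(self, rng):
        curve = random_outline(rng, n_points=50)
        out = resample_equidistant(curve, 20, fixed_start=7)
        np.testing.assert_array_equal(out[0], curve[7])

    def test_oversampling_warns(self, rng):
        curve = random_outline(rng, n_points=5)
        with pytest.warns(UserWarning, match="resolution"):
            resample_equidistant(curve, 90)


class TestTangents:
    def test_circle_tangent_perpendicular_to_radius(self):
        scheme = study_scheme(24)
        phi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        circle = np.column_stack([np.sin(phi), -np.cos(phi)])
        u = tangent_directions(circle, scheme)
        dots = np.abs((u * circle).sum(axis=1))
        assert dots.max() < 1e-9

    def test_collinear_triple(self):
        scheme = study_scheme(6)
        pts = np.array([[0, 0], [1, 0.0], [2, 0], [2, 1], [1, 1], [0, 1]],
                       dtype=float)
        u = tangent_directions(pts, scheme)
        np.testing.assert_allclose(np.abs(u[1]), [1, 0], atol=1e-12)

    def test_analytic_curve_oracle(self):
        """Neighbor-chord tangents track the analytic tangent of a smooth
        bean curve within 2 degrees at 90 points."""
        scheme = study_scheme(90)
        t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        r = 1 + 0.15 * np.cos(2 * t) - 0.1 * np.cos(t)
        pts = np.column_stack([r * np.sin(t), -r * np.cos(t)])
        u = tangent_directions(pts, scheme)
        # analytic derivative via dense finite differences
        td = np.linspace(0, 2 * np.pi, 200000, endpoint=False)
        rd = 1 + 0.15 * np.cos(2 * td) - 0.1 * np.cos(td)
        dense = np.column_stack([rd * np.sin(td), -rd * np.cos(td)])
        grad = np.gradient(dense, td, axis=0)
        idx = (t / (2 * np.pi) * len(td)).astype(int)
        ana = grad[idx] / np.linalg.norm(grad[idx], axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(np.abs((u * ana).sum(axis=1)), 0, 1)))
        assert ang.max() < 2.0

    def test_coincident_neighbors_error(self):
        scheme = study_scheme(6)
        pts = np.array([[0, 0], [1, 0], [0, 0], [2, 1], [1, 2], [0, 1]],
                       dtype=float)
        with pytest.raises(ValueError, match="coincident"):
            tangent_directions(pts, scheme)


class TestBendingEnergy:
    def test_affine_null_space(self, rng):
        ref = random_outline(rng, n_points=24)
        kernel = build_bending_kernel(ref)
        B = kernel.bending_matrix
        k = ref.shape[0]
        assert np.abs(B @ np.ones(k)).max() < 1e-8
        assert np.abs(B @ ref[:, 0]).max() < 1e-8
        assert np.abs(B @ ref[:, 1]).max() < 1e-8
        assert bending_energy(kernel, ref) < 1e-10
        affine = ref @ np.array([[1.3, 0.2], [-0.4, 0.9]]) + np.array([2.0, 1.0])
        assert bending_energy(kernel, affine) < 1e-8

    def test_nonnegative_and_positive_for_bent_target(self, rng):
        ref = random_outline(rng, n_points=24)
        kernel = build_bending_kernel(ref)
        bent = ref.copy()
        bent[3] += [0.2, -0.1]
        assert bending_energy(kernel, bent) > 1e-6

    def test_independent_assembly_oracle(self, rng):
        """Energy from the block-inverse bending matrix equals the energy
        computed by solving the TPS interpolation system directly:
        E = sum_c w_c' K w_c with w_c = (L^-1 [v_c; 0])[:k]."""
        ref = rng.normal(size=(4, 2))
        target = rng.normal(size=(4, 2))
        kernel = build_bending_kernel(ref)
        e1 = bending_energy(kernel, target)

        k = 4
        d2 = ((ref[:, None] - ref[None]) ** 2).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            K = 0.5 * d2 * np.log(d2)
        K[d2 == 0] = 0
        Q = np.column_stack([np.ones(k), ref])
        L = np.block([[K, Q], [Q.T, np.zeros((3, 3))]])
        e2 = 0.0
        for c in range(2):
            sol = np.linalg.solve(L, np.concatenate([target[:, c], np.zeros(3)]))
            w = sol[:k]
            e2 += float(w @ K @ w)
        assert abs(e1 - e2) < 1e-10

    def test_duplicate_reference_points_rejected(self):
        ref = np.array([[0, 0], [1, 1], [1, 1], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="singular"):
            build_bending_kernel(ref)


def _aligned_pair(rng, n_points=24, noise=0.05):
    scheme = study_scheme(n_points)
    base = random_outline(rng, n_points=n_points)
    shapes = np.stack([base + noise * rng.normal(size=base.shape)
                       for _ in range(4)])
    ds = gpa(shapes, scheme=scheme)
    return ds, scheme


class TestSlideMinPd:
    def test_consensus_configuration_does_not_move(self, rng):
        ds, scheme = _aligned_pair(rng)
        coords = np.concatenate([ds.consensus[None], ds.coords])
        out, diag = slide_min_pd(coords, ds.consensus, scheme)
        np.testing.assert_allclose(out[0], ds.consensus, atol=1e-12)

    def test_perpendicular_deviation_does_not_move(self):
        scheme = study_scheme(8)
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        consensus = np.column_stack([np.sin(phi), -np.cos(phi)])
        cfg = consensus.copy()
        u = tangent_directions(cfg, scheme)
        normal = np.array([-u[3, 1], u[3, 0]])
        cfg[3] += 0.05 * normal   # consensus point deviates only off-tangent
        out, _ = slide_min_pd(cfg[None], consensus, scheme)
        np.testing.assert_allclose(out[0, 3], cfg[3], atol=1e-12)

    def test_grid_search_oracle(self, rng):
        """Each slid point is at least as close to its consensus target as
        any position on a fine grid along its tangent."""
        ds, scheme = _aligned_pair(rng)
        out, _ = slide_min_pd(ds.coords, ds.consensus, scheme)
        i = 0
        pts = ds.coords[i]
        u = tangent_directions(pts, scheme)
        for j in scheme.sliding0[:5]:
            ts = np.arange(-0.2, 0.2, 1e-4)
            cand = pts[j] + ts[:, None] * u[j]
            grid_best = np.linalg.norm(cand - ds.consensus[j], axis=1).min()
            ours = np.linalg.norm(out[i, j] - ds.consensus[j])
            assert ours <= grid_best + 1e-8

    def test_fixed_landmark_bit_identical(self, rng):
        ds, scheme = _aligned_pair(rng)
        out, _ = slide_min_pd(ds.coords, ds.consensus, scheme)
        np.testing.assert_array_equal(out[:, scheme.fixed0], ds.coords[:, scheme.fixed0])

    def test_distance_to_target_never_increases(self, rng):
        ds, scheme = _aligned_pair(rng)
        out, _ = slide_min_pd(ds.coords, ds.consensus, scheme)
        before = np.linalg.norm(ds.coords - ds.consensus, axis=2)
        after = np.linalg.norm(out - ds.consensus, axis=2)
        assert np.all(after <= before + 1e-12)


class TestSlideMinBe:
    def test_affine_related_configuration_does_not_slide(self, rng):
        scheme = study_scheme(24)
        base = random_outline(rng, n_points=24)
        affine = base @ np.array([[1.1, 0.05], [-0.05, 0.95]])
        out, diag = slide_min_be(affine[None], base, scheme)
        np.testing.assert_allclose(out[0], affine, atol=1e-7)

    def test_identical_shapes_do_not_slide(self, rng):
        scheme = study_scheme(24)
        base = random_outline(rng, n_points=24)
        coords = np.stack([base, base])
        out, _ = slide_min_be(coords, base, scheme)
        np.testing.assert_allclose(out, coords, atol=1e-9)

    def test_energy_never_increases_and_local_grid_optimality(self, rng):
        ds, scheme = _aligned_pair(rng)
        from segmorph.semilandmark_tools import build_bending_kernel
        kernel = build_bending_kernel(ds.consensus)
        out, diag = slide_min_be(ds.coords, ds.consensus, scheme)
        assert diag["total_be_after"] <= diag["total_be_before"] + 1e-12
        # grid search along one point's tangent cannot improve the optimum
        i = 1
        pts = out[i]
        u = tangent_directions(ds.coords[i], scheme)
        e_opt = bending_energy(kernel, pts)
        j = scheme.sliding0[4]
        ts = np.arange(-0.05, 0.05, 1e-4)
        for t in ts:
            cand = pts.copy()
            cand[j] = cand[j] + t * u[j]
            assert bending_energy(kernel, cand) >= e_opt - 1e-10

    def test_fixed_landmark_bit_identical(self, rng):
        ds, scheme = _aligned_pair(rng)
        out, _ = slide_min_be(ds.coords, ds.consensus, scheme)
        np.testing.assert_array_equal(out[:, scheme.fixed0], ds.coords[:, scheme.fixed0])

    def test_symmetric_dataset_stays_symmetric(self):
        """Sliding a dataset of exactly mirror-symmetric shapes keeps the
        pairs mirrored."""
        from segmorph.synthetic_data import SyntheticSpec, generate

        spec = SyntheticSpec(plants_per_locality=2, segments_per_plant=3,
                             n_points=24, da_magnitude=0, fa_sd=0, me_sd=0,
                             seed=5)
        configs, meta, _ = generate(spec)
        scheme = spec.scheme()
        ds = gpa(configs, scheme=scheme, treatment="min_be")
        for i in range(ds.n):
            refl = reflect_points(ds.coords[i], scheme)
            from segmorph.procrustes_core import procrustes_distance
            assert procrustes_distance(ds.coords[i], refl) < 1e-6


class TestTreatmentAnova:
    def test_dataset_against_itself(self, rng):
        from segmorph.synthetic_data import SyntheticSpec, generate

        spec = SyntheticSpec(plants_per_locality=2, segments_per_plant=3,
                             n_points=24, seed=9)
        configs, _, _ = generate(spec)
        scheme = spec.scheme()
        ds = gpa(configs, scheme=scheme)
        table = treatment_effect_anova(ds, ds)
        treat = table["treatment (segment)"]
        err = table["digitization error"]
        assert treat.MS == pytest.approx(0.0, abs=1e-16)
        assert treat.F == pytest.approx(0.0, abs=1e-10)
        assert err.MS > 0

    def test_hand_computed_ss_and_offset_scaling(self, rng):
        """Treatment MS grows as delta^2 for an injected per-treatment offset
        and the decomposition matches hand-computed sums of squares."""
        rng = np.random.default_rng(7)
        n_seg, k = 3, 12
        base = [random_outline(rng, n_points=k) for _ in range(n_seg)]

        def build(delta):
            a_cfgs, b_cfgs = [], []
            ids = []
            for s, b0 in enumerate(base):
                for rep in (1, 2):
                    noisy = b0 + 0.001 * rng.normal(size=b0.shape)
                    a_cfgs.append(noisy)
                    shifted = noisy.copy()
                    shifted[2] += delta   # treatment-specific displacement
                    b_cfgs.append(shifted)
                    ids.append(f"s{s}")
            from segmorph.procrustes_core import AlignedDataset
            A = np.stack(a_cfgs)
            B = np.stack(b_cfgs)
            dsa = gpa(A)
            # hand over *identically framed* data: bypass alignment effects
            # by treating raw coordinates as already superimposed
            dsa = AlignedDataset(coords=A, consensus=A.mean(axis=0),
                                 centroid_sizes=np.ones(len(A)), treatment="a")
            dsb = AlignedDataset(coords=B, consensus=B.mean(axis=0),
                                 centroid_sizes=np.ones(len(B)), treatment="b")
            return dsa, dsb, np.array(ids)

        ms = []
        for delta in (0.02, 0.04):
            dsa, dsb, ids = build(delta)
            table = treatment_effect_anova(dsa, dsb, segment_ids=ids)
            table.validate(rtol=1e-6)

            # independent oracle: redo the pooling + joint GPA, then compute
            # every SS with explicit per-group loops
            pooled = np.concatenate([dsa.coords, dsb.coords])
            joint = gpa(pooled)
            Y = joint.flat()
            seg = np.concatenate([ids, ids])
            treat = np.array([0] * len(ids) + [1] * len(ids))
            grand = Y.mean(axis=0)
            ss_seg = ss_treat = ss_err = 0.0
            for s in np.unique(seg):
                block = Y[seg == s]
                m_s = block.mean(axis=0)
                ss_seg += len(block) * ((m_s - grand) ** 2).sum()
                for tr in (0, 1):
                    cell = Y[(seg == s) & (treat == tr)]
                    m_c = cell.mean(axis=0)
                    ss_treat += len(cell) * ((m_c - m_s) ** 2).sum()
                    ss_err += ((cell - m_c) ** 2).sum()
            assert table["segment"].SS == pytest.approx(ss_seg, rel=1e-9)
            assert table["treatment (segment)"].SS == pytest.approx(ss_treat, rel=1e-9)
            assert table["digitization error"].SS == pytest.approx(ss_err, rel=1e-9)
            ms.append(table["treatment (segment)"].MS)
        # variance scaling: MS ratio approx (0.04/0.02)^2 = 4 (alignment
        # perturbs it slightly)
        assert ms[1] / ms[0] == pytest.approx(4.0, rel=0.25)
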