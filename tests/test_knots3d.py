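"""Knot classification: fixtures, invariance, simplification safety, determinants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fractalknots import beta_model as bm
from fractalknots import knots3d as k3


FIXTURES = [("unknot", 50, 1), ("trefoil", 60, 3), ("figure_eight", 80, 5)]


class TestFixtures:
    @pytest.mark.parametrize("name,n,det", FIXTURES)
    def test_fixture_determinants(self, name, n, det, rng, warm_numba):
        call = k3.classify_knot(k3.make_fixture(name, n), rng)
        assert call.determinant == det
        assert call.is_trivial == (det == 1)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            k3.make_fixture("granny", 60)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            k3.make_fixture("trefoil", 10)


class TestSimplify:
    def test_planar_convex_polygon_reduces_to_triangle(self, warm_numba):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        assert k3.simplify_chain(circle).shape[0] == 3

    def test_idempotent(self, warm_numba):
        pts = k3.make_fixture("trefoil", 120)
        once = k3.simplify_chain(pts)
        twice = k3.simplify_chain(once)
        np.testing.assert_array_equal(once, twice)

    def test_output_is_subset_of_input(self, rng, warm_numba):
        sp = bm.build_spectrum(120, 3.0, 3)
        pts = bm.sample_rings(sp, 1, rng)[0]
        simp = k3.simplify_chain(pts)
        as_rows = {tuple(r) for r in pts}
        assert all(tuple(r) in as_rows for r in simp)

    @pytest.mark.parametrize("name,n,det", FIXTURES)
    def test_preserves_knot_call(self, name, n, det, rng, warm_numba):
        pts = k3.make_fixture(name, n)
        with_s = k3.classify_knot(pts, rng, simplify=True)
        without = k3.classify_knot(pts, rng, simplify=False)
        assert with_s.determinant == without.determinant == det


class TestDiagram:
    def test_circle_projects_to_zero_crossings(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        diagram = k3.build_diagram(circle, np.array([0.0, 0.0, 1.0]))
        assert diagram.n_crossings == 0
        assert k3.alexander_determinant(diagram) == 1

    def test_trefoil_has_at_least_three_crossings(self, rng):
        pts = k3.make_fixture("trefoil", 60)
        diagram = k3.build_diagram(pts, k3._random_direction(rng))
        assert diagram.n_crossings >= 3

    def test_in_plane_projection_is_degenerate(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        with pytest.raises(k3.DegenerateProjection):
            k3.build_diagram(circle, np.array([1.0, 0.0, 0.0]))

    def test_alexander_matrix_rows_sum_to_zero(self, rng):
        pts = k3.make_fixture("figure_eight", 80)
        diagram = k3.build_diagram(pts, k3._random_direction(rng))
        mat = k3.alexander_matrix(diagram)
        assert np.all(mat.sum(axis=1) == 0)

    def test_inconsistent_diagram_rejected(self):
        bad = k3.KnotDiagram(crossings=((5, 0, 1, 1),), n_arcs=1, direction=None)
        with pytest.raises(ValueError):
            k3.alexander_matrix(bad)


class TestDeterminant:
    def test_modular_crt_matches_bareiss(self, rng, warm_numba):
        # dual route: fast CRT determinant vs pure-integer Bareiss elimination
        sp = bm.build_spectrum(100, 3.5, 3)
        checked = 0
        for pts in bm.sample_rings(sp, 30, rng):
            simp = k3.simplify_chain(pts)
            try:
                diagram = k3.build_diagram(simp, k3._random_direction(rng))
            except k3.DegenerateProjection:
                continue
            if diagram.n_crossings < 3:
                continue
            mat = k3.alexander_matrix(diagram)[:-1, :-1]
            assert k3._exact_det(mat) == k3.bareiss_determinant(mat)
            checked += 1
        assert checked >= 10

    def test_determinants_are_odd(self, rng, warm_numba):
        sp = bm.build_spectrum(100, 3.0, 3)
        pos = bm.sample_rings(sp, 100, rng)
        _, _, dets = k3.classify_batch(pos, rng)
        assert all(d % 2 == 1 and d >= 1 for d in dets)


class TestInvariance:
    @pytest.mark.parametrize("name,n,det", FIXTURES)
    def test_rigid_motion_and_scale(self, name, n, det, warm_numba):
        pts = k3.make_fixture(name, n)
        rng = np.random.default_rng(3)
        for _ in range(10):
            rot = Rotation.random(rng=rng).as_matrix()
            alpha = float(rng.uniform(0.1, 10.0))
            shift = rng.standard_normal(3) * 5
            moved = alpha * pts @ rot.T + shift
            assert k3.classify_knot(moved, rng).determinant == det

    def test_classification_is_projection_independent(self, rng, warm_numba):
        sp = bm.build_spectrum(120, 3.5, 3)
        for pts in bm.sample_rings(sp, 10, rng):
            a = k3.classify_knot(pts, np.random.default_rng(1))
            b = k3.classify_knot(pts, np.random.default_rng(2))
            assert a.determinant == b.determinant

    def test_simplification_safety_smoke(self, rng, warm_numba):
        # the full 10^3-ring safety property runs in the acceptance suite
        sp = bm.build_spectrum(150, 3.0, 3)
        for pts in bm.sample_rings(sp, 60, rng):
            with_s = k3.classify_knot(pts, rng, simplify=True)
            without = k3.classify_knot(pts, rng, simplify=False)
            assert with_s.determinant == without.determinant


class TestBatch:
    def test_batch_matches_single_calls(self, rng, warm_numba):
        sp = bm.build_spectrum(80, 4.0, 3)
        pos = bm.sample_rings(sp, 40, rng)
        trivial, crossings, dets = k3.classify_batch(pos, np.random.default_rng(0))
        singles = [
            k3.classify_knot(p, np.random.default_rng(i)) for i, p in enumerate(pos)
        ]
        assert [c.is_trivial for c in singles] == trivial.tolist()
        assert [c.determinant for c in singles] == dets

    def test_projection_crossing_counts_shape(self, rng):
        sp = bm.build_spectrum(30, 3.0, 3)
        pos = bm.sample_rings(sp, 17, rng)
        counts = k3.projection_crossing_counts(pos)
        assert counts.shape == (17,)
        assert np.all(counts >= 0)
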