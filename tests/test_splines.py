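"""B-spline bases, design assembly, and curvature penalties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.interpolate import BSpline

from dtgam.data_model import expand_person_period
from dtgam.datasets import deceased_patient_example
from dtgam.splines import (
    LinearTermSpec,
    SmoothTermSpec,
    build_design,
    evaluate_basis,
    penalty_matrix,
    place_knots,
)


def cox_de_boor(x, t, j, k):
    """Brute-force Cox-de Boor recursion for basis function j of degree k."""
    if k == 0:
        # right-closed at the last breakpoint so the partition covers t[-1]
        if t[j] <= x < t[j + 1] or (x == t[-1] and t[j] < t[j + 1] <= t[-1]
                                    and t[j + 1] == t[-1]):
            return 1.0
        return 0.0
    out = 0.0
    if t[j + k] > t[j]:
        out += (x - t[j]) / (t[j + k] - t[j]) * cox_de_boor(x, t, j, k - 1)
    if t[j + k + 1] > t[j + 1]:
        out += (t[j + k + 1] - x) / (t[j + k + 1] - t[j + 1]) * cox_de_boor(
            x, t, j + 1, k - 1
        )
    return out


def make_spec(values, n_interior=4, degree=3, name="x"):
    spec = SmoothTermSpec(name, n_interior=n_interior, degree=degree)
    spec.ensure_knots(values)
    return spec


class TestKnotPlacement:
    def test_single_interior_knot_at_median(self):
        values = np.arange(1.0, 101.0)
        t = place_knots(values, n_interior=1, degree=3)
        assert t[4] == pytest.approx(np.median(values))
        assert t[0] == 1.0 and t[-1] == 100.0
        assert len(t) == 1 + 2 * 4

    def test_uniform_sample_gives_equispaced_quantiles(self, rng):
        values = rng.uniform(0, 1, size=20000)
        t = place_knots(values, n_interior=10, degree=3)
        interior = t[4:-4]
        assert np.allclose(interior, np.arange(1, 11) / 11, atol=0.02)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            place_knots(np.ones(50), n_interior=3)

    def test_knots_nondecreasing(self, rng):
        t = place_knots(rng.lognormal(size=500), n_interior=10)
        assert np.all(np.diff(t) >= 0)


class TestBasisEvaluation:
    def test_partition_of_unity(self, rng):
        values = rng.uniform(-2, 7, size=200)
        spec = make_spec(values, n_interior=6)
        B = evaluate_basis(values, spec)
        assert B.shape == (200, spec.basis_dim)
        assert np.all(B >= 0)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_cox_de_boor_recursion(self, seed):
        """Degree-3 basis values agree with an independent brute-force recursion."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 10, size=60)
        spec = make_spec(values, n_interior=3)
        xs = rng.uniform(values.min(), values.max(), size=5)
        B = evaluate_basis(xs, spec)
        t = spec.knots
        for i, x in enumerate(xs):
            expected = [cox_de_boor(x, t, j, 3) for j in range(spec.basis_dim)]
            np.testing.assert_allclose(B[i], expected, atol=1e-10)

    def test_clamping_out_of_range(self):
        spec = make_spec(np.linspace(0, 1, 50), n_interior=2)
        with pytest.warns(UserWarning, match="clamping"):
            B = evaluate_basis([2.0], spec)
        np.testing.assert_allclose(B, evaluate_basis([1.0], spec))
        with pytest.raises(ValueError):
            evaluate_basis([2.0], spec, clamp=False)


class TestPenalty:
    def test_linear_function_has_zero_roughness(self, rng):
        values = rng.uniform(0, 5, size=100)
        spec = make_spec(values, n_interior=5)
        S = penalty_matrix(spec, centered=False)
        # coefficients reproducing a + b*x: use interpolation at Greville points
        t, k = spec.knots, spec.degree
        greville = np.array(
            [t[j + 1 : j + k + 1].mean() for j in range(spec.basis_dim)]
        )
        beta = 2.0 + 3.0 * greville  # exact for linear functions
        assert beta @ S @ beta == pytest.approx(0.0, abs=1e-8)

    def test_quadratic_form_matches_quadrature(self, rng):
        """beta' S beta equals the adaptive-quadrature integral of (s'')^2."""
        values = rng.uniform(0, 4, size=80)
        spec = make_spec(values, n_interior=4)
        S = penalty_matrix(spec, centered=False)
        beta = rng.normal(size=spec.basis_dim)
        s2 = BSpline(spec.knots, beta, spec.degree).derivative(2)
        total = 0.0
        breaks = np.unique(spec.knots)
        for a, b in zip(breaks[:-1], breaks[1:]):
            total += quad(lambda x: s2(x) ** 2, a, b, limit=200)[0]
        assert beta @ S @ beta == pytest.approx(total, rel=1e-8)

    def test_symmetric_psd_with_two_dim_null_space(self, rng):
        spec = make_spec(rng.uniform(0, 1, size=60), n_interior=6)
        S = penalty_matrix(spec, centered=False)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        eigs = np.linalg.eigvalsh(S)
        assert np.all(eigs > -1e-8 * eigs.max())
        scale = eigs.max()
        assert int(np.sum(eigs < 1e-10 * scale)) == 2  # constants + linears

    def test_degree_below_two_rejected(self, rng):
        spec = make_spec(rng.uniform(0, 1, 60), n_interior=3, degree=1)
        with pytest.raises(ValueError, match="degree"):
            penalty_matrix(spec, centered=False)


class TestDesign:
    def test_linear_only_model_is_two_columns(self, small_table):
        design = build_design(small_table, [LinearTermSpec("age")])
        assert design.Z.shape == (small_table.n_rows, 2)
        assert np.all(design.Z[:, 0] == 1.0)

    def test_centered_smooth_block_dimensions(self, small_table):
        """10 interior cubic knots give 14 basis functions, 13 after centering."""
        design = build_design(
            small_table,
            [SmoothTermSpec("pro", n_interior=10), SmoothTermSpec("bili", n_interior=10)],
        )
        assert design.blocks["pro"] == slice(1, 14)
        assert design.blocks["bili"] == slice(14, 27)
        assert design.Z.shape[1] == 27
        for name in ("pro", "bili"):
            assert design.penalties[name].shape == (13, 13)

    def test_centered_columns_have_zero_mean_effect(self, small_table):
        design = build_design(small_table, [SmoothTermSpec("bili")])
        block = design.Z[:, design.blocks["bili"]]
        np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-12)

    def test_example_patient_rows(self):
        table = expand_person_period([deceased_patient_example()])
        design = build_design(
            table, [LinearTermSpec("age"), SmoothTermSpec("bili", n_interior=2)]
        )
        assert design.n_rows == 7

    def test_deterministic(self, small_table):
        terms = lambda: [LinearTermSpec("age"), SmoothTermSpec("bili", n_interior=5)]
        Z1 = build_design(small_table, terms()).Z
        Z2 = build_design(small_table, terms()).Z
        np.testing.assert_array_equal(Z1, Z2)

    def test_time_term_uses_interval_midpoints(self, small_table):
        spec = SmoothTermSpec("time", n_interior=4)
        build_design(small_table, [spec])
        mids = small_table.frame["midpoint"]
        assert spec.knots[0] == mids.min() and spec.knots[-1] == mids.max()

    def test_duplicate_terms_rejected(self, small_table):
        with pytest.raises(ValueError, match="duplicate"):
            build_design(small_table, [LinearTermSpec("age"), LinearTermSpec("age")])
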