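import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastmeta.errors import (
    DegenerateMatrixError,
    InsufficientSampleError,
    StructureError,
    UndefinedAngleError,
)
from plastmeta.study_data import UNIT_KEYS
from plastmeta.vector_geometry import (
    PMatrix,
    angle_directed,
    angle_undirected,
    centroid,
    classify_alignment,
    comparison_geometry,
    difference_vector,
    eigen_decomposition,
    eigen_ratio,
    log_length_difference,
    p_matrix,
    projection_fraction,
    variance_change,
)

from conftest import make_comparison, make_unit

finite_vec = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=2, max_size=6
)


class TestCentroidAndP:
    def test_centroid_arithmetic(self):
        unit = make_unit("AinA", [[0, 0], [2, 2], [1, 1]])
        np.testing.assert_allclose(centroid(unit).values, [1, 1])

    def test_centroid_single_individual(self):
        unit = make_unit("AinA", [[3.5, -1]])
        np.testing.assert_allclose(centroid(unit).values, [3.5, -1])

    def test_centroid_matches_summation_oracle(self, rng):
        x = rng.standard_normal((8, 3))
        unit = make_unit("AinB", x, traits=("a", "b", "c"))
        oracle = np.array([x[:, j].sum() / 8 for j in range(3)])
        np.testing.assert_allclose(centroid(unit).values, oracle, atol=1e-12)

    def test_p_matrix_rejects_n2(self):
        unit = make_unit("AinA", [[0, 0], [1, 1]])
        with pytest.raises(InsufficientSampleError):
            p_matrix(unit)

    def test_p_matrix_one_dimensional_spread(self):
        unit = make_unit("AinA", [[0, 0], [1, 0], [2, 0]])
        np.testing.assert_allclose(p_matrix(unit).values, [[1, 0], [0, 0]], atol=1e-12)

    def test_p_matrix_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal((10, 2))
        unit = make_unit("BinB", x)
        m = x.mean(axis=0)
        oracle = sum(np.outer(r - m, r - m) for r in x) / 9
        np.testing.assert_allclose(p_matrix(unit).values, oracle, atol=1e-12)


class TestDifferenceVector:
    def test_identical_units_give_zero(self):
        u = make_unit("AinA", [[1, 2], [3, 4], [2, 3]])
        v = difference_vector(u, u, "plasticity_A")
        np.testing.assert_allclose(v.values, [0, 0])

    def test_three_four_five(self):
        a = make_unit("AinA", np.zeros((3, 2)))
        b = make_unit("AinB", np.tile([3.0, 4.0], (3, 1)))
        v = difference_vector(a, b, "plasticity_A")
        np.testing.assert_allclose(v.values, [3, 4])
        assert v.length == pytest.approx(5.0)

    def test_mismatched_traits_raise(self):
        a = make_unit("AinA", np.zeros((3, 2)))
        b = make_unit("AinB", np.zeros((3, 3)), traits=("a", "b", "c"))
        with pytest.raises(StructureError):
            difference_vector(a, b, "plasticity_A")


class TestAngles:
    @pytest.mark.parametrize(
        "v1, v2, expected",
        [
            ([1, 0], [0, 1], 90.0),
            ([1, 0], [-1, 0], 180.0),
            ([1, 0], [1, 1], 45.0),
            ([2, 0, 0], [2, 0, 0], 0.0),
        ],
    )
    def test_directed_analytic(self, v1, v2, expected):
        assert angle_directed(np.array(v1, float), np.array(v2, float)) == pytest.approx(
            expected, abs=1e-10
        )

    @pytest.mark.parametrize(
        "axis, v, expected",
        [
            ([1, 0], [0, 1], 90.0),
            ([1, 0], [-1, 0], 0.0),
            ([np.sqrt(0.5), np.sqrt(0.5)], [1, 0], 45.0),
        ],
    )
    def test_undirected_analytic(self, axis, v, expected):
        assert angle_undirected(np.array(axis, float), np.array(v, float)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_zero_vector_is_undefined(self):
        with pytest.raises(UndefinedAngleError):
            angle_directed(np.zeros(2), np.array([1.0, 0.0]))

    @given(v=finite_vec, w=finite_vec, scale=st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_directed_symmetry_scale_and_reflection(self, v, w, scale):
        n = min(len(v), len(w))
        a, b = np.array(v[:n]), np.array(w[:n])
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        ang = angle_directed(a, b)
        assert 0.0 <= ang <= 180.0
        assert angle_directed(b, a) == pytest.approx(ang, abs=1e-5)
        assert angle_directed(scale * a, b) == pytest.approx(ang, abs=1e-5)
        assert angle_directed(a, -b) == pytest.approx(180.0 - ang, abs=1e-5)

    @given(v=finite_vec, w=finite_vec)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_undirected_is_folded_directed(self, v, w):
        n = min(len(v), len(w))
        a, b = np.array(v[:n]), np.array(w[:n])
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        d = angle_directed(a, b)
        assert angle_undirected(a / np.linalg.norm(a), b) == pytest.approx(
            min(d, 180.0 - d), abs=1e-5
        )


class TestEigen:
    def test_diagonal(self):
        axes = eigen_decomposition(PMatrix([[4, 0], [0, 1]], n=10))
        assert [a.eigenvalue for a in axes] == [4.0, 1.0]
        np.testing.assert_allclose(axes[0].values, [1, 0])

    def test_identity_tie_break_prefers_first_trait(self):
        axes = eigen_decomposition(PMatrix(np.eye(2), n=10))
        np.testing.assert_allclose(axes[0].values, [1, 0], atol=1e-12)

    def test_spectral_reconstruction(self, rng):
        a = rng.standard_normal((3, 3))
        P = PMatrix(a @ a.T, n=10)
        axes = eigen_decomposition(P)
        recon = sum(ax.eigenvalue * np.outer(ax.values, ax.values) for ax in axes)
        np.testing.assert_allclose(recon, P.values, atol=1e-8)

    @pytest.mark.parametrize(
        "mat, expected",
        [
            (np.eye(2), 1.0),
            (np.diag([4.0, 1.0]), 0.25),
            (np.outer([1.0, 2.0], [1.0, 2.0]), 0.0),
        ],
    )
    def test_eigen_ratio(self, mat, expected):
        assert eigen_ratio(PMatrix(mat, n=10)) == pytest.approx(expected, abs=1e-12)

    def test_eigen_ratio_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            eigen_ratio(PMatrix(np.zeros((2, 2)), n=10))


class TestProjectionAndClassification:
    @pytest.mark.parametrize(
        "p, t, expected",
        [
            ([0.5, 0], [1, 0], 50.0),
            ([2, 0], [1, 0], 200.0),
            ([-1, 0], [1, 0], -100.0),
        ],
    )
    def test_projection_fraction(self, p, t, expected):
        assert projection_fraction(np.array(p, float), np.array(t, float)) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize(
        "angle, frac, expected",
        [
            (120.0, -40.0, "opposite"),
            (30.0, 200.0, "overshoot"),
            (30.0, 60.0, "undershoot"),
            (90.0, 0.0, "undershoot"),  # documented tie rule
        ],
    )
    def test_classify(self, angle, frac, expected):
        assert classify_alignment(angle, frac) == expected

    @given(v=finite_vec, w=finite_vec)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_opposite_iff_negative_projection_iff_obtuse(self, v, w):
        n = min(len(v), len(w))
        p, t = np.array(v[:n]), np.array(w[:n])
        if np.linalg.norm(p) < 1e-6 or np.linalg.norm(t) < 1e-6:
            return
        ang = angle_directed(p, t)
        frac = projection_fraction(p, t)
        if abs(ang - 90.0) < 1e-6:
            return  # boundary: tie rule tested separately
        assert (classify_alignment(ang, frac) == "opposite") == (frac < 0) == (ang > 90)


class TestLengthsAndVariance:
    def test_log_length_difference(self):
        assert log_length_difference(np.array([1.0, 0]), np.array([1.0, 0])) == 0.0
        e = np.e
        assert log_length_difference(np.array([e, 0.0]), np.array([1.0, 0])) == pytest.approx(1.0)
        assert log_length_difference(np.array([3.0, 4.0]), np.array([1.0, 0])) == pytest.approx(
            np.log(5), abs=1e-12
        )

    @pytest.mark.parametrize(
        "foreign, home, expected",
        [
            (np.eye(2), np.eye(2), 0.0),
            (np.diag([1.1, 1.1]), np.diag([1.0, 1.0]), 10.0),
            (np.diag([1.0, 1.0]), np.diag([0.5, 0.5]), 100.0),
        ],
    )
    def test_variance_change(self, foreign, home, expected):
        assert variance_change(
            PMatrix(foreign, n=10), PMatrix(home, n=10)
        ) == pytest.approx(expected)


class TestComparisonGeometry:
    def test_exact_antiparallel_plasticity(self):
        comp = make_comparison(
            {"AinA": [0, 0], "AinB": [1, 0], "BinB": [1, 1], "BinA": [0, 1]}
        )
        geom = comparison_geometry(comp)
        # plasticity_A = (1,0); plasticity_B = BinB->BinA = (-1,0)
        assert geom.statistics["angle_pp"] == pytest.approx(180.0, abs=1e-9)

    def test_total_equals_plasticity(self):
        comp = make_comparison(
            {"AinA": [0, 0], "AinB": [2, 0], "BinB": [2, 0], "BinA": [0, 0]}
        )
        geom = comparison_geometry(comp)
        assert geom.statistics["angle_pt"] == pytest.approx(0.0, abs=1e-9)
        assert geom.statistics["projection_pct"] == pytest.approx(100.0, abs=1e-9)

    def test_undefined_components_are_nan_not_fatal(self):
        comp = make_comparison({k: [0, 0] for k in UNIT_KEYS})
        geom = comparison_geometry(comp)
        assert np.isnan(geom.statistics["angle_pt"])
        assert geom.classification is None
        assert np.isfinite(geom.statistics["eigen_ratio_AinA"])
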