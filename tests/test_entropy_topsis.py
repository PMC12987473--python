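import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import melonopt as m
from melonopt.entropy_topsis import (
    closeness,
    entropy_values,
    entropy_weights,
    ideal_solutions,
    mean_scaled_matrix,
    normalize_matrix,
    proportion_matrix,
    separation_distances,
    weighted_matrix,
)
from melonopt.trial_data import PRINTED_QUALITY_RANKING, PRINTED_TOPSIS


# ---------------------------------------------------------------------------
# Independent straight-from-formula oracle: plain python loops, no shared
# code with the pipeline under test.
# ---------------------------------------------------------------------------

def naive_topsis(rows, scaling="mean"):
    a, b = len(rows), len(rows[0])
    norm = [
        [rows[i][j] / math.sqrt(sum(rows[k][j] ** 2 for k in range(a)))
         for j in range(b)]
        for i in range(a)
    ]
    p = [
        [norm[i][j] / sum(norm[k][j] for k in range(a)) for j in range(b)]
        for i in range(a)
    ]
    h = [
        -sum(p[i][j] * math.log(p[i][j]) for i in range(a)) / math.log(a)
        for j in range(b)
    ]
    w = [(1 - h[j]) / (b - sum(h)) for j in range(b)]
    if scaling == "mean":
        base = [
            [rows[i][j] / (sum(rows[k][j] for k in range(a)) / a)
             for j in range(b)]
            for i in range(a)
        ]
    else:
        base = norm
    z = [[w[j] * base[i][j] for j in range(b)] for i in range(a)]
    zp = [max(z[i][j] for i in range(a)) for j in range(b)]
    zm = [min(z[i][j] for i in range(a)) for j in range(b)]
    dp = [math.sqrt(sum((zp[j] - z[i][j]) ** 2 for j in range(b))) for i in range(a)]
    dm = [math.sqrt(sum((zm[j] - z[i][j]) ** 2 for j in range(b))) for i in range(a)]
    ci = [dm[i] / (dp[i] + dm[i]) for i in range(a)]
    return w, dp, dm, ci


def random_positive_matrix(rng):
    a = rng.integers(2, 13)
    b = rng.integers(1, 11)
    x = rng.uniform(0.1, 10.0, size=(a, b))
    # avoid all-constant columns (degenerate weights)
    x[0] += 0.01
    return x


# ---------------------------------------------------------------------------
# Stage-level unit tests
# ---------------------------------------------------------------------------


class TestStages:
    def test_normalize_hand_oracle(self):
        out = normalize_matrix(np.array([[3.0], [4.0]]))
        np.testing.assert_allclose(out.ravel(), [0.6, 0.8])

    def test_normalize_scale_invariance(self):
        col = np.array([[5.0], [5.0]])
        np.testing.assert_allclose(normalize_matrix(col).ravel(),
                                   [1 / math.sqrt(2)] * 2)

    def test_proportion_hand_oracle(self):
        out = proportion_matrix(np.array([[0.6], [0.8]]))
        np.testing.assert_allclose(out.ravel(), [3 / 7, 4 / 7])

    def test_proportion_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = proportion_matrix(normalize_matrix(rng.uniform(0.1, 5, (7, 4))))
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_entropy_uniform_is_one(self):
        h = entropy_values(np.array([[0.5], [0.5]]), a=2)
        np.testing.assert_allclose(h, 1.0)

    def test_entropy_hand_oracle(self):
        p = np.array([[3 / 7], [4 / 7]])
        expected = -((3 / 7) * math.log(3 / 7) + (4 / 7) * math.log(4 / 7)) / math.log(2)
        np.testing.assert_allclose(entropy_values(p, a=2), expected)
        assert abs(expected - 0.9852) < 1e-4

    def test_entropy_rejects_single_object(self):
        with pytest.raises(ValueError):
            entropy_values(np.array([[1.0]]), a=1)

    def test_weights_hand_oracle(self):
        w = entropy_weights(np.array([1.0, 0.5]))
        np.testing.assert_allclose(w.weights, [0.0, 1.0])

    def test_weights_symmetry(self):
        w = entropy_weights(np.array([0.7, 0.7]))
        np.testing.assert_allclose(w.weights, [0.5, 0.5])

    def test_all_entropies_one_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            entropy_weights(np.array([1.0, 1.0]))

    def test_weighting_zeroes_column(self):
        w = entropy_weights(np.array([1.0, 0.5]))
        z = weighted_matrix(np.ones((3, 2)), w)
        np.testing.assert_allclose(z[:, 0], 0.0)
        np.testing.assert_allclose(z[:, 1], 1.0)

    def test_weighting_dimension_mismatch(self):
        w = entropy_weights(np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="columns"):
            weighted_matrix(np.ones((3, 3)), w)

    def test_ideals_single_row(self):
        ideals = ideal_solutions(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(ideals.positive, ideals.negative)

    def test_ideals_dominant_row(self):
        z = np.array([[2.0, 3.0], [1.0, 1.0]])
        ideals = ideal_solutions(z)
        np.testing.assert_allclose(ideals.positive, z[0])
        np.testing.assert_allclose(ideals.negative, z[1])

    def test_separation_at_ideals(self):
        z = np.array([[1.0, 2.0], [0.0, 0.0]])
        ideals = ideal_solutions(z)
        dp, dm = separation_distances(z, ideals)
        assert dp[0] == 0.0 and dm[1] == 0.0

    @pytest.mark.parametrize(
        "dp, dm, expected", [(0.0, 0.4, 1.0), (0.4, 0.0, 0.0), (0.214, 0.119, 0.357)]
    )
    def test_closeness_values(self, dp, dm, expected):
        got = closeness(np.array([dp]), np.array([dm]))[0]
        assert got == pytest.approx(expected, abs=5e-4)

    def test_closeness_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            closeness(np.array([0.0]), np.array([0.0]))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


class TestRunTopsis:
    def test_reproduces_published_quality_table(self, quality_matrix):
        """All ten closeness values and both separation columns match the
        published comprehensive-quality ranking table to its printed
        precision; the rank order is exact."""
        result = m.run_topsis(quality_matrix)
        assert result.ranking() == list(PRINTED_QUALITY_RANKING)
        for i, label in enumerate(result.objects):
            dp, dm, ci, rank = PRINTED_TOPSIS[label]
            assert result.d_plus[i] == pytest.approx(dp, abs=5e-4)
            assert result.d_minus[i] == pytest.approx(dm, abs=5e-4)
            assert result.closeness[i] == pytest.approx(ci, abs=0.01)
            assert result.ranks[i] == rank
        assert not result.tied

    def test_euclidean_variant_same_ranks_close_ci(self, quality_matrix):
        mean = m.run_topsis(quality_matrix, scaling="mean")
        euc = m.run_topsis(quality_matrix, scaling="euclidean")
        assert euc.ranking() == mean.ranking()
        np.testing.assert_allclose(euc.weights.weights, mean.weights.weights,
                                   atol=1e-12)
        np.testing.assert_allclose(euc.closeness, mean.closeness, atol=0.01)

    def test_dominant_row_gets_unit_closeness(self):
        mat = m.DecisionMatrix(("a", "b"), ("i", "j"),
                               np.array([[2.0, 3.0], [1.0, 1.5]]))
        result = m.run_topsis(mat)
        np.testing.assert_allclose(result.closeness, [1.0, 0.0])

    def test_row_permutation_equivariance(self, quality_matrix):
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(quality_matrix.objects))
        permuted = m.DecisionMatrix(
            tuple(quality_matrix.objects[i] for i in perm),
            quality_matrix.indicators,
            quality_matrix.values[perm],
        )
        base = m.run_topsis(quality_matrix)
        shuf = m.run_topsis(permuted)
        np.testing.assert_allclose(shuf.closeness, base.closeness[perm], atol=1e-12)

    @pytest.mark.parametrize("scaling", ["mean", "euclidean"])
    def test_oracle_equivalence_random_matrices(self, scaling):
        """Pipeline closeness agrees with the naive loop oracle to 1e-10
        on 100 random matrices (a <= 12, b <= 10)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            x = random_positive_matrix(rng)
            mat = m.DecisionMatrix(
                tuple(f"o{i}" for i in range(x.shape[0])),
                tuple(f"i{j}" for j in range(x.shape[1])),
                x,
            )
            result = m.run_topsis(mat, scaling=scaling)
            w, dp, dm, ci = naive_topsis(x.tolist(), scaling=scaling)
            np.testing.assert_allclose(result.weights.weights, w, atol=1e-10)
            np.testing.assert_allclose(result.d_plus, dp, atol=1e-10)
            np.testing.assert_allclose(result.d_minus, dm, atol=1e-10)
            np.testing.assert_allclose(result.closeness, ci, atol=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=arrays(float, (5, 4), elements=st.floats(0.1, 50.0)),
        col=st.integers(0, 3),
        factor=st.floats(0.01, 100.0),
    )
    def test_column_scale_invariance(self, x, col, factor):
        """Multiplying any indicator column by a positive constant leaves
        weights and closeness unchanged (unit removal)."""
        x = x + np.linspace(0, 1, 5)[:, None]  # break constant columns
        scaled = x.copy()
        scaled[:, col] *= factor
        objs = tuple("abcde")
        inds = tuple("wxyz")
        base = m.run_topsis(m.DecisionMatrix(objs, inds, x))
        mod = m.run_topsis(m.DecisionMatrix(objs, inds, scaled))
        np.testing.assert_allclose(mod.weights.weights, base.weights.weights,
                                   atol=1e-9)
        np.testing.assert_allclose(mod.closeness, base.closeness, atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=arrays(float, (6, 3), elements=st.floats(0.5, 20.0)))
    def test_weights_sum_to_one(self, x):
        x = x + np.linspace(0, 1, 6)[:, None]
        result = m.run_topsis(
            m.DecisionMatrix(tuple("abcdef"), tuple("pqr"), x)
        )
        assert result.weights.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(result.closeness >= 0) and np.all(result.closeness <= 1)

    def test_benefit_monotonicity_with_fixed_weights(self):
        """With the weighted matrix fixed, raising one entry of object i
        never lowers that object's closeness."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            z = rng.uniform(0.1, 1.0, size=(6, 4))
            i, j = rng.integers(0, 6), rng.integers(0, 4)
            bumped = z.copy()
            bumped[i, j] += rng.uniform(0.01, 0.5)

            def ci_of(mat, row):
                ideals = ideal_solutions(mat)
                dp, dm = separation_distances(mat, ideals)
                return closeness(dp, dm)[row]

            assert ci_of(bumped, i) >= ci_of(z, i) - 1e-12


class TestGoodnessOfFit:
    def test_perfect_positive(self):
        assert m.goodness_of_fit([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert m.goodness_of_fit([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_oracle(self):
        # dx=(-1,0,1), dy=(-4/3,-1/3,5/3): r = 3 / (sqrt(2)*sqrt(42)/3)
        expected = 9 / math.sqrt(84)
        assert m.goodness_of_fit([1, 2, 3], [1, 2, 4]) == pytest.approx(expected)
        assert expected == pytest.approx(0.9820, abs=1e-4)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            m.goodness_of_fit([1, 1, 1], [1, 2, 3])
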