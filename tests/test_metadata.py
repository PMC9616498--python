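import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metamap as mm


class TestCategoricalEpsilon:
    @pytest.mark.parametrize(
        "f_i, f_j, p, c, expected",
        [
            (0, 0, 0.5, 50.0, 0.5),     # same class -> p
            (0, 1, 0.5, 50.0, 0.01),    # different class -> p / c
            (0, 1, 0.3, 1.0, 0.3),      # c = 1: class-blind
            (1, 1, 0.3, 1.0, 0.3),
        ],
    )
    def test_values(self, f_i, f_j, p, c, expected):
        params = mm.CategoricalParams(p=p, c=c)
        assert mm.categorical_epsilon(f_i, f_j, params) == pytest.approx(expected)

    @given(st.integers(0, 5), st.integers(0, 5))
    def test_symmetric_in_classes(self, f_i, f_j):
        params = mm.CategoricalParams(p=0.4, c=7.0)
        assert mm.categorical_epsilon(f_i, f_j, params) == mm.categorical_epsilon(
            f_j, f_i, params
        )

    def test_regimes(self):
        assortative = mm.CategoricalParams(p=0.5, c=10.0)
        assert mm.categorical_epsilon(0, 0, assortative) > mm.categorical_epsilon(
            0, 1, assortative
        )
        disassortative = mm.CategoricalParams(p=0.5, c=0.8)
        assert mm.categorical_epsilon(0, 0, disassortative) < mm.categorical_epsilon(
            0, 1, disassortative
        )
        neutral = mm.CategoricalParams(p=0.5, c=1.0)
        assert mm.categorical_epsilon(0, 0, neutral) == mm.categorical_epsilon(
            0, 1, neutral
        )

    @pytest.mark.parametrize("p, c", [(0.0, 1.0), (1.2, 2.0), (0.5, 0.4)])
    def test_invalid_parameters(self, p, c):
        with pytest.raises(mm.MetadataError):
            mm.CategoricalParams(p=p, c=c)


class TestContinuousEpsilon:
    def test_zero_distance_recovers_p_at_full_strength(self):
        params = mm.ContinuousParams(p=0.37, b=0.5, s=1.0)
        assert mm.continuous_epsilon(1.3, 1.3, params) == pytest.approx(0.37)

    @given(st.floats(0.1, 5.0), st.floats(0.05, 1.0))
    def test_unit_distance_matches_categorical_with_c_exp_inv_b(self, b, p):
        params = mm.ContinuousParams(p=p, b=b, s=1.0)
        cat = mm.CategoricalParams(p=p, c=float(np.exp(1.0 / b)))
        assert mm.continuous_epsilon(0.0, 1.0, params) == pytest.approx(
            mm.categorical_epsilon(0, 1, cat)
        )

    def test_zero_strength_always_encodes(self):
        params = mm.ContinuousParams(p=0.4, b=1.0, s=0.0)
        for d in (0.0, 1.0, 30.0):
            assert mm.continuous_epsilon(0.0, d, params) == 1.0

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_depends_only_on_absolute_difference(self, f_i, f_j):
        params = mm.ContinuousParams(p=0.6, b=0.7, s=0.8)
        e = mm.continuous_epsilon(f_i, f_j, params)
        assert e == mm.continuous_epsilon(f_j, f_i, params)
        assert e == mm.continuous_epsilon(0.0, abs(f_i - f_j), params)
        assert 0.0 <= e <= 1.0

    def test_monotone_nonincreasing_in_distance(self):
        params = mm.ContinuousParams(p=0.5, b=1.0, s=0.9)
        distances = np.linspace(0, 5, 40)
        values = [mm.continuous_epsilon(0.0, d, params) for d in distances]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_factored_form_hits_p_at_zero_distance(self):
        literal = mm.ContinuousParams(p=0.4, b=1.0, s=0.5)
        factored = mm.ContinuousParams(p=0.4, b=1.0, s=0.5, form="factored")
        assert mm.continuous_epsilon(0, 0, literal) == pytest.approx(0.7)  # s*p + 1-s
        assert mm.continuous_epsilon(0, 0, factored) == pytest.approx(0.4)

    def test_nonfinite_metadata_rejected(self):
        params = mm.ContinuousParams(p=0.5, b=1.0, s=1.0)
        with pytest.raises(mm.MetadataError):
            mm.continuous_epsilon(np.nan, 0.0, params)


class TestStandardize:
    def test_two_point(self):
        meta = mm.MetadataMap({"a": 0.0, "b": 2.0}, "continuous")
        z = mm.standardize_metadata(meta)
        assert z.values["a"] == pytest.approx(-1.0)
        assert z.values["b"] == pytest.approx(1.0)

    def test_moments_after_transform(self):
        meta = mm.MetadataMap({"a": 1.0, "b": 2.0, "c": 3.0}, "continuous")
        z = np.array(list(mm.standardize_metadata(meta).values.values()))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_idempotent(self):
        meta = mm.MetadataMap({"a": -1.0, "b": 0.0, "c": 1.0}, "continuous")
        z1 = mm.standardize_metadata(meta)
        z2 = mm.standardize_metadata(z1)
        for v in meta.values:
            assert z2.values[v] == pytest.approx(z1.values[v], abs=1e-12)

    def test_constant_metadata_rejected(self):
        with pytest.raises(mm.MetadataError, match="variance"):
            mm.standardize_metadata(mm.MetadataMap({"a": 1.0, "b": 1.0}, "continuous"))


class TestEpsilonMatrix:
    def graph3(self):
        return mm.Graph.from_edges([("x", "y"), ("y", "z")])

    def test_neutral_all_ones(self):
        meta = mm.MetadataMap({"x": 0, "y": 0, "z": 1}, "categorical")
        eps = mm.epsilon_matrix(self.graph3(), meta, mm.CategoricalParams(p=1.0, c=1.0))
        np.testing.assert_array_equal(eps, np.ones((3, 3)))

    def test_categorical_blocks(self):
        meta = mm.MetadataMap({"x": 0, "y": 0, "z": 1}, "categorical")
        eps = mm.epsilon_matrix(self.graph3(), meta, mm.CategoricalParams(p=0.5, c=50.0))
        expect = np.array(
            [[0.5, 0.5, 0.01], [0.5, 0.5, 0.01], [0.01, 0.01, 0.5]]
        )
        np.testing.assert_allclose(eps, expect)

    def test_continuous_pairwise_decay(self):
        meta = mm.MetadataMap({"x": 0.0, "y": 0.0, "z": 1.0}, "continuous")
        params = mm.ContinuousParams(p=0.5, b=0.5, s=1.0, standardize=False)
        eps = mm.epsilon_matrix(self.graph3(), meta, params)
        assert eps[0, 1] == pytest.approx(0.5)
        assert eps[0, 2] == pytest.approx(0.5 * np.exp(-2.0))

    def test_binary_continuous_equals_categorical(self, random12):
        graph, meta_cat = random12
        f = {v: float(meta_cat.values[v]) for v in graph.node_ids}
        meta_cont = mm.MetadataMap(f, "continuous")
        b = 0.75
        eps_cont = mm.epsilon_matrix(
            graph, meta_cont, mm.ContinuousParams(p=0.6, b=b, s=1.0, standardize=False)
        )
        eps_cat = mm.epsilon_matrix(
            graph, meta_cat, mm.CategoricalParams(p=0.6, c=float(np.exp(1 / b)))
        )
        np.testing.assert_allclose(eps_cont, eps_cat, rtol=1e-12)

    def test_missing_metadata_listed(self):
        meta = mm.MetadataMap({"x": 0, "y": 1}, "categorical")
        with pytest.raises(mm.MetadataError, match="z"):
            mm.epsilon_matrix(self.graph3(), meta, mm.CategoricalParams(p=1.0, c=1.0))

    def test_floor_applied(self):
        meta = mm.MetadataMap({"x": 0.0, "y": 0.0, "z": 500.0}, "continuous")
        params = mm.ContinuousParams(p=1.0, b=0.01, s=1.0, standardize=False)
        eps = mm.epsilon_matrix(self.graph3(), meta, params)
        assert eps.min() == mm.EPSILON_FLOOR
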