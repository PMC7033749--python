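"""Item response function and marginal-likelihood building blocks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from mlmirt import (
    ItemParams,
    LatentStructure,
    ModelSpec,
    Quadrature,
    ResponseData,
    cluster_marginal_likelihood,
    irf_prob,
    total_log_likelihood,
)
from mlmirt.model_core import load_item_params_csv, save_item_params_csv

from conftest import trapezoid_cluster_loglik

finite = st.floats(-5, 5, allow_nan=False)
pos = st.floats(0.1, 4, allow_nan=False)


class TestIrfProb:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1, 1, 0, 0, 0), 0.5),
            ((2, 0, 1, 1, 0.7), expit(1.0)),  # 2*1 + 0*0.7 - 1 = 1
            ((0.8, 0.4, -0.3, 1.2, -0.5), expit(0.8 * 1.2 + 0.4 * -0.5 + 0.3)),
        ],
    )
    def test_direct_evaluation(self, args, expected):
        assert irf_prob(*args) == pytest.approx(expected, abs=1e-12)

    @given(a=pos, b=finite, beta=finite, tw=finite, tb=finite)
    def test_logistic_symmetry_and_bounds(self, a, b, beta, tw, tb):
        p = irf_prob(a, b, beta, tw, tb)
        q = irf_prob(a, b, -beta, -tw, -tb)
        assert 0.0 < p < 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)

    @given(a=pos, b=finite, beta=finite, tb=finite)
    def test_monotone_in_within_ability(self, a, b, beta, tb):
        grid = np.linspace(-3, 3, 13)
        probs = irf_prob(a, b, beta, grid, tb)
        assert np.all(np.diff(probs) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            irf_prob(np.nan, 1, 0, 0, 0)
        with pytest.raises(ValueError):
            irf_prob(1, 1, 0, np.inf, 0)


class TestTypes:
    def test_item_params_shape_mismatch(self):
        with pytest.raises(ValueError):
            ItemParams(np.ones((2, 3)), np.ones(3), np.ones((3, 2)))

    def test_item_params_class_invariant_mask(self, small_params):
        assert small_params.class_invariant_items().tolist() == [False, True, True]

    def test_structure_probability_validation(self):
        with pytest.raises(ValueError):
            LatentStructure([0.6, 0.6], [[0.5, 0.5], [0.5, 0.5]], [0, 1], [1, 1])
        with pytest.raises(ValueError):
            LatentStructure([0.5, 0.5], [[0.7, 0.5], [0.5, 0.5]], [0, 1], [1, 1])
        with pytest.raises(ValueError):  # anchor violated
            LatentStructure([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [0.3, 1], [1, 1])

    def test_model_spec_labels(self):
        assert ModelSpec(2, 3).label == "CB2C3"
        assert ModelSpec.from_label("cb1c2") == ModelSpec(1, 2)
        with pytest.raises(ValueError):
            ModelSpec.from_label("XB2C2")

    def test_response_data_validation(self):
        with pytest.raises(ValueError):  # cluster 2 missing
            ResponseData(np.zeros((2, 2)), [1, 3])
        with pytest.raises(ValueError):  # non-binary entry
            ResponseData(np.full((2, 2), 2), [1, 2])

    def test_item_params_csv_round_trip(self, small_params, tmp_path):
        path = tmp_path / "params.csv"
        save_item_params_csv(small_params, path)
        loaded = load_item_params_csv(path)
        np.testing.assert_allclose(loaded.thresholds, small_params.thresholds)
        np.testing.assert_allclose(loaded.disc_within, small_params.disc_within)
        np.testing.assert_allclose(loaded.disc_between, small_params.disc_between)


def _one_class_structure():
    return LatentStructure([1.0], [[1.0]], [0.0], [1.0], 1.0)


class TestClusterMarginalLikelihood:
    def test_constant_half_probability(self):
        params = ItemParams(np.zeros((1, 1)), np.zeros(1), np.zeros((1, 1)))
        v = cluster_marginal_likelihood(params, _one_class_structure(), [[1]])
        assert v == pytest.approx(np.log(0.5), abs=1e-12)

    def test_zero_discrimination_closed_form(self):
        """With all discriminations 0 the abilities drop out and the marginal
        reduces to a discrete mixture of Bernoulli products."""
        params = ItemParams(
            np.zeros((2, 3)), np.zeros(3), [[-0.4, 0.2, 1.0], [0.5, -0.1, 1.0]]
        )
        structure = LatentStructure(
            [0.6, 0.4], [[0.7, 0.3], [0.2, 0.8]], [0.0, 1.0], [1.0, 1.0]
        )
        Y = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0]])
        p = expit(-params.thresholds)  # (G, I)
        per_person = (p[None] ** Y[:, None, :]) * ((1 - p[None]) ** (1 - Y[:, None, :]))
        lik_pg = per_person.prod(axis=2)  # (n, G)
        expected = 0.0
        for b, pb in enumerate(structure.between_class_probs):
            cluster = np.prod(lik_pg @ structure.within_class_probs[b])
            expected += pb * cluster
        v = cluster_marginal_likelihood(params, structure, Y)
        assert v == pytest.approx(np.log(expected), abs=1e-10)

    def test_matches_dense_grid_oracle(self):
        """2 persons, 3 items, one class at each level: Gauss-Hermite result
        agrees with brute-force trapezoid integration to 1e-6."""
        params = ItemParams(
            [[1.2, 0.7, 1.0]], [0.8, 0.5, 0.6], [[-0.5, 0.3, 1.1]]
        )
        structure = _one_class_structure()
        Y = [[1, 0, 1], [0, 1, 1]]
        ours = cluster_marginal_likelihood(params, structure, Y, Quadrature(31, 31))
        oracle = trapezoid_cluster_loglik(params, structure, Y)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_matches_dense_grid_oracle_mixture(self):
        """Full two-level mixture instance against the same oracle."""
        params = ItemParams(
            [[1.0, 0.8, 1.2], [0.9, 1.1, 0.7]],
            [0.5, 0.4, 0.6],
            [[-0.5, 0.0, 0.7], [0.5, -0.2, 0.7]],
        )
        structure = LatentStructure(
            [0.5, 0.5], [[0.7, 0.3], [0.3, 0.7]], [0.0, 1.0], [1.0, 1.0]
        )
        Y = [[1, 0, 1], [0, 1, 0]]
        ours = cluster_marginal_likelihood(params, structure, Y, Quadrature(31, 31))
        oracle = trapezoid_cluster_loglik(params, structure, Y, n_grid=2001)
        assert ours == pytest.approx(oracle, abs=1e-5)

    def test_quadrature_convergence(self, small_params, cb2c2_structure):
        Y = [[1, 0, 1], [0, 1, 1], [1, 1, 0]]
        v1 = cluster_marginal_likelihood(
            small_params, cb2c2_structure, Y, Quadrature(15, 15)
        )
        v2 = cluster_marginal_likelihood(
            small_params, cb2c2_structure, Y, Quadrature(30, 30)
        )
        assert v1 == pytest.approx(v2, abs=1e-6)

    def test_empty_cluster_rejected(self, small_params, cb2c2_structure):
        with pytest.raises(ValueError):
            cluster_marginal_likelihood(
                small_params, cb2c2_structure, np.empty((0, 3))
            )

    def test_total_invariant_to_cluster_permutation(self, small_params, cb2c2_structure, rng):
        Y = rng.integers(0, 2, size=(12, 3))
        ids = np.repeat([1, 2, 3], 4)
        data = ResponseData(Y, ids)
        # relabel clusters 1<->3 and shuffle rows
        swapped = ids.copy()
        swapped[ids == 1], swapped[ids == 3] = 3, 1
        order = rng.permutation(12)
        data2 = ResponseData(Y[order], swapped[order])
        a = total_log_likelihood(small_params, cb2c2_structure, data)
        b = total_log_likelihood(small_params, cb2c2_structure, data2)
        assert a == pytest.approx(b, abs=1e-10)
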