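"""EM estimation, posteriors, class assignment, and label alignment."""

import numpy as np
import pytest
from scipy.special import expit

from mlmirt import (
    Condition,
    FitOptions,
    FitResult,
    ItemParams,
    LatentStructure,
    ModelSpec,
    ResponseData,
    align_labels,
    assign_classes,
    default_structure,
    fit,
    generate_dataset,
    make_item_params,
    n_free_params,
    posterior_within_probs,
)

CHEAP = dict(n_starts=1, max_iter=60, quad_within=7, quad_between=7, abs_tol=0.05)


@pytest.fixture(scope="module")
def small_fit():
    """One CB2C2 fit on a small dataset, shared across checks."""
    cond = Condition(8, "equal", 50, 20, 15)
    params = make_item_params(8, 50, delta=1.2, seed=4)
    data = generate_dataset(cond, params, default_structure("equal"), seed=21)
    res = fit(ModelSpec(2, 2), data, FitOptions(seed=5, **CHEAP))
    return cond, params, data, res


class TestFit:
    def test_em_loglik_monotone(self, small_fit):
        *_, res = small_fit
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_result_bookkeeping(self, small_fit):
        *_, res = small_fit
        assert res.loglik == res.start_logliks.max()
        np.testing.assert_allclose(res.posterior_within.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.posterior_between.sum(axis=1), 1.0, atol=1e-8)
        assert res.posterior_within.shape == (300, 2)
        assert res.posterior_between.shape == (20, 2)
        assert res.n_params == n_free_params(ModelSpec(2, 2), 8)

    def test_same_seed_reproducible(self, small_fit):
        cond, params, data, res = small_fit
        res2 = fit(ModelSpec(2, 2), data, FitOptions(seed=5, **CHEAP))
        assert res2.loglik == res.loglik
        np.testing.assert_array_equal(res2.params.thresholds, res.params.thresholds)

    def test_degenerate_column_warned_and_bounded(self):
        cond = Condition(5, "equal", 40, 8, 10)
        params = make_item_params(5, 40, seed=2)
        data = generate_dataset(cond, params, default_structure("equal"), seed=3)
        responses = data.responses.copy()
        responses[:, 0] = 1  # perfect item
        data = ResponseData(responses, data.cluster_ids)
        with pytest.warns(UserWarning, match="all-0 or all-1"):
            res = fit(ModelSpec(1, 1), data, FitOptions(seed=1, **CHEAP))
        assert np.all(np.abs(res.params.thresholds[:, 0]) <= 8.0)

    def test_nonconvergence_is_flagged_not_raised(self):
        cond = Condition(5, "equal", 40, 8, 10)
        params = make_item_params(5, 40, seed=2)
        data = generate_dataset(cond, params, default_structure("equal"), seed=3)
        opts = FitOptions(n_starts=1, max_iter=2, quad_within=5, quad_between=5,
                          rel_tol=1e-12, abs_tol=1e-9)
        res = fit(ModelSpec(2, 2), data, opts)
        assert res.converged is False

    def test_nested_models_loglik_ordering(self):
        """CB2C2 can always mimic CB1C2, so its maximized log-likelihood should
        not fall below CB1C2's by more than restart noise."""
        cond = Condition(8, "equal", 50, 30, 20)
        params = make_item_params(8, 50, delta=1.2, seed=6)
        data = generate_dataset(cond, params, default_structure("equal"), seed=31)
        opts = FitOptions(n_starts=2, max_iter=150, quad_within=9, quad_between=11,
                          abs_tol=0.02, seed=7)
        ll_12 = fit(ModelSpec(1, 2), data, opts).loglik
        ll_22 = fit(ModelSpec(2, 2), data, opts).loglik
        assert ll_22 >= ll_12 - 1.0


class TestParamCount:
    @pytest.mark.parametrize(
        "B, G, I",
        [(1, 1, 10), (1, 2, 10), (2, 2, 10), (2, 3, 30), (3, 3, 50)],
    )
    def test_free_parameter_count(self, B, G, I):
        # independent tally: per-class item params, shared between slopes,
        # mixture weights and means net of the fixed anchors
        expected = (
            G * I  # thresholds
            + G * I  # within discriminations
            + I  # between discriminations
            + (B - 1)  # between-class probabilities
            + B * (G - 1)  # conditional mixing rows
            + (B - 1)  # non-anchor between means
        )
        assert n_free_params(ModelSpec(B, G), I) == expected
        assert n_free_params(ModelSpec(B, G), I, estimate_disc_between=False) == expected - I


class TestPosteriorWithinProbs:
    def _data_one_person(self, y):
        return ResponseData(np.array([y]), [1])

    def test_single_class_is_degenerate(self):
        params = ItemParams([[1.0, 1.0]], [0.0, 0.0], [[0.0, 0.5]])
        structure = LatentStructure([1.0], [[1.0]], [0.0], [1.0])
        post = posterior_within_probs(
            params, structure, self._data_one_person([1, 0]), np.zeros((1, 1)), np.zeros(1)
        )
        np.testing.assert_allclose(post, [[1.0]])

    def test_hand_computed_bayes_ratio(self):
        """One person, two items: normalized pi-weighted Bernoulli products."""
        params = ItemParams(
            [[1.0, 0.5], [1.5, 0.8]], [0.3, 0.4], [[-0.2, 0.6], [0.4, -0.5]]
        )
        structure = LatentStructure(
            [0.5, 0.5], [[0.7, 0.3], [0.5, 0.5]], [0.0, 0.8], [1.0, 1.0]
        )
        y = [1, 0]
        tw = np.array([[0.3, -0.1]])
        tb = np.array([0.25])
        pi = structure.marginal_within_probs()
        terms = []
        for g in range(2):
            p1 = expit(params.disc_within[g, 0] * tw[0, g] + params.disc_between[0] * tb[0] - params.thresholds[g, 0])
            p2 = expit(params.disc_within[g, 1] * tw[0, g] + params.disc_between[1] * tb[0] - params.thresholds[g, 1])
            terms.append(pi[g] * p1 * (1 - p2))
        expected = np.array(terms) / np.sum(terms)
        post = posterior_within_probs(params, structure, self._data_one_person(y), tw, tb)
        np.testing.assert_allclose(post[0], expected, atol=1e-10)

    def test_rows_sum_to_one(self, small_fit):
        _, _, data, res = small_fit
        post = posterior_within_probs(
            res.params, res.structure, data, res.eap_within, res.eap_between
        )
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestAssignClasses:
    def test_argmax_and_tie_break(self):
        post = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        np.testing.assert_array_equal(assign_classes(post), [1, 1, 2])

    def test_matches_elementwise_scan(self, rng):
        post = rng.dirichlet(np.ones(3), size=200)
        labels = assign_classes(post)
        for row, lab in zip(post, labels):
            best, best_idx = -1.0, None
            for idx, val in enumerate(row):
                if val > best:
                    best, best_idx = val, idx
            assert lab == best_idx + 1


class TestAlignLabels:
    def _make_fit(self, params, structure, N=4, K=2):
        G = params.n_within_classes
        B = structure.n_between_classes
        post_w = np.tile(np.eye(G)[0], (N, 1)) * 0.8 + 0.2 / G
        post_w /= post_w.sum(axis=1, keepdims=True)
        return FitResult(
            model=ModelSpec(B, G),
            params=params,
            structure=structure,
            loglik=-10.0,
            n_params=n_free_params(ModelSpec(B, G), params.n_items),
            posterior_within=post_w,
            posterior_between=np.full((K, B), 1.0 / B),
            converged=True,
            n_iter=3,
            start_logliks=np.array([-10.0]),
        )

    def test_identity_when_already_aligned(self, small_params, cb2c2_structure):
        ref = small_params
        res = self._make_fit(small_params.copy(), cb2c2_structure.copy())
        aligned, wperm, bperm = align_labels(res, ref)
        assert wperm == (0, 1)
        assert bperm == (0, 1)

    def test_recovers_swapped_classes(self, small_params, cb2c2_structure):
        ref = small_params
        swapped = ItemParams(
            small_params.disc_within[::-1],
            small_params.disc_between,
            small_params.thresholds[::-1],
        )
        res = self._make_fit(swapped, cb2c2_structure.copy())
        aligned, wperm, _ = align_labels(res, ref)
        assert wperm == (1, 0)
        np.testing.assert_allclose(aligned.params.thresholds, ref.thresholds, atol=1e-12)
        # posteriors permuted consistently
        np.testing.assert_allclose(
            aligned.posterior_within, res.posterior_within[:, [1, 0]]
        )

    def test_alignment_never_increases_distance(self, small_params, cb2c2_structure, rng):
        ref = small_params
        for _ in range(10):
            perturbed = ItemParams(
                small_params.disc_within,
                small_params.disc_between,
                small_params.thresholds[rng.permutation(2)] + rng.normal(0, 0.4, (2, 3)),
            )
            res = self._make_fit(perturbed, cb2c2_structure.copy())
            aligned, _, _ = align_labels(res, ref)
            before = np.sum((perturbed.thresholds - ref.thresholds) ** 2)
            after = np.sum((aligned.params.thresholds - ref.thresholds) ** 2)
            assert after <= before + 1e-12

    def test_between_reordering_and_scale_placement(self, small_params):
        """A fit whose between classes come out in descending-mean order is
        reordered, and the mean shift moves into the thresholds exactly."""
        structure = LatentStructure(
            [0.4, 0.6], [[0.6, 0.4], [0.3, 0.7]], [0.0, -1.5], [1.0, 1.0]
        )
        res = self._make_fit(small_params.copy(), structure)
        aligned, _, bperm = align_labels(res, small_params)
        assert bperm == (1, 0)
        assert aligned.structure.between_means[0] < aligned.structure.between_means[1]
        # shift absorbed through the between discriminations
        shift = (res.params.thresholds - aligned.params.thresholds) / res.params.disc_between[None, :]
        np.testing.assert_allclose(shift, shift.flat[0], atol=1e-10)

    def test_dimension_mismatch_rejected(self, small_params, cb2c2_structure):
        res = self._make_fit(small_params.copy(), cb2c2_structure.copy())
        bad_ref = ItemParams(np.ones((2, 5)), np.ones(5), np.zeros((2, 5)))
        with pytest.raises(ValueError):
            align_labels(res, bad_ref)
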