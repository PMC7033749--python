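"""Shared fixtures and independent numeric oracles."""

import numpy as np
import pytest
from hypothesis import settings

from mlmirt import Condition, ItemParams, default_structure

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    """Two classes, three items, one class-variant item, hand-set values."""
    return ItemParams(
        disc_within=[[1.0, 0.8, 1.2], [1.0, 0.8, 1.2]],
        disc_between=[0.5, 0.5, 0.5],
        thresholds=[[-0.5, 0.0, 0.7], [0.5, 0.0, 0.7]],
    )


@pytest.fixture
def cb2c2_structure():
    return default_structure("equal")


@pytest.fixture
def tiny_condition():
    return Condition(n_items=5, mixing="equal", pct_variant=40, n_clusters=10, cluster_size=5)


# ---------------------------------------------------------------------------
# independent oracles (brute-force paths, deliberately unlike the package code)
# ---------------------------------------------------------------------------


def trapezoid_cluster_loglik(params, structure, Y, n_grid=3001, span=8.0):
    """Dense-grid trapezoid evaluation of the cluster marginal log-likelihood.

    Direct nested numeric integration of
    sum_b P(b) int phi_b prod_j [ sum_g pi_{g|b} int phi_w prod_i p^y (1-p)^(1-y) ] .
    """
    from scipy.stats import norm

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, I = Y.shape
    G = params.n_within_classes
    B = structure.n_between_classes
    tw = np.linspace(-span, span, n_grid)
    tb = np.linspace(-span, span, n_grid)
    total = 0.0
    for b in range(B):
        dens_b = norm.pdf(tb, structure.between_means[b], np.sqrt(structure.between_var))
        per_person = np.zeros((n, n_grid))
        for j in range(n):
            mix = np.zeros(n_grid)
            for g in range(G):
                dens_w = norm.pdf(tw, 0.0, np.sqrt(structure.within_var[g]))
                logp = np.zeros((n_grid, n_grid))  # (tw, tb)
                for i in range(I):
                    lam = (
                        params.disc_within[g, i] * tw[:, None]
                        + params.disc_between[i] * tb[None, :]
                        - params.thresholds[g, i]
                    )
                    p = 1.0 / (1.0 + np.exp(-lam))
                    logp += Y[j, i] * np.log(p) + (1 - Y[j, i]) * np.log1p(-p)
                inner = np.trapezoid(dens_w[:, None] * np.exp(logp), tw, axis=0)
                mix += structure.within_class_probs[b, g] * inner
            per_person[j] = mix
        cluster_lik = np.prod(per_person, axis=0)
        total += structure.between_class_probs[b] * np.trapezoid(dens_b * cluster_lik, tb)
    return float(np.log(total))


def twopl_marginal_loglik(disc, thresh, Y, n_nodes=21):
    """Single-level 2PL marginal log-likelihood by Gauss-Hermite quadrature
    (probabilists' rule applied directly; no shared code with the estimator)."""
    from numpy.polynomial.hermite_e import hermegauss

    z, w = hermegauss(n_nodes)
    w = w / w.sum()
    lam = disc[None, :, None] * z[None, None, :] - thresh[None, :, None]  # (1, I, Q)
    logp = -np.log1p(np.exp(-lam))
    log1mp = -np.log1p(np.exp(lam))
    Y = np.asarray(Y, dtype=float)
    ll_nodes = np.einsum("ni,oiq->nq", Y, logp) + np.einsum(
        "ni,oiq->nq", 1 - Y, log1mp
    )
    m = ll_nodes.max(axis=1, keepdims=True)
    return float(np.sum(m[:, 0] + np.log(np.exp(ll_nodes - m) @ w)))


def fit_twopl_oracle(Y, n_nodes=21):
    """Independent standard 2PL marginal-ML fit: direct L-BFGS maximization."""
    from scipy.optimize import minimize

    Y = np.asarray(Y, dtype=float)
    I = Y.shape[1]
    pbar = np.clip(Y.mean(axis=0), 0.02, 0.98)
    x0 = np.concatenate([np.ones(I), -np.log(pbar / (1 - pbar))])

    def negll(x):
        return -twopl_marginal_loglik(x[:I], x[I:], Y, n_nodes)

    res = minimize(negll, x0, method="L-BFGS-B", options={"maxiter": 500})
    return -res.fun, res.x[:I], res.x[I:]
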