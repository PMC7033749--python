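"""Marginal maximum-likelihood estimation of CBmCn multilevel mixture 2PL models.

The estimator is a plain EM algorithm on a discretized version of the model:
both continuous abilities are replaced by fixed Gauss-Hermite grids (the
between-level grid is shared across between classes, with the class means
folded into reweighted discrete node probabilities).  Because the grid never
moves with the parameters, the discretized marginal likelihood is a fixed
function of the parameters and the observed-data log-likelihood is
non-decreasing across EM iterations — each M-step piece (weighted logistic
Newton updates for item parameters with step halving, closed-form mixing
updates, one-dimensional concave Newton for the between-class means) increases
the EM Q-function.

Identification during estimation: sigma_g^2 = tau^2 = 1 fixed (scale absorbed
by the discriminations), the first between-class mean fixed at 0 (location
absorbed by the thresholds), discriminations free.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .model_core import (
    ItemParams,
    LatentStructure,
    ModelSpec,
    ResponseData,
    gauss_hermite_normal,
)

logger = logging.getLogger("mlmirt.estimator")

__all__ = [
    "FitOptions",
    "FitResult",
    "fit",
    "n_free_params",
    "posterior_within_probs",
    "assign_classes",
    "align_labels",
]

_PROB_FLOOR = 1e-4  # mixing floor preventing class collapse
_THRESHOLD_BOUND = 8.0  # logit bound for degenerate (all-0/all-1) items


@dataclass
class FitOptions:
    """EM control settings.

    n_starts random restarts are run; the first start is derived from a
    one-class 2PL base fit with class-specific threshold perturbations, the
    remainder are fully random.  ``estimate_disc_between=False`` pins the
    between-level discriminations at 0, collapsing the model to a single-level
    mixture 2PL (useful for degenerate-model checks).
    """

    max_iter: int = 500
    rel_tol: float = 1e-5
    abs_tol: float = 0.01
    n_starts: int = 5
    quad_within: int = 15
    quad_between: int = 21
    seed: int = 0
    estimate_disc_between: bool = True

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.quad_within < 3 or self.quad_between < 3:
            raise ValueError("quadrature node counts must be >= 3")


@dataclass
class FitResult:
    """Fitted model with posteriors and convergence diagnostics."""

    model: ModelSpec
    params: ItemParams
    structure: LatentStructure
    loglik: float
    n_params: int
    posterior_within: np.ndarray  # (N, G)
    posterior_between: np.ndarray  # (K, B)
    converged: bool
    n_iter: int
    start_logliks: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    eap_within: Optional[np.ndarray] = None  # (N, G) class-specific EAP theta_w
    eap_between: Optional[np.ndarray] = None  # (K,) EAP theta_b

    def to_json(self, path) -> None:
        payload = {
            "model": self.model.label,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "start_logliks": np.asarray(self.start_logliks).tolist(),
            "disc_within": self.params.disc_within.tolist(),
            "disc_between": self.params.disc_between.tolist(),
            "thresholds": self.params.thresholds.tolist(),
            "between_class_probs": self.structure.between_class_probs.tolist(),
            "within_class_probs": self.structure.within_class_probs.tolist(),
            "between_means": self.structure.between_means.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def save_posteriors_csv(self, path) -> None:
        import pandas as pd

        G = self.posterior_within.shape[1]
        df = pd.DataFrame(
            self.posterior_within, columns=[f"P_class_{g + 1}" for g in range(G)]
        )
        df.insert(0, "person", np.arange(1, len(df) + 1))
        df.to_csv(path, index=False)


def n_free_params(spec: ModelSpec, n_items: int, estimate_disc_between: bool = True) -> int:
    """Free-parameter count d after identification constraints.

    G*I thresholds + G*I within discriminations + I between discriminations
    (when estimated) + (B-1) between-class probabilities + B*(G-1) conditional
    mixing proportions + (B-1) between means; variances are fixed at 1.
    """
    B, G, I = spec.n_between_classes, spec.n_within_classes, n_items
    d = 2 * G * I + (B - 1) + B * (G - 1) + (B - 1)
    if estimate_disc_between:
        d += I
    return d


# ---------------------------------------------------------------------------
# EM engine
# ---------------------------------------------------------------------------


class _EMEngine:
    """Precomputed data layout plus E/M-step kernels for one dataset/model."""

    def __init__(self, spec: ModelSpec, data: ResponseData, options: FitOptions):
        self.spec = spec
        self.options = options
        self.B, self.G = spec.n_between_classes, spec.n_within_classes
        self.I = data.n_items
        self.N = data.n_persons
        self.K = data.n_clusters
        self.Y = data.responses.astype(float)
        # cluster segment layout (sorted once; reduceat needs contiguous runs)
        self.order = np.argsort(data.cluster_ids, kind="stable")
        sorted_ids = data.cluster_ids[self.order]
        self.seg_starts = np.searchsorted(sorted_ids, np.arange(1, self.K + 1))
        self.cluster_of = data.cluster_ids - 1  # (N,) 0-based

        zw, ww = gauss_hermite_normal(options.quad_within)
        self.xw = zw  # sigma_g = 1 fixed during estimation
        self.log_ww = np.log(ww)
        # Fixed between grid (never moves with the parameters, so the
        # discretized likelihood is a fixed function of them and EM ascent is
        # exact).  One between class: plain Gauss-Hermite for N(0, tau^2).
        # Several classes: a uniform grid wide enough for shifted class means,
        # with the class means entering through normalized discrete
        # probabilities p_t(b) ~ exp(base_logw_t - (x_t - mu_b)^2 / (2 tau^2)).
        tau = 1.0  # tau^2 fixed at 1 during estimation
        if self.B == 1:
            zb, wb = gauss_hermite_normal(options.quad_between)
            self.xb = tau * zb
            self.base_logw = np.log(wb) + 0.5 * self.xb**2 / tau**2
        else:
            half = 3.5 * tau + 2.0
            self.xb = np.linspace(-half, half, options.quad_between)
            self.base_logw = np.zeros_like(self.xb)
        self.S, self.T = zw.size, self.xb.size

        self.degenerate_items = np.flatnonzero(
            (self.Y.sum(axis=0) == 0) | (self.Y.sum(axis=0) == self.N)
        )
        if self.degenerate_items.size:
            warnings.warn(
                f"items {list(self.degenerate_items + 1)} have all-0 or all-1 "
                f"responses; their thresholds are bounded at +/-{_THRESHOLD_BOUND}",
                stacklevel=2,
            )

        # design matrix for the per-item weighted logistic M-step, cells (g,s,t)
        G, S, T = self.G, self.S, self.T
        ncols = 2 * G + (1 if options.estimate_disc_between else 0)
        X = np.zeros((G * S * T, ncols))
        cell_g = np.repeat(np.arange(G), S * T)
        cell_s = np.tile(np.repeat(np.arange(S), T), G)
        cell_t = np.tile(np.arange(T), G * S)
        for g in range(G):
            X[cell_g == g, g] = self.xw[cell_s[cell_g == g]]
        col = G
        if options.estimate_disc_between:
            X[:, col] = self.xb[cell_t]
            col += 1
        for g in range(G):
            X[cell_g == g, col + g] = -1.0
        self.X = X
        self._beta_col0 = col

    # -- parameter packing for the logistic update -------------------------
    def _pack_item(self, params: ItemParams, i: int) -> np.ndarray:
        parts = [params.disc_within[:, i]]
        if self.options.estimate_disc_between:
            parts.append(params.disc_between[i : i + 1])
        parts.append(params.thresholds[:, i])
        return np.concatenate(parts)

    def _unpack_item(self, theta: np.ndarray, params: ItemParams, i: int) -> None:
        G = self.G
        params.disc_within[:, i] = theta[:G]
        if self.options.estimate_disc_between:
            params.disc_between[i] = theta[G]
        params.thresholds[:, i] = theta[self._beta_col0 :]

    def _log_pb(self, structure: LatentStructure) -> np.ndarray:
        """(B, T) log probabilities of the discrete between-node distribution."""
        mu = structure.between_means
        tau2 = structure.between_var
        log_u = (
            self.base_logw[None, :]
            - 0.5 * (self.xb[None, :] - mu[:, None]) ** 2 / tau2
        )
        return log_u - logsumexp(log_u, axis=1, keepdims=True)

    # -- E-step ------------------------------------------------------------
    def e_step(self, params: ItemParams, structure: LatentStructure) -> dict:
        N, G, B, S, T, I = self.N, self.G, self.B, self.S, self.T, self.I
        PL = np.empty((N, G, T))
        Wpost = np.empty((G, N, S, T))  # P(within node s | g, t, person)
        for g in range(G):
            lam = (
                params.disc_within[g][:, None, None] * self.xw[None, :, None]
                + params.disc_between[:, None, None] * self.xb[None, None, :]
                - params.thresholds[g][:, None, None]
            ).reshape(I, S * T)
            base = log_expit(-lam).sum(axis=0)
            A = (self.Y @ lam + base).reshape(N, S, T)
            A += self.log_ww[None, :, None]
            amax = A.max(axis=1, keepdims=True)
            E = np.exp(A - amax)
            Es = E.sum(axis=1, keepdims=True)
            PL[:, g, :] = (amax + np.log(Es))[:, 0, :]
            Wpost[g] = E / Es
        with np.errstate(divide="ignore"):
            log_pi = np.log(structure.within_class_probs)  # (B, G)
            log_prior_b = np.log(structure.between_class_probs)
        # mix within classes per between class: (N, B, T)
        PB = logsumexp(PL[:, None, :, :] + log_pi[None, :, :, None], axis=2)
        # per-cluster sums and marginal likelihood
        SC = np.add.reduceat(PB[self.order], self.seg_starts, axis=0)  # (K, B, T)
        log_pb = self._log_pb(structure)
        node_post = SC + log_pb[None] + log_prior_b[:, None][None]  # (K, B, T)
        LK = logsumexp(node_post.reshape(self.K, -1), axis=1)
        R = np.exp(node_post - LK[:, None, None])
        return {
            "Wpost": Wpost,
            "PL": PL,
            "PB": PB,
            "R": R,
            "loglik": float(LK.sum()),
            "log_pi": log_pi,
        }

    def person_posteriors(self, est: dict, structure: LatentStructure):
        """Posterior P(g, node_t | person) -> E1 (N, G, T), and N_gb (B, G)."""
        Rj = est["R"][self.cluster_of]  # (N, B, T)
        PL, PB = est["PL"], est["PB"]
        pi = structure.within_class_probs
        E1 = np.zeros((self.N, self.G, self.T))
        N_gb = np.zeros((self.B, self.G))
        for b in range(self.B):
            # exp(PL - PB_b) <= 1/pi_{g|b}: stable
            term = Rj[:, b, None, :] * pi[b][None, :, None] * np.exp(
                PL - PB[:, b, None, :]
            )
            E1 += term
            N_gb[b] = term.sum(axis=(0, 2))
        return E1, N_gb

    # -- M-step pieces ------------------------------------------------------
    def m_step_items(
        self, params: ItemParams, est: dict, E1: np.ndarray
    ) -> ItemParams:
        """Weighted logistic Newton updates (step-halved; guarantees Q ascent)."""
        N, G, S, T = self.N, self.G, self.S, self.T
        n_cell = np.zeros((G, S, T))
        k_cell = np.zeros((self.I, G, S, T))
        num_eap = np.zeros((self.N, G))
        Wpost = est["Wpost"]
        for g in range(G):
            omega = E1[:, g, None, :] * Wpost[g]  # (N, S, T)
            n_cell[g] = omega.sum(axis=0)
            k_cell[:, g] = (self.Y.T @ omega.reshape(N, S * T)).reshape(
                self.I, S, T
            )
            num_eap[:, g] = omega.sum(axis=2) @ self.xw
        self._eap_within_num = num_eap  # cached for the caller
        n_flat = n_cell.ravel()
        new = params.copy()
        for i in range(self.I):
            theta = self._pack_item(new, i)
            k_flat = k_cell[i].ravel()
            theta = _newton_logistic(self.X, k_flat, n_flat, theta)
            if i in self.degenerate_items:
                theta[self._beta_col0 :] = np.clip(
                    theta[self._beta_col0 :], -_THRESHOLD_BOUND, _THRESHOLD_BOUND
                )
            self._unpack_item(theta, new, i)
        return new

    def m_step_structure(
        self, structure: LatentStructure, est: dict, N_gb: np.ndarray
    ) -> LatentStructure:
        R = est["R"]
        new = structure.copy()
        # between-class probabilities
        pb = R.sum(axis=(0, 2)) / self.K
        if np.any(pb < _PROB_FLOOR):
            logger.info("between-class probability floored (possible class collapse)")
            pb = np.maximum(pb, _PROB_FLOOR)
        new.between_class_probs = pb / pb.sum()
        # conditional mixing proportions
        pi = N_gb / np.maximum(N_gb.sum(axis=1, keepdims=True), 1e-300)
        if np.any(pi < _PROB_FLOOR):
            logger.info("within-class mixing floored (possible class collapse)")
            pi = np.maximum(pi, _PROB_FLOOR)
        new.within_class_probs = pi / pi.sum(axis=1, keepdims=True)
        # between means (first anchored at 0): 1-D concave Newton per class
        mu = new.between_means.copy()
        for b in range(1, self.B):
            r_t = R[:, b, :].sum(axis=0)
            if r_t.sum() < 1e-12:
                continue
            mu[b] = self._update_mu(mu[b], r_t, structure.between_var)
        new.between_means = mu
        return new

    def _update_mu(self, mu0: float, r_t: np.ndarray, tau2: float) -> float:
        x = self.xb
        R_b = r_t.sum()
        xbar = r_t @ x / R_b
        c = self.base_logw - 0.5 * x**2 / tau2

        def obj(mu):
            lp = c + x * mu / tau2
            lp -= logsumexp(lp)
            return r_t @ lp, lp

        mu = mu0
        f, lp = obj(mu)
        for _ in range(50):
            p = np.exp(lp)
            ex = p @ x
            var = p @ (x - ex) ** 2
            if var < 1e-12:
                break
            step = tau2 * (xbar - ex) / var
            if abs(step) < 1e-10:
                break
            for _ in range(30):  # halving: obj is concave, keep the ascent exact
                f_new, lp_new = obj(mu + step)
                if f_new >= f - 1e-12:
                    break
                step *= 0.5
            mu, f, lp = mu + step, f_new, lp_new
        lo, hi = x.min(), x.max()
        return float(np.clip(mu, lo, hi))

    # -- posteriors / EAP summaries -----------------------------------------
    def summaries(self, est: dict, structure: LatentStructure):
        E1, _ = self.person_posteriors(est, structure)
        post_w = E1.sum(axis=2)
        post_w /= post_w.sum(axis=1, keepdims=True)
        post_b = est["R"].sum(axis=2)
        post_b /= post_b.sum(axis=1, keepdims=True)
        eap_b = est["R"].sum(axis=1) @ self.xb
        # class-specific within EAP from the cached within-node posteriors
        num = np.zeros((self.N, self.G))
        for g in range(self.G):
            omega = E1[:, g, None, :] * est["Wpost"][g]
            num[:, g] = omega.sum(axis=2) @ self.xw
        denom = np.maximum(E1.sum(axis=2), 1e-300)
        eap_w = num / denom
        return post_w, post_b, eap_w, eap_b


def _newton_logistic(
    X: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    theta0: np.ndarray,
    max_iter: int = 10,
    tol: float = 1e-9,
) -> np.ndarray:
    """Maximize the weighted Bernoulli log-likelihood sum k*log p + (n-k)*log(1-p),
    p = sigmoid(X theta), by damped Newton steps (concave objective)."""

    def q(th):
        eta = X @ th
        return k @ log_expit(eta) + (n - k) @ log_expit(-eta)

    theta = theta0.copy()
    f = q(theta)
    for _ in range(max_iter):
        eta = X @ theta
        mu = expit(eta)
        grad = X.T @ (k - n * mu)
        if np.max(np.abs(grad)) < tol:
            break
        w = n * mu * (1 - mu)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        for _ in range(30):
            f_new = q(theta + step)
            if f_new >= f - 1e-12:
                break
            step *= 0.5
        if f_new < f - 1e-12:
            break
        theta, f = theta + step, f_new
    return theta


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------


def _moment_init(spec: ModelSpec, data: ResponseData, est_ab: bool) -> tuple:
    """Crude observed-proportion start for a base one-class fit."""
    pbar = np.clip(data.responses.mean(axis=0), 0.02, 0.98)
    beta = -np.log(pbar / (1 - pbar))
    I = data.n_items
    G, B = spec.n_within_classes, spec.n_between_classes
    params = ItemParams(
        np.ones((G, I)), np.full(I, 0.5 if est_ab else 0.0), np.tile(beta, (G, 1))
    )
    structure = _uniform_structure(B, G)
    return params, structure

def _uniform_structure(B: int, G: int, means: Optional[np.ndarray] = None) -> LatentStructure:
    if means is None:
        means = np.linspace(0.0, 1.0, B) if B > 1 else np.zeros(1)
        means[0] = 0.0
    return LatentStructure(
        np.full(B, 1.0 / B), np.full((B, G), 1.0 / G), means, np.ones(G), 1.0
    )


def _init_from_base(
    spec: ModelSpec, base: "FitResult", rng: np.random.Generator, est_ab: bool
) -> tuple:
    B, G = spec.n_between_classes, spec.n_within_classes
    I = base.params.n_items
    beta0 = base.params.thresholds[0]
    aw0 = base.params.disc_within[0]
    thresholds = np.vstack([beta0 + rng.normal(0, 0.5, I) for _ in range(G)])
    disc_w = np.tile(np.abs(aw0), (G, 1))
    disc_b = base.params.disc_between.copy() if est_ab else np.zeros(I)
    if est_ab and np.allclose(disc_b, 0):
        disc_b[:] = 0.5
    params = ItemParams(disc_w, disc_b, thresholds)
    pi = rng.dirichlet(np.full(G, 20.0), size=B) if G > 1 else np.ones((B, 1))
    pb = rng.dirichlet(np.full(B, 20.0)) if B > 1 else np.ones(1)
    means = np.linspace(0.0, 1.0, B) if B > 1 else np.zeros(1)
    means[0] = 0.0
    structure = LatentStructure(pb, pi, means, np.ones(G), 1.0)
    return params, structure


def _init_random(
    spec: ModelSpec, I: int, rng: np.random.Generator, est_ab: bool
) -> tuple:
    B, G = spec.n_between_classes, spec.n_within_classes
    params = ItemParams(
        rng.uniform(0.5, 1.5, (G, I)),
        rng.uniform(0.2, 1.0, I) if est_ab else np.zeros(I),
        rng.normal(0, 1, (G, I)),
    )
    pi = rng.dirichlet(np.full(G, 5.0), size=B) if G > 1 else np.ones((B, 1))
    pb = rng.dirichlet(np.full(B, 5.0)) if B > 1 else np.ones(1)
    means = np.zeros(B)
    if B > 1:
        means[1:] = np.sort(np.abs(rng.normal(0.8, 0.5, B - 1)))
    structure = LatentStructure(pb, pi, means, np.ones(G), 1.0)
    return params, structure


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def fit(
    spec: ModelSpec,
    data: ResponseData,
    options: Optional[FitOptions] = None,
    _base_fit: bool = False,
) -> FitResult:
    """Fit a CBmCn model by EM; returns the best of ``n_starts`` restarts.

    Never raises on non-convergence: the result carries ``converged=False``
    when the relative log-likelihood change has not dropped below ``rel_tol``
    within ``max_iter`` iterations.
    """
    if options is None:
        options = FitOptions()
    if data.n_persons == 0:
        raise ValueError("data is empty")
    engine = _EMEngine(spec, data, options)
    rng = np.random.default_rng(options.seed)
    est_ab = options.estimate_disc_between

    starts: list[tuple] = []
    if _base_fit or (spec.n_between_classes == 1 and spec.n_within_classes == 1):
        starts.append(_moment_init(spec, data, est_ab))
    else:
        base_opts = replace(
            options,
            n_starts=1,
            max_iter=min(100, options.max_iter),
            rel_tol=max(1e-4, options.rel_tol),
            abs_tol=max(0.05, options.abs_tol),
            quad_between=7,  # B=1 base fit: plain Gauss-Hermite suffices
        )
        base = fit(ModelSpec(1, 1), data, base_opts, _base_fit=True)
        starts.append(_init_from_base(spec, base, rng, est_ab))
    while len(starts) < options.n_starts:
        starts.append(_init_random(spec, data.n_items, rng, est_ab))

    best = None
    start_logliks = []
    for s_idx, (params, structure) in enumerate(starts):
        result = _run_em(engine, spec, params, structure, options)
        start_logliks.append(result["loglik"])
        logger.debug(
            "start %d: loglik=%.4f converged=%s iters=%d",
            s_idx,
            result["loglik"],
            result["converged"],
            result["n_iter"],
        )
        if best is None or result["loglik"] > best["loglik"]:
            best = result
    logger.info(
        "%s fit: loglik=%.4f (best of %d starts), converged=%s",
        spec.label,
        best["loglik"],
        len(starts),
        best["converged"],
    )

    post_w, post_b, eap_w, eap_b = engine.summaries(best["est"], best["structure"])
    return FitResult(
        model=spec,
        params=best["params"],
        structure=best["structure"],
        loglik=best["loglik"],
        n_params=n_free_params(spec, data.n_items, est_ab),
        posterior_within=post_w,
        posterior_between=post_b,
        converged=best["converged"],
        n_iter=best["n_iter"],
        start_logliks=np.array(start_logliks),
        loglik_trace=best["trace"],
        eap_within=eap_w,
        eap_between=eap_b,
    )


def _run_em(
    engine: _EMEngine,
    spec: ModelSpec,
    params: ItemParams,
    structure: LatentStructure,
    options: FitOptions,
) -> dict:
    trace = []
    converged = False
    est = engine.e_step(params, structure)
    trace.append(est["loglik"])
    n_iter = 0
    for n_iter in range(1, options.max_iter + 1):
        E1, N_gb = engine.person_posteriors(est, structure)
        params = engine.m_step_items(params, est, E1)
        structure = engine.m_step_structure(structure, est, N_gb)
        est = engine.e_step(params, structure)
        trace.append(est["loglik"])
        change = abs(trace[-1] - trace[-2])
        rel = change / (abs(trace[-2]) + 1e-12)
        if rel < options.rel_tol and change < options.abs_tol:
            converged = True
            break
    return {
        "params": params,
        "structure": structure,
        "loglik": trace[-1],
        "converged": converged,
        "n_iter": n_iter,
        "trace": np.array(trace),
        "est": est,
    }


# ---------------------------------------------------------------------------
# posteriors, assignment, label alignment
# ---------------------------------------------------------------------------


def posterior_within_probs(
    params: ItemParams,
    structure: LatentStructure,
    data: ResponseData,
    theta_within: np.ndarray,
    theta_between: np.ndarray,
) -> np.ndarray:
    """Plug-in posterior class probabilities P_jkg at predicted ability scores.

    P_jkg is proportional to pi_g * prod_i P^y (1-P)^(1-y), evaluated at the
    person's predicted within score for class g (``theta_within``, shape (N, G)
    or (N,)) and the cluster's predicted between score (``theta_between``,
    shape (K,)); rows are normalized to sum to 1 over the G classes.
    """
    if not (
        np.all(np.isfinite(params.disc_within))
        and np.all(np.isfinite(params.thresholds))
    ):
        raise ValueError("fitted parameters must be finite")
    N, I = data.n_persons, data.n_items
    G = params.n_within_classes
    theta_within = np.asarray(theta_within, dtype=float)
    if theta_within.ndim == 1:
        theta_within = np.tile(theta_within[:, None], (1, G))
    if theta_within.shape != (N, G):
        raise ValueError("theta_within must have shape (N, G) or (N,)")
    theta_between = np.asarray(theta_between, dtype=float).ravel()
    if theta_between.shape != (data.n_clusters,):
        raise ValueError("theta_between must have one entry per cluster")
    tb = theta_between[data.cluster_ids - 1]  # (N,)
    Y = data.responses.astype(float)
    pi_g = structure.marginal_within_probs()
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_g)
    log_post = np.empty((N, G))
    for g in range(G):
        lam = (
            params.disc_within[g][None, :] * theta_within[:, g, None]
            + params.disc_between[None, :] * tb[:, None]
            - params.thresholds[g][None, :]
        )  # (N, I)
        log_post[:, g] = log_pi[g] + np.sum(
            Y * lam + log_expit(-lam), axis=1
        )
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


def assign_classes(posteriors: np.ndarray) -> np.ndarray:
    """Highest-posterior class per row, 1-based; exact ties go to the lowest
    class index (argmax takes the first maximum)."""
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=float))
    return np.argmax(posteriors, axis=1) + 1


def align_labels(
    fit_result: FitResult, reference_params: ItemParams
) -> tuple[FitResult, tuple[int, ...], tuple[int, ...]]:
    """Correct label switching against reference (generating) parameters.

    Within-level classes: exhaustive search over the G! permutations for the
    one minimizing the summed squared threshold difference to the reference.
    Between-level classes: reordered by ascending between mean.  The estimates
    are then placed onto the reference (generating) scale: the between-ability
    location is only anchored up to an arbitrary convention, so the shift c
    minimizing sum_(g,i) (beta_hat - a_b c - beta_ref)^2 is absorbed into the
    thresholds through the between discriminations and subtracted from the
    between means — an exact reparameterization that leaves the likelihood
    untouched.  Posteriors and mixing proportions are permuted consistently.
    Returns (relabeled fit, within perm, between perm), permutations given as
    tuples of old indices in new order.
    """
    G = fit_result.params.n_within_classes
    if reference_params.n_within_classes != G:
        raise ValueError("reference has a different number of within classes")
    if reference_params.n_items != fit_result.params.n_items:
        raise ValueError("reference has a different number of items")

    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(G)):
        cost = float(
            np.sum(
                (fit_result.params.thresholds[list(perm)] - reference_params.thresholds)
                ** 2
            )
        )
        if cost < best_cost - 1e-15:
            best_perm, best_cost = perm, cost
    wperm = list(best_perm)

    structure = fit_result.structure
    bperm = [int(i) for i in np.argsort(structure.between_means, kind="stable")]

    params = ItemParams(
        fit_result.params.disc_within[wperm],
        fit_result.params.disc_between.copy(),
        fit_result.params.thresholds[wperm],
    )
    # scale placement: theta_b -> theta_b - c, compensated in the thresholds
    a_b = params.disc_between
    denom = G * float(a_b @ a_b)
    if denom > 1e-12:
        shift = float(
            np.sum(a_b[None, :] * (params.thresholds - reference_params.thresholds))
            / denom
        )
    else:
        shift = 0.0
    means = structure.between_means[bperm] - shift
    params.thresholds = params.thresholds - a_b[None, :] * shift
    new_structure = LatentStructure(
        structure.between_class_probs[bperm],
        structure.within_class_probs[np.ix_(bperm, wperm)],
        means,
        structure.within_var[wperm],
        structure.between_var,
        anchored=False,
    )
    aligned = FitResult(
        model=fit_result.model,
        params=params,
        structure=new_structure,
        loglik=fit_result.loglik,
        n_params=fit_result.n_params,
        posterior_within=fit_result.posterior_within[:, wperm],
        posterior_between=fit_result.posterior_between[:, bperm],
        converged=fit_result.converged,
        n_iter=fit_result.n_iter,
        start_logliks=fit_result.start_logliks,
        loglik_trace=fit_result.loglik_trace,
        eap_within=None
        if fit_result.eap_within is None
        else fit_result.eap_within[:, wperm],
        eap_between=None
        if fit_result.eap_between is None
        else fit_result.eap_between - shift,
    )
    return aligned, tuple(wperm), tuple(bperm)
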