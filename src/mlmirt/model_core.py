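"""Core data types and likelihood building blocks for multilevel mixture 2PL models.

The model: person j in cluster k belongs to a within-level latent class g
(categorical, G classes) and carries a within-level ability theta_w ~ N(0, sigma_g^2);
cluster k belongs to a between-level latent class b (B classes) and carries a
between-level ability theta_b ~ N(mu_b, tau^2).  The probability of a correct
response to item i is

    logit P(Y = 1) = a_w[g, i] * theta_w + a_b[i] * theta_b - beta[g, i],

so each within-level class has its own discriminations and thresholds while the
between-level discriminations are shared across classes.  Between-level classes
shift the between ability mean and the conditional within-class mixing
proportions pi_{g|b}; the first between mean is anchored at 0 for identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit, log_expit, logsumexp

__all__ = [
    "ItemParams",
    "LatentStructure",
    "ModelSpec",
    "ResponseData",
    "Quadrature",
    "irf_prob",
    "cluster_marginal_likelihood",
    "total_log_likelihood",
    "gauss_hermite_normal",
]


def gauss_hermite_normal(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite rule adapted to a standard normal density.

    Returns nodes ``x`` and weights ``w`` with ``sum(w) == 1`` such that
    ``sum(w * f(x))`` approximates ``E[f(Z)]`` for ``Z ~ N(0, 1)``.
    """
    if n < 1:
        raise ValueError("need at least one quadrature node")
    x, w = hermegauss(n)
    return x, w / w.sum()


@dataclass
class Quadrature:
    """Quadrature settings for the two nested normal integrals.

    ``between_mode`` selects how between-level nodes are placed: ``"centered"``
    puts Gauss-Hermite nodes at mu_b + tau * z per between class (most accurate
    for one-off likelihood evaluations); ``"fixed"`` uses a single shared grid
    drawn from N(0, between_scale^2) and folds the class means into reweighted
    discrete probabilities (used by the EM estimator so the discretized
    likelihood stays a fixed function of the parameters).
    """

    n_within: int = 15
    n_between: int = 7
    between_mode: str = "centered"
    between_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_within < 3 or self.n_between < 3:
            raise ValueError("quadrature node counts must be >= 3")
        if self.between_mode not in ("centered", "fixed"):
            raise ValueError(f"unknown between_mode: {self.between_mode!r}")


@dataclass
class ItemParams:
    """Item parameters for G within-level classes over I items.

    disc_within : (G, I) within-level discriminations a_w[g, i]
    disc_between : (I,) between-level discriminations a_b[i] (class-invariant)
    thresholds : (G, I) class-specific item locations beta[g, i], logit units
    """

    disc_within: np.ndarray
    disc_between: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.disc_within = np.atleast_2d(np.asarray(self.disc_within, dtype=float))
        self.disc_between = np.asarray(self.disc_between, dtype=float).ravel()
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if self.disc_within.shape != self.thresholds.shape:
            raise ValueError(
                "disc_within and thresholds must share shape (G, I); got "
                f"{self.disc_within.shape} vs {self.thresholds.shape}"
            )
        if self.disc_between.shape != (self.n_items,):
            raise ValueError("disc_between must have one entry per item")
        for name in ("disc_within", "disc_between", "thresholds"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_items(self) -> int:
        return self.disc_within.shape[1]

    @property
    def n_within_classes(self) -> int:
        return self.disc_within.shape[0]

    def class_invariant_items(self, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of items whose thresholds agree across all classes."""
        ref = self.thresholds[0]
        return np.all(np.abs(self.thresholds - ref) <= atol, axis=0)

    def copy(self) -> "ItemParams":
        return ItemParams(
            self.disc_within.copy(), self.disc_between.copy(), self.thresholds.copy()
        )


@dataclass
class LatentStructure:
    """Latent-class structure at both levels.

    between_class_probs : (B,) marginal probabilities P(b)
    within_class_probs : (B, G) conditional mixing proportions pi_{g|b}
    between_means : (B,) between-ability means, first anchored at 0
    within_var : (G,) within-ability variances sigma_g^2
    between_var : scalar between-ability variance tau^2
    anchored : when True (the default), the first between mean must be the
        0 identification anchor; label-aligned results re-expressed on a
        reference scale set this to False
    """

    between_class_probs: np.ndarray
    within_class_probs: np.ndarray
    between_means: np.ndarray
    within_var: np.ndarray
    between_var: float = 1.0
    anchored: bool = True

    def __post_init__(self) -> None:
        self.between_class_probs = np.asarray(self.between_class_probs, dtype=float).ravel()
        self.within_class_probs = np.atleast_2d(
            np.asarray(self.within_class_probs, dtype=float)
        )
        self.between_means = np.asarray(self.between_means, dtype=float).ravel()
        self.within_var = np.asarray(self.within_var, dtype=float).ravel()
        self.between_var = float(self.between_var)
        B, G = self.within_class_probs.shape
        if self.between_class_probs.shape != (B,):
            raise ValueError("between_class_probs length must match within_class_probs rows")
        if self.between_means.shape != (B,):
            raise ValueError("between_means length must equal number of between classes")
        if self.within_var.shape != (G,):
            raise ValueError("within_var length must equal number of within classes")
        if not np.isclose(self.between_class_probs.sum(), 1.0, atol=1e-8):
            raise ValueError("between_class_probs must sum to 1")
        if not np.allclose(self.within_class_probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each row of within_class_probs must sum to 1")
        if np.any(self.within_var <= 0) or self.between_var <= 0:
            raise ValueError("variances must be positive")
        if self.anchored and self.between_means[0] != 0.0:
            raise ValueError("between_means[0] is the identification anchor and must be 0")

    @property
    def n_between_classes(self) -> int:
        return self.between_class_probs.shape[0]

    @property
    def n_within_classes(self) -> int:
        return self.within_class_probs.shape[1]

    def marginal_within_probs(self) -> np.ndarray:
        """Marginal within-class mixing proportions pi_g = sum_b P(b) pi_{g|b}."""
        return self.between_class_probs @ self.within_class_probs

    def copy(self) -> "LatentStructure":
        return LatentStructure(
            self.between_class_probs.copy(),
            self.within_class_probs.copy(),
            self.between_means.copy(),
            self.within_var.copy(),
            self.between_var,
            self.anchored,
        )


@dataclass(frozen=True)
class ModelSpec:
    """A CBmCn candidate model: m between-level and n within-level classes."""

    n_between_classes: int
    n_within_classes: int

    def __post_init__(self) -> None:
        if self.n_between_classes < 1 or self.n_within_classes < 1:
            raise ValueError("class counts must be >= 1")

    @property
    def label(self) -> str:
        return f"CB{self.n_between_classes}C{self.n_within_classes}"

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        m = label.strip().upper()
        if not (m.startswith("CB") and "C" in m[2:]):
            raise ValueError(f"not a CBmCn label: {label!r}")
        b_part, g_part = m[2:].split("C", 1)
        return cls(int(b_part), int(g_part))


@dataclass
class ResponseData:
    """Binary response matrix with cluster structure and optional true memberships.

    responses : (N, I) 0/1 matrix
    cluster_ids : (N,) integer cluster labels in 1..K, each appearing at least once
    true_within_class : optional (N,) labels in 1..G
    true_between_class : optional (K,) labels in 1..B (cluster order = sorted ids)
    """

    responses: np.ndarray
    cluster_ids: np.ndarray
    true_within_class: Optional[np.ndarray] = None
    true_between_class: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int).ravel()
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D (N, I) matrix")
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must contain only 0/1 (no missing data)")
        self.responses = self.responses.astype(np.int8)
        if self.cluster_ids.shape != (self.responses.shape[0],):
            raise ValueError("cluster_ids must have one entry per person")
        uniq = np.unique(self.cluster_ids)
        if uniq[0] < 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("cluster ids must cover 1..K with every cluster non-empty")
        if self.true_within_class is not None:
            self.true_within_class = np.asarray(self.true_within_class, dtype=int).ravel()
            if self.true_within_class.shape != (self.n_persons,):
                raise ValueError("true_within_class must have one entry per person")
        if self.true_between_class is not None:
            self.true_between_class = np.asarray(self.true_between_class, dtype=int).ravel()
            if self.true_between_class.shape != (self.n_clusters,):
                raise ValueError("true_between_class must have one entry per cluster")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids.max())

    def cluster_slices(self) -> list[np.ndarray]:
        """Row indices per cluster, ordered by cluster id 1..K."""
        order = np.argsort(self.cluster_ids, kind="stable")
        bounds = np.searchsorted(self.cluster_ids[order], np.arange(1, self.n_clusters + 2))
        return [order[bounds[k] : bounds[k + 1]] for k in range(self.n_clusters)]


def irf_prob(disc_w, disc_b, threshold, theta_w, theta_b):
    """Item response probability of the multilevel mixture 2PL.

    Inverse logit of ``disc_w * theta_w + disc_b * theta_b - threshold``.
    Accepts scalars or broadcastable arrays; all inputs must be finite.
    """
    args = [np.asarray(a, dtype=float) for a in (disc_w, disc_b, threshold, theta_w, theta_b)]
    for a in args:
        if not np.all(np.isfinite(a)):
            raise ValueError("irf_prob requires finite inputs")
    disc_w, disc_b, threshold, theta_w, theta_b = args
    return expit(disc_w * theta_w + disc_b * theta_b - threshold)


def _between_grid(
    structure: LatentStructure, quad: Quadrature
) -> tuple[np.ndarray, np.ndarray]:
    """Between-level node values and log discrete probabilities.

    Returns ``theta_b`` of shape (B, T) and ``log_pb`` of shape (B, T) where
    ``log_pb[b, t]`` is the log probability that a cluster in between class b
    sits at node t (weights sum to 1 within each class).
    """
    z, w = gauss_hermite_normal(quad.n_between)
    tau = np.sqrt(structure.between_var)
    mu = structure.between_means
    if quad.between_mode == "centered":
        theta = mu[:, None] + tau * z[None, :]
        log_pb = np.broadcast_to(np.log(w), theta.shape).copy()
        return theta, log_pb
    # fixed shared grid: nodes from N(0, s^2), class means folded into the
    # (normalized) discrete probabilities -- the grid does not move with mu.
    s = quad.between_scale
    if s is None:
        s = max(1.5 * tau, tau + float(np.max(np.abs(mu))))
    x = s * z
    # log w_t + log phi(x; mu_b, tau^2) - log phi(x; 0, s^2), then normalize per b
    log_u = (
        np.log(w)[None, :]
        - 0.5 * (x[None, :] - mu[:, None]) ** 2 / structure.between_var
        + 0.5 * x[None, :] ** 2 / s**2
        + np.log(s / tau)
    )
    log_pb = log_u - logsumexp(log_u, axis=1, keepdims=True)
    theta = np.broadcast_to(x, (mu.size, x.size)).copy()
    return theta, log_pb


def _person_loglik_given_nodes(
    params: ItemParams,
    structure: LatentStructure,
    Y: np.ndarray,
    theta_b_flat: np.ndarray,
    quad: Quadrature,
) -> np.ndarray:
    """log P(Y_j | g, theta_w integrated out, theta_b = node) -> (n, G, C).

    ``theta_b_flat`` is the flattened (B*T,) vector of between-node values; the
    within ability is integrated over its class-specific Gauss-Hermite rule.
    The log-odds of a response equal the linear predictor, so the Bernoulli
    log-likelihood reduces to ``Y @ lam - sum softplus(lam)``.
    """
    G, I = params.n_within_classes, params.n_items
    zw, ww = gauss_hermite_normal(quad.n_within)
    C = theta_b_flat.size
    S = zw.size
    out = np.empty((Y.shape[0], G, C))
    log_ww = np.log(ww)
    for g in range(G):
        xw = np.sqrt(structure.within_var[g]) * zw  # (S,)
        lam = (
            params.disc_within[g][:, None, None] * xw[None, :, None]
            + params.disc_between[:, None, None] * theta_b_flat[None, None, :]
            - params.thresholds[g][:, None, None]
        )  # (I, S, C)
        lam2 = lam.reshape(I, S * C)
        # log sigma(-lam) = log_expit(-lam) = -softplus(lam)
        base = log_expit(-lam2).sum(axis=0)  # (S*C,)
        ll = Y @ lam2 + base  # (n, S*C)
        ll = ll.reshape(Y.shape[0], S, C) + log_ww[None, :, None]
        out[:, g, :] = logsumexp(ll, axis=1)
    return out


def cluster_marginal_likelihood(
    params: ItemParams,
    structure: LatentStructure,
    cluster_responses: np.ndarray,
    quad: Quadrature | None = None,
) -> float:
    """Log marginal likelihood contribution of one cluster.

    Evaluates, by fixed-node Gauss-Hermite quadrature at both levels,

        log sum_b P(b) int phi(t_b; mu_b, tau^2)
            prod_j [ sum_g pi_{g|b} int phi(t_w; 0, sigma_g^2)
                     prod_i P^y (1-P)^(1-y) dt_w ] dt_b .

    All accumulation is done in log space (log-sum-exp), so long response
    patterns do not underflow.
    """
    if quad is None:
        quad = Quadrature()
    Y = np.atleast_2d(np.asarray(cluster_responses))
    if Y.size == 0:
        raise ValueError("cluster must contain at least one person")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("cluster responses must be 0/1")
    if Y.shape[1] != params.n_items:
        raise ValueError("response columns must match the number of items")
    Y = Y.astype(float)
    B = structure.n_between_classes
    theta_b, log_pb = _between_grid(structure, quad)  # (B, T) each
    pl = _person_loglik_given_nodes(params, structure, Y, theta_b.ravel(), quad)
    pl = pl.reshape(Y.shape[0], structure.n_within_classes, B, theta_b.shape[1])
    with np.errstate(divide="ignore"):
        log_pi = np.log(structure.within_class_probs)  # (B, G)
        log_prior_b = np.log(structure.between_class_probs)
    # mix over within classes, sum persons, integrate between nodes, mix b
    mixed = logsumexp(pl + log_pi.T[None, :, :, None], axis=1)  # (n, B, T)
    per_node = mixed.sum(axis=0) + log_pb  # (B, T)
    return float(logsumexp(logsumexp(per_node, axis=1) + log_prior_b))


def total_log_likelihood(
    params: ItemParams,
    structure: LatentStructure,
    data: ResponseData,
    quad: Quadrature | None = None,
) -> float:
    """Sum of independent cluster contributions over the whole dataset."""
    return float(
        sum(
            cluster_marginal_likelihood(params, structure, data.responses[idx], quad)
            for idx in data.cluster_slices()
        )
    )


def load_item_params_csv(path, n_within_classes: Optional[int] = None) -> ItemParams:
    """Read an item-parameter table with columns item, class, disc_within,
    disc_between, threshold (one row per item x within-class)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"item", "class", "disc_within", "disc_between", "threshold"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"item parameter CSV missing columns: {sorted(missing)}")
    items = np.sort(df["item"].unique())
    classes = np.sort(df["class"].unique())
    if n_within_classes is not None and len(classes) != n_within_classes:
        raise ValueError("unexpected number of within classes in CSV")
    I, G = len(items), len(classes)
    disc_w = np.empty((G, I))
    thr = np.empty((G, I))
    disc_b = np.empty(I)
    for gi, g in enumerate(classes):
        sub = df[df["class"] == g].set_index("item").loc[items]
        disc_w[gi] = sub["disc_within"].to_numpy()
        thr[gi] = sub["threshold"].to_numpy()
        disc_b = sub["disc_between"].to_numpy()
    return ItemParams(disc_w, disc_b, thr)


def save_item_params_csv(params: ItemParams, path) -> None:
    """Write the item-parameter table in the layout read by ``load_item_params_csv``."""
    import pandas as pd

    rows = []
    for g in range(params.n_within_classes):
        for i in range(params.n_items):
            rows.append(
                {
                    "item": i + 1,
                    "class": g + 1,
                    "disc_within": params.disc_within[g, i],
                    "disc_between": params.disc_between[i],
                    "threshold": params.thresholds[g, i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
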