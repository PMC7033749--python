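"""Generators for the factorial simulation design.

The study world: clustered dichotomous responses from a two-between-class,
two-within-class multilevel mixture 2PL (CB2C2).  The factorial grid crosses
test length (10/30/50 items), mixing proportions (equal 0.5/0.5 vs unequal
0.75/0.25), percentage of class-variant items (30/60/90%), number of clusters
(50/100) and cluster size (10/50) — 72 conditions.  Condition labels follow
the study's convention: ``E5010`` = equal mixing, 50 clusters of size 10;
``NE10050`` = unequal mixing, 100 clusters of size 50.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import ItemParams, LatentStructure, ResponseData, irf_prob

__all__ = [
    "Condition",
    "make_design_grid",
    "make_item_params",
    "default_structure",
    "generate_dataset",
    "write_response_csv",
    "read_response_csv",
    "write_condition_grid_csv",
    "DESIGN_FACTORS",
]

# the full factorial design of the simulation study
DESIGN_FACTORS: dict[str, tuple] = {
    "n_items": (10, 30, 50),
    "mixing": ("equal", "unequal"),
    "pct_variant": (30, 60, 90),
    "n_clusters": (50, 100),
    "cluster_size": (10, 50),
}

MIXING_PROPORTIONS = {"equal": (0.5, 0.5), "unequal": (0.75, 0.25)}


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design."""

    n_items: int
    mixing: str
    pct_variant: int
    n_clusters: int
    cluster_size: int

    def __post_init__(self) -> None:
        if self.mixing not in MIXING_PROPORTIONS:
            raise ValueError("mixing must be 'equal' or 'unequal'")
        if not 0 <= self.pct_variant <= 100:
            raise ValueError("pct_variant must be a percentage")
        for f in ("n_items", "n_clusters", "cluster_size"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")

    @property
    def label(self) -> str:
        prefix = "E" if self.mixing == "equal" else "NE"
        return f"{prefix}{self.n_clusters}{self.cluster_size}"

    @property
    def mixing_proportions(self) -> tuple[float, float]:
        return MIXING_PROPORTIONS[self.mixing]

    @property
    def n_persons(self) -> int:
        return self.n_clusters * self.cluster_size


def make_design_grid(
    factors: Optional[dict[str, Sequence]] = None, strict: bool = True
) -> list[Condition]:
    """Cartesian product of the design factors in a fixed, documented order.

    Order: items x mixing x pct_variant x n_clusters x cluster_size, each
    factor in the order given.  The defaults reproduce the 72-cell study grid.
    With ``strict`` on, factor values outside the study's domains are rejected.
    """
    f = dict(DESIGN_FACTORS)
    if factors:
        unknown = set(factors) - set(f)
        if unknown:
            raise ValueError(f"unknown design factors: {sorted(unknown)}")
        f.update({k: tuple(v) for k, v in factors.items()})
    for name, vals in f.items():
        if len(vals) == 0:
            raise ValueError(f"factor {name} is empty")
        if strict:
            bad = set(vals) - set(DESIGN_FACTORS[name])
            if bad:
                raise ValueError(
                    f"factor {name} values {sorted(bad)} outside the design domain "
                    f"{DESIGN_FACTORS[name]} (pass strict=False to allow)"
                )
    return [
        Condition(i, m, p, k, s)
        for i, m, p, k, s in itertools.product(
            f["n_items"], f["mixing"], f["pct_variant"], f["n_clusters"], f["cluster_size"]
        )
    ]


def make_item_params(
    n_items: int,
    pct_variant: float,
    delta: float = 1.0,
    base_thresholds: Optional[np.ndarray] = None,
    base_disc: Optional[np.ndarray] = None,
    disc_between: Optional[np.ndarray] = None,
    seed: int = 0,
) -> ItemParams:
    """Generating item parameters for a two-within-class design.

    Exactly ``round(n_items * pct_variant / 100)`` items are class-variant:
    their class-2 threshold differs from class 1 by ``delta`` with alternating
    sign (+, -, +, ...), mimicking balanced uniform DIF; the remaining items
    are class-invariant.  If ``base_thresholds`` is omitted the class-1
    thresholds are drawn from N(0, 1) under ``seed``.  Discriminations default
    to 1 at both levels.
    """
    if not 0 <= pct_variant <= 100:
        raise ValueError("pct_variant must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    if base_thresholds is None:
        base_thresholds = rng.normal(0.0, 1.0, size=n_items)
    base_thresholds = np.asarray(base_thresholds, dtype=float).ravel()
    if base_thresholds.shape != (n_items,):
        raise ValueError("base_thresholds must have length n_items")
    if base_disc is None:
        base_disc = np.ones(n_items)
    base_disc = np.asarray(base_disc, dtype=float).ravel()
    if base_disc.shape != (n_items,):
        raise ValueError("base_disc must have length n_items")
    if disc_between is None:
        disc_between = np.ones(n_items)
    disc_between = np.asarray(disc_between, dtype=float).ravel()
    if disc_between.shape != (n_items,):
        raise ValueError("disc_between must have length n_items")

    n_variant = int(round(n_items * pct_variant / 100.0))
    shifts = np.zeros(n_items)
    signs = np.where(np.arange(n_variant) % 2 == 0, 1.0, -1.0)
    shifts[:n_variant] = signs * delta
    thresholds = np.vstack([base_thresholds, base_thresholds + shifts])
    disc_within = np.vstack([base_disc, base_disc])
    return ItemParams(disc_within, disc_between, thresholds)


def default_structure(
    mixing: str = "equal",
    between_means: Sequence[float] = (0.0, 1.0),
    mixing_tilt: float = 0.2,
    within_var: Sequence[float] = (1.0, 1.0),
    between_var: float = 1.0,
    between_probs: Sequence[float] = (0.5, 0.5),
) -> LatentStructure:
    """CB2C2 generating structure whose marginal within-class proportions equal
    the condition's mixing proportions.

    With equal between-class probabilities, conditional mixing rows
    (pi_1 + tilt, pi_2 - tilt) and (pi_1 - tilt, pi_2 + tilt) average back to
    the marginal (pi_1, pi_2); the tilt gives the between classes distinct
    within-class composition on top of their ability-mean shift.
    """
    pi = np.asarray(MIXING_PROPORTIONS[mixing], dtype=float)
    tilt = float(mixing_tilt)
    p_b = np.asarray(between_probs, dtype=float)
    if not np.allclose(p_b, 0.5):
        raise ValueError("default_structure assumes equal between-class probabilities")
    rows = np.vstack([pi + np.array([tilt, -tilt]), pi - np.array([tilt, -tilt])])
    if np.any(rows < 0) or np.any(rows > 1):
        raise ValueError("mixing_tilt too large for the requested mixing proportions")
    return LatentStructure(
        between_class_probs=p_b,
        within_class_probs=rows,
        between_means=np.asarray(between_means, dtype=float),
        within_var=np.asarray(within_var, dtype=float),
        between_var=between_var,
    )


def generate_dataset(
    condition: Condition,
    params: ItemParams,
    structure: LatentStructure,
    seed: int = 0,
) -> ResponseData:
    """Simulate one clustered response dataset under the generating model.

    For each cluster: draw its between class b and ability theta_k ~
    N(mu_b, tau^2); for each member: draw the within class g ~ pi_{g|b} and
    ability theta ~ N(0, sigma_g^2), then Bernoulli responses through the item
    response function.  True memberships are recorded.  Identical seeds give
    bit-identical datasets.
    """
    if params.n_within_classes != structure.n_within_classes:
        raise ValueError("params and structure disagree on the number of within classes")
    rng = np.random.default_rng(seed)
    K, n, I = condition.n_clusters, condition.cluster_size, condition.n_items
    if params.n_items != I:
        raise ValueError("params built for a different number of items")
    B, G = structure.n_between_classes, structure.n_within_classes
    tau = np.sqrt(structure.between_var)

    b_k = rng.choice(B, size=K, p=structure.between_class_probs)
    theta_k = rng.normal(structure.between_means[b_k], tau)

    cluster_ids = np.repeat(np.arange(1, K + 1), n)
    b_person = np.repeat(b_k, n)
    # per-person within class from the conditional mixing of its cluster's b
    u = rng.random(K * n)
    cum = np.cumsum(structure.within_class_probs, axis=1)
    g_person = (u[:, None] > cum[b_person]).sum(axis=1)
    sigma = np.sqrt(structure.within_var)
    theta_w = rng.normal(0.0, sigma[g_person])

    p = irf_prob(
        params.disc_within[g_person],  # (N, I)
        params.disc_between[None, :],
        params.thresholds[g_person],
        theta_w[:, None],
        np.repeat(theta_k, n)[:, None],
    )
    responses = (rng.random((K * n, I)) < p).astype(np.int8)
    return ResponseData(
        responses=responses,
        cluster_ids=cluster_ids,
        true_within_class=g_person + 1,
        true_between_class=b_k + 1,
    )


def write_response_csv(data: ResponseData, path) -> None:
    """Wide-format response table: cluster_id, person_id, item_1..item_I, and
    (when recorded) true_within_class / true_between_class columns."""
    I = data.n_items
    df = pd.DataFrame(data.responses, columns=[f"item_{i + 1}" for i in range(I)])
    df.insert(0, "person_id", np.arange(1, data.n_persons + 1))
    df.insert(0, "cluster_id", data.cluster_ids)
    if data.true_within_class is not None:
        df["true_within_class"] = data.true_within_class
    if data.true_between_class is not None:
        df["true_between_class"] = data.true_between_class[data.cluster_ids - 1]
    df.to_csv(path, index=False)


def read_response_csv(path) -> ResponseData:
    """Read a table written by ``write_response_csv`` (or any file in that layout)."""
    df = pd.read_csv(path)
    item_cols = [c for c in df.columns if c.startswith("item_")]
    item_cols.sort(key=lambda c: int(c.split("_")[1]))
    responses = df[item_cols].to_numpy()
    cluster_ids = df["cluster_id"].to_numpy()
    tw = df["true_within_class"].to_numpy() if "true_within_class" in df else None
    tb = None
    if "true_between_class" in df:
        per_cluster = df.groupby("cluster_id")["true_between_class"].first()
        tb = per_cluster.sort_index().to_numpy()
    return ResponseData(responses, cluster_ids, tw, tb)


def write_condition_grid_csv(conditions: Sequence[Condition], path) -> None:
    """One row per condition: label plus the five factor columns."""
    pd.DataFrame(
        [
            {
                "label": c.label,
                "n_items": c.n_items,
                "mixing": c.mixing,
                "pct_variant": c.pct_variant,
                "n_clusters": c.n_clusters,
                "cluster_size": c.cluster_size,
            }
            for c in conditions
        ]
    ).to_csv(path, index=False)
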