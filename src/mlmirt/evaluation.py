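"""Outcome measures of the simulation study: threshold recovery and
classification accuracy.

RMSE follows the study's definition per parameter across replications,
sqrt( sum_r (estimate_r - truth)^2 / R ), computed per (class, item) cell on
label-aligned estimates, then averaged — over classes to give per-item values
and over items to give the condition's mean RMSE.  Classification accuracy is
the percentage of examinees whose estimated within-level class (after label
alignment) equals the generating one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RecoveryResult", "AccuracyResult", "threshold_rmse", "classification_accuracy"]


@dataclass
class RecoveryResult:
    per_item_rmse: np.ndarray  # (I,) averaged over classes
    mean_rmse: float
    n_replications: int


@dataclass
class AccuracyResult:
    n_correct: int
    n_total: int

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.n_correct / self.n_total


def threshold_rmse(
    estimates: np.ndarray, truth: np.ndarray, variant_only_mask: np.ndarray | None = None
) -> RecoveryResult:
    """RMSE of aligned threshold estimates against the generating values.

    estimates : (R, G, I) stacked label-aligned estimates over R replications
    truth : (G, I) generating thresholds
    variant_only_mask : optional (I,) boolean restriction of the item set
        (e.g. class-variant items only); the default averages over all items.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.ndim != 3 or estimates.shape[1:] != truth.shape:
        raise ValueError("estimates must have shape (R, G, I) matching truth (G, I)")
    R = estimates.shape[0]
    if R == 0:
        raise ValueError("need at least one replication")
    per_cell = np.sqrt(np.mean((estimates - truth[None]) ** 2, axis=0))  # (G, I)
    per_item = per_cell.mean(axis=0)
    if variant_only_mask is not None:
        variant_only_mask = np.asarray(variant_only_mask, dtype=bool)
        per_item_used = per_item[variant_only_mask]
    else:
        per_item_used = per_item
    return RecoveryResult(
        per_item_rmse=per_item,
        mean_rmse=float(per_item_used.mean()),
        n_replications=R,
    )


def classification_accuracy(
    true_classes: np.ndarray, estimated_classes: np.ndarray
) -> AccuracyResult:
    """Exact agreement between generating and (aligned) estimated memberships."""
    true_classes = np.asarray(true_classes).ravel()
    estimated_classes = np.asarray(estimated_classes).ravel()
    if true_classes.shape != estimated_classes.shape:
        raise ValueError("membership vectors must have equal length")
    n = true_classes.size
    if n == 0:
        raise ValueError("empty membership vectors")
    return AccuracyResult(int(np.sum(true_classes == estimated_classes)), n)
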