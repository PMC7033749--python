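"""Information criteria and correct-detection bookkeeping for model selection.

Four penalized -2 log L indices are compared, smaller is better:

    AIC   = -2 log L + 2 d
    BIC   = -2 log L + d ln(N)
    CAIC  = -2 log L + d (ln(N) + 1)
    SABIC = -2 log L + d ln((N + 2) / 24)

where N is the number of examinees (level-1 units, never the cluster count)
and d the number of free parameters.  Natural logarithms throughout.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

__all__ = [
    "CRITERIA",
    "information_criteria",
    "ic_table",
    "select_model",
    "correct_detection_count",
]

CRITERIA = ("AIC", "BIC", "CAIC", "SABIC")


def information_criteria(loglik: float, d: int, n_examinees: int) -> dict[str, float]:
    """The four indices for one fitted model; N counts examinees (level-1 units)."""
    if d < 1:
        raise ValueError("parameter count d must be >= 1")
    if n_examinees < 1:
        raise ValueError("N must be >= 1")
    m2ll = -2.0 * float(loglik)
    return {
        "AIC": m2ll + 2.0 * d,
        "BIC": m2ll + d * math.log(n_examinees),
        "CAIC": m2ll + d * (math.log(n_examinees) + 1.0),
        "SABIC": m2ll + d * math.log((n_examinees + 2) / 24.0),
    }


def ic_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build the candidate-model comparison table.

    Each input row needs ``model`` (a CBmCn label), ``loglik``, ``d`` and ``N``;
    the four criteria are computed and appended.  Rows are indexed by label.
    """
    records = []
    for row in rows:
        ics = information_criteria(row["loglik"], row["d"], row["N"])
        records.append(
            {"model": row["model"], "loglik": row["loglik"], "d": row["d"], "N": row["N"], **ics}
        )
    if not records:
        raise ValueError("ic_table needs at least one row")
    return pd.DataFrame(records).set_index("model")


def select_model(table: pd.DataFrame, criterion: str) -> str:
    """Label of the row minimizing the chosen criterion.

    Ties are broken toward the smaller parameter count d, then toward the
    lexicographically smaller label.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    if len(table) == 0:
        raise ValueError("empty model table")
    ranked = table.assign(_label=table.index.astype(str)).sort_values(
        [criterion, "d", "_label"], kind="stable"
    )
    return str(ranked.index[0])


def correct_detection_count(
    selections: Sequence[str], true_label: str
) -> tuple[int, float]:
    """Count (and proportion) of selections matching the generating model."""
    selections = list(selections)
    if not selections:
        raise ValueError("no selections to tally")
    n = sum(1 for s in selections if s == true_label)
    return n, n / len(selections)
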