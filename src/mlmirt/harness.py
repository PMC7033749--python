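"""Study orchestration: simulate -> fit candidates -> select -> evaluate.

`run_condition` executes every replication of one design cell; `run_study`
sweeps the full factorial grid and assembles the study tables: mean threshold
RMSE per condition, classification accuracy rates, and correct-detection
counts per information criterion.

Seed policy: the dataset seed for replication r of condition c is
``base_seed + 10_000 * c + r``; generating base thresholds are drawn once per
test length (seed ``base_seed + n_items``) so every condition that shares a
test length shares its generating item set, the way a single calibrated item
pool would anchor all conditions.  The whole study output is a pure function
of the configuration.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimator import (
    FitOptions,
    FitResult,
    align_labels,
    assign_classes,
    fit,
    posterior_within_probs,
)
from .evaluation import classification_accuracy, threshold_rmse
from .model_core import ModelSpec
from .model_selection import CRITERIA, correct_detection_count, ic_table, select_model
from .synthetic_data import (
    Condition,
    default_structure,
    generate_dataset,
    make_design_grid,
    make_item_params,
)

__all__ = ["StudyConfig", "ConditionResult", "run_condition", "run_study"]


@dataclass
class StudyConfig:
    """Configuration of a (possibly scaled-down) run of the simulation study.

    ``n_replications`` defaults to a desk-scale 20; the full-scale design uses
    100.  Generator settings (``delta``, ``between_means``, ``mixing_tilt``)
    default to the package's stated generating world.
    """

    factors: Optional[dict] = None
    n_replications: int = 20
    candidate_models: tuple[str, ...] = ("CB1C2", "CB2C2", "CB2C3", "CB3C3")
    true_model: str = "CB2C2"
    base_seed: int = 1
    delta: float = 1.0
    between_means: tuple[float, ...] = (0.0, 1.0)
    mixing_tilt: float = 0.2
    fit_options: FitOptions = field(default_factory=FitOptions)
    out_dir: Optional[str] = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.fit_options, dict):
            self.fit_options = FitOptions(**self.fit_options)
        self.candidate_models = tuple(self.candidate_models)
        self.between_means = tuple(self.between_means)
        if self.true_model not in self.candidate_models:
            raise ValueError("candidate_models must contain true_model")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    def conditions(self) -> list[Condition]:
        # custom factor sets may leave the study's factorial domains
        return make_design_grid(self.factors, strict=self.factors is None)

    @property
    def expected_run_count(self) -> int:
        return len(self.conditions()) * self.n_replications * len(self.candidate_models)

    # -- config file round trip (JSON or YAML) -----------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidate_models"] = list(self.candidate_models)
        d["between_means"] = list(self.between_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "fit_options" in d and isinstance(d["fit_options"], dict):
            d["fit_options"] = FitOptions(**d["fit_options"])
        for key in ("candidate_models", "between_means"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)


@dataclass
class ConditionResult:
    """Aggregates for one design cell plus per-replication detail."""

    condition: Condition
    n_replications: int
    n_converged: int  # replications where every candidate fit converged
    mean_rmse: float
    accuracy_percent: float
    detection_counts: dict  # {criterion: {label: count, "nonconverged": count}}
    replications: pd.DataFrame  # one row per (replication, model)

    def summary_row(self) -> dict:
        row = {
            "label": self.condition.label,
            "n_items": self.condition.n_items,
            "mixing": self.condition.mixing,
            "pct_variant": self.condition.pct_variant,
            "n_clusters": self.condition.n_clusters,
            "cluster_size": self.condition.cluster_size,
            "n_replications": self.n_replications,
            "n_converged": self.n_converged,
            "mean_rmse": self.mean_rmse,
            "accuracy_percent": self.accuracy_percent,
        }
        for crit in CRITERIA:
            row[f"detect_{crit}"] = self.detection_counts[crit].get(
                self.condition_true_label, 0
            )
        return row

    @property
    def condition_true_label(self) -> str:
        return self.replications.attrs.get("true_model", "CB2C2")


def _generating_inputs(config: StudyConfig, condition: Condition):
    params = make_item_params(
        condition.n_items,
        condition.pct_variant,
        delta=config.delta,
        seed=config.base_seed + condition.n_items,
    )
    structure = default_structure(
        condition.mixing,
        between_means=config.between_means,
        mixing_tilt=config.mixing_tilt,
    )
    return params, structure


def run_condition(
    config: StudyConfig, condition: Condition, condition_index: Optional[int] = None
) -> ConditionResult:
    """All replications of one condition: generate, fit candidates, select,
    align the true-model fit and score recovery plus classification accuracy."""
    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        try:
            probe.write_text("")
            probe.unlink()
        except OSError as exc:  # unwritable before any computation
            raise OSError(f"output directory {out_dir} is not writable") from exc
    if condition_index is None:
        try:
            condition_index = config.conditions().index(condition)
        except ValueError:
            condition_index = 0

    gen_params, gen_structure = _generating_inputs(config, condition)
    true_label = config.true_model
    N = condition.n_persons

    records = []
    aligned_thresholds = []
    acc_correct = acc_total = 0
    detection = {crit: {label: 0 for label in config.candidate_models} for crit in CRITERIA}
    for crit in CRITERIA:
        detection[crit]["nonconverged"] = 0
    n_all_converged = 0

    for r in range(config.n_replications):
        data_seed = config.base_seed + 10_000 * condition_index + r
        data = generate_dataset(condition, gen_params, gen_structure, seed=data_seed)
        rows = []
        fits: dict[str, FitResult] = {}
        for m_idx, label in enumerate(config.candidate_models):
            spec = ModelSpec.from_label(label)
            opts = FitOptions(
                **{
                    **asdict(config.fit_options),
                    "seed": (data_seed * 10 + m_idx) % (2**31),
                }
            )
            res = fit(spec, data, opts)
            fits[label] = res
            rows.append(
                {
                    "replication": r,
                    "model": label,
                    "loglik": res.loglik,
                    "d": res.n_params,
                    "N": N,
                    "converged": res.converged,
                    "n_iter": res.n_iter,
                }
            )
        table = ic_table(rows)
        all_converged = all(row["converged"] for row in rows)
        if all_converged:
            n_all_converged += 1
            for crit in CRITERIA:
                detection[crit][select_model(table, crit)] += 1
        else:
            for crit in CRITERIA:
                detection[crit]["nonconverged"] += 1

        true_fit = fits[true_label]
        if true_fit.converged:
            aligned, _, _ = align_labels(true_fit, gen_params)
            aligned_thresholds.append(aligned.params.thresholds)
            post = posterior_within_probs(
                aligned.params,
                aligned.structure,
                data,
                aligned.eap_within,
                aligned.eap_between,
            )
            est_classes = assign_classes(post)
            acc = classification_accuracy(data.true_within_class, est_classes)
            acc_correct += acc.n_correct
            acc_total += acc.n_total
            for row in rows:
                if row["model"] == true_label:
                    row["accuracy_percent"] = acc.rate_percent
        for crit in CRITERIA:
            sel = select_model(table, crit) if all_converged else "nonconverged"
            for row in rows:
                row[f"selected_{crit}"] = sel
        records.extend(rows)

    if aligned_thresholds:
        recovery = threshold_rmse(np.stack(aligned_thresholds), gen_params.thresholds)
        mean_rmse = recovery.mean_rmse
    else:
        mean_rmse = float("nan")
    accuracy_percent = 100.0 * acc_correct / acc_total if acc_total else float("nan")

    detail = pd.DataFrame(records)
    detail.attrs["true_model"] = true_label
    result = ConditionResult(
        condition=condition,
        n_replications=config.n_replications,
        n_converged=n_all_converged,
        mean_rmse=mean_rmse,
        accuracy_percent=accuracy_percent,
        detection_counts=detection,
        replications=detail,
    )
    if out_dir is not None:
        stem = f"{condition.label}_I{condition.n_items}_p{condition.pct_variant}"
        detail.to_csv(out_dir / f"replications_{stem}.csv", index=False)
    return result


def _pivot(summary: pd.DataFrame, value: str) -> pd.DataFrame:
    """Study-table layout: rows = condition labels, columns = items x percent."""
    wide = summary.pivot(
        index="label", columns=["n_items", "pct_variant"], values=value
    )
    wide.columns = [f"items{i}_pct{p}" for i, p in wide.columns]
    label_order = [lab for lab in _LABEL_ORDER if lab in wide.index]
    label_order += [lab for lab in wide.index if lab not in _LABEL_ORDER]
    return wide.loc[label_order]


_LABEL_ORDER = [
    "E5010", "E5050", "E10010", "E10050",
    "NE5010", "NE5050", "NE10010", "NE10050",
]


def run_study(config: StudyConfig) -> dict:
    """Sweep the design grid and build the study tables.

    Returns a dict with the per-condition ``summary`` frame, the wide ``rmse``
    and ``accuracy`` tables, one wide ``detect_<criterion>`` table per index,
    and the run ``manifest``.  Conditions are independent; with ``n_jobs > 1``
    they are dispatched through joblib with identical results.
    """
    conditions = config.conditions()
    t0 = time.time()
    failed: list[str] = []

    def _one(idx: int, cond: Condition):
        try:
            return run_condition(config, cond, condition_index=idx)
        except Exception as exc:  # partial failure: record and skip
            return (cond, repr(exc))

    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        raw = Parallel(n_jobs=config.n_jobs)(
            delayed(_one)(i, c) for i, c in enumerate(conditions)
        )
    else:
        raw = [_one(i, c) for i, c in enumerate(conditions)]

    results: list[ConditionResult] = []
    for item in raw:
        if isinstance(item, ConditionResult):
            results.append(item)
        else:
            cond, err = item
            failed.append(f"{cond.label}/I{cond.n_items}/p{cond.pct_variant}: {err}")

    summary = pd.DataFrame([r.summary_row() for r in results])
    tables: dict[str, object] = {"summary": summary}
    tables["rmse"] = _pivot(summary, "mean_rmse")
    tables["accuracy"] = _pivot(summary, "accuracy_percent")
    for crit in CRITERIA:
        tables[f"detect_{crit}"] = _pivot(summary, f"detect_{crit}")

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "base_seed": config.base_seed,
        "n_conditions": len(conditions),
        "n_replications": config.n_replications,
        "candidate_models": list(config.candidate_models),
        "expected_run_count": config.expected_run_count,
        "failed_conditions": failed,
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    tables["manifest"] = manifest

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        for name in ["rmse", "accuracy"] + [f"detect_{c}" for c in CRITERIA]:
            tables[name].to_csv(out / f"table_{name}.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
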