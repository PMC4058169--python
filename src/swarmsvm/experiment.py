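"""End-to-end comparison experiments.

``run_experiment`` executes the full pipeline for one optimizer —
split, min-max normalize (fitted on the training rows only), tune
(C, kernel parameter) on the training set, refit, evaluate on train and
test — and ``compare_models`` runs several optimizers over the identical
split to produce a comparison table with columns
{train accuracy, test accuracy, precision, recall, F-measure}.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as data_mod
from .data import LabeledDataset, SplitSpec, apply_normalization, normalize_minmax, split
from .metrics import classification_report, f_measure
from .tuning import OPTIMIZER_DEFAULTS, TunedSVM

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "compare_models",
           "write_comparison"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one tuned-SVM experiment.

    ``dataset`` is either a path to a delimited file or a dict of
    ``generate_synthetic`` keyword arguments.  ``optimizer_params``
    override the defaults for the named optimizer (population size,
    iteration count, coefficients).
    """

    dataset: str | dict
    n_train: int
    optimizer: str = "cs-pso"
    kernel_kind: str = "rbf"
    fitness_mode: str = "cv"
    cv_folds: int = 5
    optimizer_params: dict = field(default_factory=dict)
    label_column: int = -1
    label_map: dict | None = None
    missing_policy: str = "error"
    split_order: str = "random"
    positive_label: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZER_DEFAULTS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def load_dataset(self) -> LabeledDataset:
        if isinstance(self.dataset, dict):
            kwargs = dict(self.dataset)
            kwargs.setdefault("seed", self.seed)
            if "n_per_class" in kwargs:
                kwargs["n_per_class"] = tuple(kwargs["n_per_class"])
            return data_mod.generate_synthetic(**kwargs)
        return data_mod.read_delimited(
            self.dataset, label_column=self.label_column,
            label_map=self.label_map, missing_policy=self.missing_policy,
        )


@dataclass
class ExperimentReport:
    """Metrics and provenance for one experiment run."""

    optimizer: str
    best_params: dict
    best_fitness: float
    train_accuracy: float
    test_accuracy: float
    precision: float
    recall: float
    f_measure: float
    n_train: int
    n_test: int
    split_hash: str
    seed: int
    n_evaluations: int
    results: object = None  # TunedSVMResults (carries the trace and model)

    def to_row(self) -> dict:
        return {
            "algorithm": f"{self.optimizer.upper()}-SVM",
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }

    def to_json(self) -> str:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "results"}
        return json.dumps(d, indent=1, sort_keys=True)


def _split_hash(train_idx_labels: np.ndarray, test_idx_labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(train_idx_labels).tobytes())
    h.update(b"|")
    h.update(np.ascontiguousarray(test_idx_labels).tobytes())
    return h.hexdigest()[:16]


def _prepare(config: ExperimentConfig):
    """Load, split and normalize; shared by run_experiment/compare_models."""
    dataset = config.load_dataset()
    spec = SplitSpec(n_train=config.n_train, seed=config.seed, order=config.split_order)
    train, test = split(dataset, spec)
    train, params = normalize_minmax(train)
    test = apply_normalization(test, params)
    shash = _split_hash(train.features, test.features)
    return train, test, params, shash


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None,
                   _prepared=None) -> ExperimentReport:
    """Run one tuned-SVM experiment; optionally persist artifacts.

    With ``out_dir`` set, writes the convergence trace (CSV), the
    serialized model (JSON) and the report (JSON) there.  Fully
    reproducible: the same config and seed yield an identical report.
    """
    train, test, norm, shash = _prepared if _prepared is not None else _prepare(config)

    model = TunedSVM.from_dataset(
        train, kernel_kind=config.kernel_kind, optimizer=config.optimizer,
        fitness_mode=config.fitness_mode, cv_folds=config.cv_folds,
    )
    results = model.fit(seed=config.seed, **config.optimizer_params)

    train_rep = results.evaluate(train.features, train.labels, config.positive_label)
    test_rep = results.evaluate(test.features, test.labels, config.positive_label)

    report = ExperimentReport(
        optimizer=config.optimizer,
        best_params=results.best_params,
        best_fitness=results.best_fitness,
        train_accuracy=train_rep["accuracy"],
        test_accuracy=test_rep["accuracy"],
        precision=test_rep["precision"],
        recall=test_rep["recall"],
        f_measure=test_rep["f_measure"],
        n_train=train.n_samples,
        n_test=test.n_samples,
        split_hash=shash,
        seed=config.seed,
        n_evaluations=results.n_evaluations,
        results=results,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = config.optimizer.replace("-", "_")
        results.trace.write_csv(out / f"trace_{stem}.csv", model.space)
        results.svm_results.save(out / f"model_{stem}.json", norm)
        (out / f"report_{stem}.json").write_text(report.to_json())
    return report


def compare_models(configs: list[ExperimentConfig],
                   out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run several optimizers on the identical dataset and split.

    All configs must agree on everything except the optimizer and its
    parameters; the shared seed guarantees the same train/test partition,
    which is asserted by hashing the split.
    """
    if not configs:
        raise ValueError("no experiment configs given")
    ref = configs[0]
    for c in configs[1:]:
        same = (c.dataset == ref.dataset and c.n_train == ref.n_train
                and c.seed == ref.seed and c.kernel_kind == ref.kernel_kind
                and c.split_order == ref.split_order)
        if not same:
            raise ValueError("compare_models requires identical data, split, "
                             "kernel and seed across configs")
    prepared = _prepare(ref)
    reports = [run_experiment(c, out_dir=out_dir, _prepared=prepared) for c in configs]
    hashes = {r.split_hash for r in reports}
    assert len(hashes) == 1, "optimizers saw different train/test partitions"
    table = pd.DataFrame([r.to_row() for r in reports])
    # internal consistency: the F column is the harmonic mean of P and R
    for _, row in table.iterrows():
        assert abs(row["f_measure"] - f_measure(row["precision"], row["recall"])) < 1e-9
    if out_dir is not None:
        write_comparison(table, Path(out_dir) / "comparison.csv")
    return table


def write_comparison(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a comparison table as CSV (percent values, 4 decimals)."""
    table.to_csv(path, index=False, float_format="%.4f")
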