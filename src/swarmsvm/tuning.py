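"""Metaheuristic hyperparameter tuning of the kernel SVM.

The tuned dimensions are the box penalty ``C`` and one kernel parameter
(the RBF width ``sigma`` by default), searched on log2 scales.  Fitness is
the mean stratified k-fold cross-validation accuracy (percent) of an SVM
trained at the candidate hyperparameters — the standard choice in the
PSO-SVM literature — with plain training-set accuracy available as an
alternative mode.

``TunedSVM`` is the model-level entry point: construct from data, call
``fit`` with an optimizer name (``ga``, ``pso``, ``cs`` or ``cs-pso``),
and receive a results object holding the best hyperparameters, the
convergence trace and the final SVM refitted on the full training set.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import LabeledDataset
from .kernels import KernelSpec
from .metrics import classification_report
from .optimizers import (
    ConvergenceTrace,
    CuckooSearch,
    HybridCSPSO,
    ParticleSwarm,
    RealCodedGA,
    SearchSpace,
)
from .svm import KernelSVM, TrainConfig, train_smo

__all__ = [
    "stratified_folds",
    "FitnessFunction",
    "evaluate_fitness",
    "make_optimizer",
    "TunedSVM",
    "TunedSVMResults",
    "OPTIMIZER_DEFAULTS",
]

# population settings used throughout the comparison experiments
OPTIMIZER_DEFAULTS = {
    "ga": {"pop_size": 20, "n_iters": 100, "p_c": 0.5, "p_m": 0.005},
    "pso": {"pop_size": 20, "n_iters": 100, "c1": 1.5, "c2": 1.7},
    "cs": {"pop_size": 20, "n_iters": 100, "pa": 0.25},
    "cs-pso": {"pop_size": 20, "n_iters": 100, "pa": 0.25, "c1": 1.5, "c2": 1.7},
}


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold index pairs (train_idx, val_idx).

    Each class is shuffled once under ``seed`` and dealt round-robin into
    the k folds, so fold class ratios match the full set within one
    sample.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    folds = []
    for f in range(k):
        val = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        folds.append((train, val))
    return folds


def _kernel_from_values(kernel_kind: str, values: np.ndarray, names: list[str]) -> tuple[float, KernelSpec]:
    """Map a decoded search-space point onto (C, KernelSpec)."""
    params = dict(zip(names, np.atleast_1d(values)))
    C = float(params.pop("C"))
    spec = KernelSpec(kernel_kind, {k: float(v) for k, v in params.items()})
    return C, spec


class FitnessFunction:
    """Callable fitness: hyperparameter vector -> accuracy percentage.

    Parameters
    ----------
    train : training dataset (already normalized).
    kernel_kind : kernel family whose parameter is tuned.
    mode : ``"cv"`` (default) for stratified k-fold CV accuracy, or
        ``"train-accuracy"`` for resubstitution accuracy.
    k : fold count for CV mode.
    seed : controls fold assignment and the SMO solver; folds are drawn
        once at construction so every candidate sees the same partition.
    """

    def __init__(self, train: LabeledDataset, kernel_kind: str = "rbf",
                 mode: str = "cv", k: int = 5, seed: int = 0,
                 space: SearchSpace | None = None,
                 tolerance: float = 1e-3, max_passes: int = 50):
        if mode not in ("cv", "train-accuracy"):
            raise ValueError(f"unknown fitness mode {mode!r}")
        self.train = train
        self.kernel_kind = kernel_kind
        self.mode = mode
        self.k = k
        self.seed = seed
        self.space = space if space is not None else SearchSpace.for_svm(kernel_kind)
        self.names = self.space.names()
        self.tolerance = tolerance
        self.max_passes = max_passes
        self.folds = (
            stratified_folds(train.labels, k, seed) if mode == "cv" else None
        )

    def __call__(self, values: np.ndarray) -> float:
        C, spec = _kernel_from_values(self.kernel_kind, values, self.names)
        if self.mode == "train-accuracy":
            return self._accuracy(np.arange(self.train.n_samples),
                                  np.arange(self.train.n_samples), C, spec)
        scores = []
        for train_idx, val_idx in self.folds:
            scores.append(self._accuracy(train_idx, val_idx, C, spec))
        return float(np.mean(scores))

    def _accuracy(self, train_idx, val_idx, C, spec) -> float:
        X, y = self.train.features, self.train.labels
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = KernelSVM(X[train_idx], y[train_idx], kernel=spec, C=C)
                res = model.fit(tolerance=self.tolerance,
                                max_passes=self.max_passes, seed=self.seed)
            pred = res.predict(X[val_idx])
        except Exception as exc:  # a failed fold scores 0, search continues
            warnings.warn(f"SVM training failed for C={C:g}: {exc}; fold scores 0")
            return 0.0
        return 100.0 * float(np.mean(pred == y[val_idx]))


def evaluate_fitness(position, train: LabeledDataset, k: int = 5,
                     kernel_kind: str = "rbf", seed: int = 0) -> float:
    """One-shot CV fitness of a decoded (C, kernel parameter) point."""
    return FitnessFunction(train, kernel_kind=kernel_kind, k=k, seed=seed)(
        np.asarray(position, dtype=float)
    )


def make_optimizer(name: str, space: SearchSpace, seed: int = 0, **overrides):
    """Construct an optimizer by name with the package's default settings."""
    name = name.lower()
    if name not in OPTIMIZER_DEFAULTS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZER_DEFAULTS)}")
    params = dict(OPTIMIZER_DEFAULTS[name])
    params.update(overrides)
    cls = {"ga": RealCodedGA, "pso": ParticleSwarm, "cs": CuckooSearch,
           "cs-pso": HybridCSPSO}[name]
    return cls(space, seed=seed, **params)


class TunedSVM:
    """Kernel SVM with metaheuristically tuned hyperparameters.

    Parameters
    ----------
    X, y : training data (labels in {+1, -1}).
    kernel_kind : kernel family; its parameter joins ``C`` in the search.
    optimizer : ``"ga"``, ``"pso"``, ``"cs"`` or ``"cs-pso"``.
    space : hyperparameter box; defaults to ``SearchSpace.for_svm``.
    fitness_mode, cv_folds : see :class:`FitnessFunction`.
    """

    def __init__(self, X, y, kernel_kind: str = "rbf", optimizer: str = "cs-pso",
                 space: SearchSpace | None = None, fitness_mode: str = "cv",
                 cv_folds: int = 5):
        self.data = LabeledDataset(np.asarray(X, dtype=float), np.asarray(y))
        self.kernel_kind = kernel_kind
        self.optimizer_name = optimizer
        self.space = space if space is not None else SearchSpace.for_svm(kernel_kind)
        self.fitness_mode = fitness_mode
        self.cv_folds = cv_folds

    @classmethod
    def from_dataset(cls, data: LabeledDataset, **kwargs) -> "TunedSVM":
        return cls(data.features, data.labels, **kwargs)

    def fit(self, seed: int = 0, **optimizer_overrides) -> "TunedSVMResults":
        """Run the search, refit at the best point, return results."""
        fitness = FitnessFunction(
            self.data, kernel_kind=self.kernel_kind, mode=self.fitness_mode,
            k=self.cv_folds, seed=seed, space=self.space,
        )
        opt = make_optimizer(self.optimizer_name, self.space, seed=seed,
                             **optimizer_overrides)
        best, trace = opt.run(fitness)
        decoded = self.space.decode_dict(best.position)
        C, spec = _kernel_from_values(
            self.kernel_kind, self.space.decode(best.position), self.space.names()
        )
        config = TrainConfig(C=C, tolerance=fitness.tolerance,
                             max_passes=200, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final = train_smo(self.data, config, kernel=spec)
        return TunedSVMResults(
            model=self,
            best_params=decoded,
            best_fitness=best.fitness,
            trace=trace,
            svm_results=final,
            n_evaluations=opt.n_evaluations,
            seed=seed,
        )


class TunedSVMResults:
    """Outcome of a tuned fit: hyperparameters, trace, final classifier."""

    def __init__(self, model, best_params, best_fitness, trace, svm_results,
                 n_evaluations, seed):
        self.model = model
        self.best_params = best_params
        self.best_fitness = best_fitness
        self.trace: ConvergenceTrace = trace
        self.svm_results = svm_results
        self.n_evaluations = n_evaluations
        self.seed = seed

    def predict(self, X) -> np.ndarray:
        return self.svm_results.predict(X)

    def evaluate(self, X, y, positive_label: int = 1) -> dict:
        """Accuracy/precision/recall/F on a labeled set (percentages)."""
        return classification_report(np.asarray(y), self.predict(X), positive_label)

    def summary(self) -> str:
        p = ", ".join(f"{k}={v:.4g}" for k, v in self.best_params.items())
        lines = [
            f"Tuned SVM ({self.model.optimizer_name.upper()})",
            "=" * 40,
            f"kernel:            {self.model.kernel_kind}",
            f"fitness:           {self.model.fitness_mode} "
            f"({self.model.cv_folds}-fold)" if self.model.fitness_mode == "cv"
            else f"fitness:           {self.model.fitness_mode}",
            f"best parameters:   {p}",
            f"best fitness:      {self.best_fitness:.4f} %",
            f"generations:       {len(self.trace)}",
            f"objective evals:   {self.n_evaluations}",
            f"support vectors:   {self.svm_results.n_support}",
            f"seed:              {self.seed}",
        ]
        return "\n".join(lines)
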