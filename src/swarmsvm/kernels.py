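"""Kernel functions for the soft-margin SVM.

Four kinds are supported:

- ``linear``:      k(x, z) = x . z
- ``polynomial``:  k(x, z) = (x . z + a)^b        (offset a, degree b)
- ``rbf``:         k(x, z) = exp(-||x - z||^2 / (2 sigma^2))
- ``sigmoid``:     k(x, z) = tanh(a x . z - b)

The sigmoid kernel is not positive semi-definite for general (a, b); the
trainer emits a warning but proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelSpec", "kernel_eval", "kernel_matrix"]

_KINDS = ("linear", "polynomial", "rbf", "sigmoid")

_DEFAULTS = {
    "linear": {},
    "polynomial": {"a": 1.0, "b": 3},
    "rbf": {"sigma": 1.0},
    "sigmoid": {"a": 1.0, "b": 0.0},
}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus its parameters.

    ``params`` keys: ``a``/``b`` for polynomial and sigmoid, ``sigma`` for
    rbf (width, > 0).  Missing parameters take field defaults.
    """

    kind: str = "rbf"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; choose from {_KINDS}")
        merged = dict(_DEFAULTS[self.kind])
        merged.update(self.params)
        object.__setattr__(self, "params", merged)
        if self.kind == "rbf" and merged["sigma"] <= 0:
            raise ValueError("rbf width sigma must be > 0")
        if self.kind == "polynomial" and merged["b"] < 1:
            raise ValueError("polynomial degree must be >= 1")

    def with_param(self, **updates) -> "KernelSpec":
        p = dict(self.params)
        p.update(updates)
        return KernelSpec(self.kind, p)

    @property
    def tuned_param_name(self) -> str:
        """Name of the kernel parameter exposed to hyperparameter search."""
        return {"rbf": "sigma", "polynomial": "a", "sigmoid": "a", "linear": None}[self.kind]


def kernel_eval(spec: KernelSpec, x: np.ndarray, z: np.ndarray) -> float:
    """Evaluate k(x, z) for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    return float(kernel_matrix(spec, x[None, :], z[None, :])[0, 0])


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Z[j]) (Z defaults to X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    p = spec.params
    if spec.kind == "linear":
        return X @ Z.T
    if spec.kind == "polynomial":
        return (X @ Z.T + p["a"]) ** p["b"]
    if spec.kind == "rbf":
        sq = (
            np.sum(X * X, axis=1)[:, None]
            - 2.0 * (X @ Z.T)
            + np.sum(Z * Z, axis=1)[None, :]
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-sq / (2.0 * p["sigma"] ** 2))
    # sigmoid
    return np.tanh(p["a"] * (X @ Z.T) - p["b"])
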