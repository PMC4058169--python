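"""Soft-margin kernel SVM trained by sequential minimal optimization.

The classifier solves the dual problem

    max_a  sum_i a_i - 1/2 a^T H a
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0,      H_ij = y_i y_j k(x_i, x_j)

where C is the box penalty trading margin width against slack.  The
decision function is f(x) = sum_i a_i y_i k(x_i, x) + b with the bias b
averaged over support vectors; prediction is sgn(f(x)) with ties mapped
to +1.

The solver is SMO with working-set selection by maximal KKT violation for
the first index and a max-|E1 - E2| heuristic (seeded-random fallback)
for the second.  A brute-force dual solver built on scipy's SLSQP is
provided as an independent oracle for small instances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import LabeledDataset, NormalizationParams
from .kernels import KernelSpec, kernel_matrix

__all__ = [
    "TrainConfig",
    "KernelSVM",
    "SVMResults",
    "train_smo",
    "compute_bias",
    "dual_objective",
    "solve_dual_reference",
]

# numerical rank threshold: a_i counts as a support vector when a_i > RANK_TOL * C
RANK_TOL = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    """SMO solver settings.

    ``tolerance`` is the KKT tolerance used both for working-set selection
    and as the convergence criterion; ``max_passes`` bounds the number of
    full-sweep equivalents (n * max_passes pair updates).
    """

    C: float = 1.0
    tolerance: float = 1e-3
    max_passes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


class KernelSVM:
    """Soft-margin kernel SVM model (statsmodels-style: ``fit`` -> results).

    Parameters
    ----------
    X : (n, p) training feature matrix.
    y : (n,) labels in {+1, -1}; both classes must be present.
    kernel : :class:`~swarmsvm.kernels.KernelSpec`.
    C : box-constraint penalty, > 0.
    """

    def __init__(self, X, y, kernel: KernelSpec | None = None, C: float = 1.0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be (n, p) and y must be (n,)")
        if not np.all(np.isin(self.y, (1, -1))):
            raise ValueError("labels must be +1 or -1")
        if len(np.unique(self.y)) < 2:
            raise ValueError("training data contains a single class")
        self.kernel = kernel if kernel is not None else KernelSpec("rbf")
        if C <= 0:
            raise ValueError("C must be > 0")
        self.C = float(C)
        if self.kernel.kind == "sigmoid":
            warnings.warn(
                "sigmoid kernel is not positive semi-definite in general; "
                "the dual is non-concave and SMO may return a local solution",
                stacklevel=2,
            )

    @classmethod
    def from_dataset(cls, data: LabeledDataset, kernel: KernelSpec | None = None,
                     C: float = 1.0) -> "KernelSVM":
        return cls(data.features, data.labels, kernel=kernel, C=C)

    def fit(self, tolerance: float = 1e-3, max_passes: int = 200, seed: int = 0) -> "SVMResults":
        """Solve the dual by SMO and return an :class:`SVMResults`."""
        config = TrainConfig(C=self.C, tolerance=tolerance, max_passes=max_passes, seed=seed)
        return self._fit(config)

    def _fit(self, config: TrainConfig) -> "SVMResults":
        n = self.X.shape[0]
        C, tol = config.C, config.tolerance
        K = kernel_matrix(self.kernel, self.X)
        if not np.all(np.isfinite(K)):
            raise ValueError("kernel matrix contains non-finite values")
        y = self.y.astype(float)
        rng = np.random.default_rng(config.seed)

        alpha = np.zeros(n)
        b = 0.0
        u = np.zeros(n)  # u_i = sum_j alpha_j y_j K_ij (decision value sans bias)
        eps = 1e-12
        max_steps = config.max_passes * n
        steps = 0
        converged = False

        def take_step(i1: int, i2: int) -> bool:
            nonlocal b
            if i1 == i2:
                return False
            a1, a2 = alpha[i1], alpha[i2]
            y1, y2 = y[i1], y[i2]
            E1 = u[i1] + b - y1
            E2 = u[i2] + b - y2
            s = y1 * y2
            if s > 0:
                L, H = max(0.0, a1 + a2 - C), min(C, a1 + a2)
            else:
                L, H = max(0.0, a2 - a1), min(C, C + a2 - a1)
            if H - L < eps:
                return False
            k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
            eta = k11 + k22 - 2.0 * k12
            if eta > eps:
                a2_new = a2 + y2 * (E1 - E2) / eta
                a2_new = min(H, max(L, a2_new))
            else:
                # non-PSD kernel: dual is flat/convex along this pair; take the
                # better endpoint of the feasible segment (bias-free values)
                f1 = y1 * (u[i1] - y1) - a1 * k11 - s * a2 * k12
                f2 = y2 * (u[i2] - y2) - s * a1 * k12 - a2 * k22
                L1 = a1 + s * (a2 - L)
                H1 = a1 + s * (a2 - H)
                obj_L = (L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11
                         + 0.5 * L * L * k22 + s * L * L1 * k12)
                obj_H = (H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11
                         + 0.5 * H * H * k22 + s * H * H1 * k12)
                if obj_L < obj_H - eps:
                    a2_new = L
                elif obj_H < obj_L - eps:
                    a2_new = H
                else:
                    return False
            if abs(a2_new - a2) < eps * (a2_new + a2 + eps):
                return False
            a1_new = a1 + s * (a2 - a2_new)
            # bias update (Platt): keep f consistent on the updated pair
            b1 = b - E1 - y1 * (a1_new - a1) * k11 - y2 * (a2_new - a2) * k12
            b2 = b - E2 - y1 * (a1_new - a1) * k12 - y2 * (a2_new - a2) * k22
            if 0.0 < a1_new < C:
                b = b1
            elif 0.0 < a2_new < C:
                b = b2
            else:
                b = 0.5 * (b1 + b2)
            u[:] += y1 * (a1_new - a1) * K[i1] + y2 * (a2_new - a2) * K[i2]
            alpha[i1], alpha[i2] = a1_new, a2_new
            return True

        while steps < max_steps:
            E = u + b - y
            r = y * E
            can_up = alpha < C - RANK_TOL * C
            can_dn = alpha > RANK_TOL * C
            viol = np.maximum(np.where(can_up, -r, -np.inf), np.where(can_dn, r, -np.inf))
            i1 = int(np.argmax(viol))
            if viol[i1] <= tol:
                converged = True
                break
            # second choice: maximize |E1 - E2|, preferring non-bound points
            order = np.argsort(-np.abs(E[i1] - E))
            non_bound = can_up & can_dn
            candidates = [int(j) for j in order if non_bound[j]]
            candidates += [int(j) for j in order if not non_bound[j]]
            stepped = False
            for i2 in candidates[:16]:
                if take_step(i1, i2):
                    stepped = True
                    break
            if not stepped:
                for i2 in rng.permutation(n):
                    if take_step(i1, int(i2)):
                        stepped = True
                        break
            if not stepped:
                # no pair can make progress: treat as converged at current tol
                converged = True
                break
            steps += 1

        support = np.flatnonzero(alpha > RANK_TOL * C)
        bias = compute_bias(alpha, y, K, C) if support.size else b
        return SVMResults(
            model=self,
            alphas=alpha,
            bias=bias,
            support_indices=support,
            n_steps=steps,
            converged=converged,
            config=config,
            _K=K,
        )


def compute_bias(alpha: np.ndarray, y: np.ndarray, K: np.ndarray, C: float) -> float:
    """Bias averaged over the support set V:  b = mean_v (y_v - sum_i a_i y_i k(x_i, x_v)).

    Unbounded support vectors (0 < a_v < C) sit exactly on the margin and
    give the sharpest estimate, so they are preferred; if none exist the
    average runs over all support vectors.
    """
    sv = np.flatnonzero(alpha > RANK_TOL * C)
    if sv.size == 0:
        raise ValueError("empty support set: no alpha exceeds the rank threshold")
    unbounded = sv[alpha[sv] < C * (1.0 - RANK_TOL)]
    V = unbounded if unbounded.size else sv
    u = K[:, V].T @ (alpha * y)
    return float(np.mean(y[V] - u))


def dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    """Dual objective  sum_i a_i - 1/2 a^T H a,  H = (y y^T) * K."""
    v = alpha * y
    return float(np.sum(alpha) - 0.5 * v @ K @ v)


class SVMResults:
    """Fitted SVM: multipliers, bias, support set, prediction and diagnostics."""

    def __init__(self, model, alphas, bias, support_indices, n_steps, converged,
                 config, _K=None):
        self.model = model
        self.alphas = alphas
        self.bias = float(bias)
        self.support_indices = support_indices
        self.n_steps = n_steps
        self.converged = converged
        self.config = config
        self._K = _K

    # -- core interface -------------------------------------------------
    @property
    def n_support(self) -> int:
        return int(self.support_indices.size)

    def decision_function(self, X) -> np.ndarray:
        """f(x) = sum_{i in V} a_i y_i k(x_i, x) + b, evaluated on support vectors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"expected {self.model.X.shape[1]} features, got {X.shape[1]}"
            )
        sv = self.support_indices
        if sv.size == 0:
            return np.full(X.shape[0], self.bias)
        Ksv = kernel_matrix(self.model.kernel, self.model.X[sv], X)
        return (self.alphas[sv] * self.model.y[sv]) @ Ksv + self.bias

    def predict(self, X) -> np.ndarray:
        """Labels in {+1, -1}; a decision value of exactly 0 maps to +1."""
        f = self.decision_function(X)
        return np.where(f >= 0.0, 1, -1)

    def dual_objective(self) -> float:
        return dual_objective(self.alphas, self.model.y.astype(float), self._gram())

    # -- diagnostics ----------------------------------------------------
    def _gram(self) -> np.ndarray:
        if self._K is None:
            self._K = kernel_matrix(self.model.kernel, self.model.X)
        return self._K

    def margins(self) -> np.ndarray:
        """y_i f(x_i) on the training points."""
        u = self._gram() @ (self.alphas * self.model.y) + self.bias
        return self.model.y * u

    def kkt_violation(self) -> float:
        """Largest violation of the KKT optimality conditions.

        a_i = 0  =>  y_i f(x_i) >= 1;  0 < a_i < C  =>  y_i f(x_i) = 1;
        a_i = C  =>  y_i f(x_i) <= 1.  Returns max_i of the shortfall.
        """
        m = self.margins()
        a, C = self.alphas, self.model.C
        lo, hi = RANK_TOL * C, C * (1.0 - RANK_TOL)
        viol = np.zeros_like(a)
        free = (a > lo) & (a < hi)
        viol[a <= lo] = np.maximum(0.0, 1.0 - m[a <= lo])
        viol[free] = np.abs(m[free] - 1.0)
        viol[a >= hi] = np.maximum(0.0, m[a >= hi] - 1.0)
        return float(viol.max()) if viol.size else 0.0

    def feasibility_gap(self) -> float:
        """|sum_i a_i y_i|, which the dual equality constraint drives to 0."""
        return float(abs(np.dot(self.alphas, self.model.y)))

    def summary(self) -> str:
        lines = [
            "Soft-margin kernel SVM (SMO)",
            "=" * 40,
            f"n_samples:        {self.model.X.shape[0]}",
            f"n_features:       {self.model.X.shape[1]}",
            f"kernel:           {self.model.kernel.kind} {self.model.kernel.params}",
            f"C:                {self.model.C:g}",
            f"support vectors:  {self.n_support}",
            f"bias b:           {self.bias:.6g}",
            f"dual objective:   {self.dual_objective():.6g}",
            f"max KKT violation: {self.kkt_violation():.3g}",
            f"converged:        {self.converged} ({self.n_steps} pair updates)",
        ]
        return "\n".join(lines)

    # -- serialization --------------------------------------------------
    def to_dict(self, normalization: NormalizationParams | None = None) -> dict:
        sv = self.support_indices
        d = {
            "kernel": {"kind": self.model.kernel.kind, "params": self.model.kernel.params},
            "C": self.model.C,
            "bias": self.bias,
            "alphas": self.alphas[sv].tolist(),
            "support_labels": self.model.y[sv].tolist(),
            "support_vectors": self.model.X[sv].tolist(),
        }
        if normalization is not None:
            d["normalization"] = {
                "mins": normalization.mins.tolist(),
                "maxs": normalization.maxs.tolist(),
            }
        return d

    def save(self, path, normalization: NormalizationParams | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(normalization), fh, indent=1)


def load_model(path) -> "SVMResults":
    """Reload a serialized model for prediction.

    The reloaded object carries only the support set, which fully
    determines the decision function.
    """
    with open(path) as fh:
        d = json.load(fh)
    X = np.array(d["support_vectors"], dtype=float)
    y = np.array(d["support_labels"], dtype=int)
    kernel = KernelSpec(d["kernel"]["kind"], d["kernel"]["params"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = KernelSVM(X, y, kernel=kernel, C=d["C"])
    alphas = np.array(d["alphas"], dtype=float)
    return SVMResults(
        model=model,
        alphas=alphas,
        bias=d["bias"],
        support_indices=np.arange(X.shape[0]),
        n_steps=0,
        converged=True,
        config=TrainConfig(C=d["C"]),
    )


def train_smo(data: LabeledDataset, config: TrainConfig,
              kernel: KernelSpec | None = None) -> SVMResults:
    """Functional entry point: fit an SVM on a dataset with given settings."""
    model = KernelSVM.from_dataset(data, kernel=kernel, C=config.C)
    return model._fit(config)


def solve_dual_reference(X, y, C: float, kernel: KernelSpec | None = None) -> tuple[np.ndarray, float]:
    """Brute-force solution of the dual QP for small instances (oracle).

    Maximizes sum a - 1/2 a^T H a subject to the box and equality
    constraints with scipy's SLSQP from several feasible starts.  Intended
    for <= ~10 points; independent of the SMO path.

    Returns (alpha, dual objective value).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kernel = kernel if kernel is not None else KernelSpec("rbf")
    K = kernel_matrix(kernel, X)
    H = np.outer(y, y) * K
    n = len(y)

    def neg_obj(a):
        return -(np.sum(a) - 0.5 * a @ H @ a)

    def neg_grad(a):
        return -(np.ones(n) - H @ a)

    constraints = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    bounds = [(0.0, C)] * n
    best_a, best_val = np.zeros(n), 0.0
    rng = np.random.default_rng(12345)
    starts = [np.zeros(n)] + [rng.uniform(0, C, n) for _ in range(8)]
    for a0 in starts:
        # project start onto the equality constraint
        a0 = a0 - y * (a0 @ y) / n
        a0 = np.clip(a0, 0, C)
        res = optimize.minimize(
            neg_obj, a0, jac=neg_grad, bounds=bounds, constraints=constraints,
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success or res.status == 0:
            val = -neg_obj(res.x)
            if val > best_val:
                best_val, best_a = val, res.x
    return best_a, best_val
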