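"""Soft-margin SVM over precomputed kernels and multiple kernel learning.

The MKL classifier learns a convex combination K = sum_k beta_k K_k of
sub-kernel Gram matrices jointly with the SVM dual solution, following the
semi-infinite linear programming (SILP) formulation: alternate between
(i) solving a standard SVM on the current combined kernel and (ii) updating
the weights beta by a cutting-plane LP over the accumulated dual iterates.
A halving line search between the incumbent and the LP proposal keeps the
MKL objective monotonically non-increasing.

The inner dual solve is delegated to libsvm (scikit-learn's ``SVC`` with a
precomputed kernel); weights live on the probability simplex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sklearn.svm import SVC

from .data_model import Instance, InstanceSet, WindowSpec
from .kernels import KernelConfig, KernelMatrix, build_matrix, kernel_between


def _as_array(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def dual_objective(K: np.ndarray, labels: np.ndarray, alphas: np.ndarray) -> float:
    """Soft-margin dual objective sum(a) - 1/2 (a*y)' K (a*y)."""
    ay = alphas * labels
    return float(np.sum(alphas) - 0.5 * ay @ K @ ay)


def train_svm(K, labels, C: float, tol: float = 1e-6):
    """Solve the soft-margin SVM dual on a precomputed kernel.

    Returns ``(alphas, bias)`` with 0 <= alpha_i <= C over *all* training
    instances (zero off the support set) and the decision-function offset b,
    computed by libsvm from the free support vectors.
    """
    K = _as_array(K)
    y = np.asarray(labels, dtype=float)
    if C <= 0:
        raise ValueError("C must be positive")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate problem: all labels identical")
    clf = SVC(kernel="precomputed", C=C, tol=tol)
    clf.fit(K, y)
    alphas = np.zeros(len(y))
    alphas[clf.support_] = np.abs(clf.dual_coef_[0])
    bias = float(clf.intercept_[0])
    return alphas, bias


@dataclass
class MKLModel:
    """A trained multiple-kernel SVM: simplex weights beta over sub-kernels,
    dual coefficients alpha, bias b, and everything needed to score new
    windows without retraining."""

    betas: np.ndarray
    alphas: np.ndarray
    bias: float
    labels: np.ndarray
    C: float
    configs: list[KernelConfig] | None = None
    training_instances: list[Instance] | None = None
    stored_spec: WindowSpec | None = None
    converged: bool = True
    n_iterations: int = 0
    objective_history: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_history[-1] if self.objective_history else float("nan")

    @property
    def display_weights(self) -> np.ndarray:
        """Weights rescaled so the largest equals 1 (reporting convention)."""
        m = self.betas.max()
        return self.betas / m if m > 0 else self.betas

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        if self.configs is None or self.training_instances is None:
            raise ValueError("model lacks configs/instances; cannot serialize")
        doc = {
            "betas": self.betas.tolist(),
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "labels": self.labels.tolist(),
            "C": self.C,
            "configs": [c.to_dict() for c in self.configs],
            "stored_spec": {"left": self.stored_spec.left,
                            "right": self.stored_spec.right},
            "training_instances": [
                {"seq_window": i.seq_window, "ss_window": i.ss_window,
                 "sa_window": i.sa_window, "label": i.label,
                 "source_id": i.source_id, "bond_index": i.bond_index}
                for i in self.training_instances
            ],
        }
        return json.dumps(doc)

    @staticmethod
    def from_json(text: str) -> "MKLModel":
        doc = json.loads(text)
        return MKLModel(
            betas=np.array(doc["betas"]),
            alphas=np.array(doc["alphas"]),
            bias=float(doc["bias"]),
            labels=np.array(doc["labels"]),
            C=float(doc["C"]),
            configs=[KernelConfig.from_dict(c) for c in doc["configs"]],
            stored_spec=WindowSpec(**doc["stored_spec"]),
            training_instances=[Instance(**d) for d in doc["training_instances"]],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @staticmethod
    def load(path) -> "MKLModel":
        with open(path) as fh:
            return MKLModel.from_json(fh.read())


def _lp_step(cuts: list[tuple[float, np.ndarray]], n_kernels: int) -> np.ndarray:
    """Restricted-master LP of the SILP: min theta subject to
    sum(alpha^t) - sum_k beta_k T_k(alpha^t) <= theta for every stored cut,
    beta on the simplex.  Variables are (beta_1..K, theta)."""
    n = n_kernels
    A_ub, b_ub = [], []
    for s_alpha, T in cuts:
        A_ub.append(list(-T) + [-1.0])
        b_ub.append(-s_alpha)
    res = linprog(
        c=[0.0] * n + [1.0],
        A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=[[1.0] * n + [0.0]], b_eq=[1.0],
        bounds=[(0, None)] * n + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"MKL restricted LP failed: {res.message}")
    beta = np.clip(res.x[:n], 0.0, None)
    return beta / beta.sum()


def _identical_groups(K_arrays: list[np.ndarray]) -> list[list[int]]:
    groups: list[list[int]] = []
    for i, K in enumerate(K_arrays):
        for g in groups:
            if np.allclose(K, K_arrays[g[0]], atol=1e-12):
                g.append(i)
                break
        else:
            groups.append([i])
    return groups


def train_mkl(K_list, labels, C: float, tol: float = 1e-4,
              max_iter: int = 100, svm_tol: float = 1e-6) -> MKLModel:
    """Learn simplex weights beta and the SVM dual solution jointly.

    Alternates libsvm solves on the combined kernel with cutting-plane LP
    updates of beta; a halving line search guarantees the objective never
    increases.  Exactly duplicated sub-kernels receive equal weight (maximum
    entropy over the tied set), which leaves the objective unchanged.
    """
    Ks = [_as_array(K) for K in K_list]
    y = np.asarray(labels, dtype=float)
    n_k = len(Ks)
    if n_k < 1:
        raise ValueError("at least one sub-kernel required")
    if len({K.shape for K in Ks}) != 1:
        raise ValueError("sub-kernel matrices must share a shape")

    def solve(beta):
        Kc = np.einsum("k,kij->ij", beta, np.stack(Ks)) if n_k > 1 else Ks[0]
        alphas, bias = train_svm(Kc, y, C, tol=svm_tol)
        return alphas, bias, dual_objective(Kc, y, alphas)

    betas = np.full(n_k, 1.0 / n_k)
    alphas, bias, J = solve(betas)
    history = [J]
    warnings: list[str] = []
    converged = n_k == 1
    it = 0

    def make_cut(a):
        ay = a * y
        T = np.array([0.5 * ay @ K @ ay for K in Ks])
        return (float(np.sum(a)), T)

    if not converged:
        cuts = [make_cut(alphas)]
        for it in range(1, max_iter + 1):
            beta_prop = _lp_step(cuts, n_k)
            step = 1.0
            while True:
                beta_try = (1.0 - step) * betas + step * beta_prop
                a_try, b_try, J_try = solve(beta_try)
                if J_try <= J + 1e-12 or step <= 1.0 / 64:
                    break
                step *= 0.5
            rel_change = abs(J - J_try) / max(abs(J_try), 1.0)
            betas, alphas, bias, J = beta_try, a_try, b_try, J_try
            history.append(J)
            cuts.append(make_cut(alphas))
            if rel_change < tol:
                converged = True
                break
        if not converged:
            warnings.append(
                f"MKL did not converge in {max_iter} iterations; "
                "returning best iterate"
            )

    # Maximum-entropy tie-break: equal weight over identical sub-kernels.
    groups = _identical_groups(Ks)
    if any(len(g) > 1 for g in groups):
        for g in groups:
            betas[g] = betas[g].mean()
        alphas, bias, J = solve(betas)
        history.append(J)

    return MKLModel(betas=betas, alphas=alphas, bias=bias, labels=y, C=C,
                    converged=converged, n_iterations=it,
                    objective_history=history, warnings=warnings)


def fit_mkl(instances: InstanceSet, configs: list[KernelConfig], C: float = 1.0,
            **kwargs) -> MKLModel:
    """Convenience wrapper: build per-config Gram matrices from an instance
    set, run MKL, and attach everything needed for later scoring."""
    insts = list(instances)
    stored = instances.spec
    Ks = [build_matrix(insts, cfg, stored) for cfg in configs]
    y = np.array([i.label for i in insts], dtype=float)
    model = train_mkl(Ks, y, C, **kwargs)
    model.configs = list(configs)
    model.training_instances = insts
    model.stored_spec = stored
    return model


def decision_scores(model: MKLModel, queries: list[Instance]) -> np.ndarray:
    """Combined decision function sum_i alpha_i y_i sum_k beta_k k_k(x_i, q) + b
    for a batch of query instances."""
    if model.configs is None or model.training_instances is None:
        raise ValueError("model is not scoreable: missing configs or instances")
    Kc = np.zeros((len(model.training_instances), len(queries)))
    for beta, cfg in zip(model.betas, model.configs):
        if beta == 0.0:
            continue
        Kc += beta * kernel_between(model.training_instances, queries, cfg,
                                    model.stored_spec)
    ay = model.alphas * model.labels
    return ay @ Kc + model.bias


def decision_function(model: MKLModel, query: Instance) -> float:
    """Decision value for a single candidate window."""
    return float(decision_scores(model, [query])[0])
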