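"""Experimental protocol: repeated cross-validated AUC, paired comparisons,
hyperparameter grid search, and coordinate-descent window optimization.

Performance is measured as the area under the ROC curve (AUC), averaged over
repeated stratified k-fold cross-validation (10 repeats of 10-fold by
default, i.e. 100 fold-level AUCs) with the standard error of the mean over
all fold AUCs.  Negatives are re-sampled once per repeat.  Splitting is at
the instance level by default; substrate-level (grouped) splitting is
available to guard against homolog leakage between folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .data_model import AnnotatedSubstrate, WindowSpec, build_instances
from .kernels import KernelConfig, build_matrix
from .mkl_svm import train_mkl


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic P(score+ > score-) + 1/2 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class CVReport:
    """Fold-level AUCs from a repeated cross-validation run."""

    auc_values: list[float]
    config_summary: str
    seed: int
    skipped_folds: int = 0
    fold_table: pd.DataFrame | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def sem(self) -> float:
        v = np.asarray(self.auc_values)
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    def summary(self) -> str:
        return (f"{self.config_summary}: AUC {100 * self.mean_auc:.2f}% "
                f"(SEM {100 * self.sem:.2f}%) over {len(self.auc_values)} folds")


def _score_fold(K_arrays, y, train_idx, test_idx, C, mkl_kwargs):
    K_tr = [K[np.ix_(train_idx, train_idx)] for K in K_arrays]
    model = train_mkl(K_tr, y[train_idx], C, **mkl_kwargs)
    Kc = np.zeros((len(train_idx), len(test_idx)))
    for beta, K in zip(model.betas, K_arrays):
        if beta:
            Kc += beta * K[np.ix_(train_idx, test_idx)]
    ay = model.alphas * y[train_idx]
    return ay @ Kc + model.bias


def cross_validate(substrates: list[AnnotatedSubstrate],
                   kernel_configs: list[KernelConfig], C: float = 1.0,
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   neg_ratio: int = 10, split_by_sequence: bool = False,
                   mkl_kwargs: dict | None = None) -> CVReport:
    """Repeated stratified k-fold CV of the MKL classifier.

    Per repeat r: negatives are re-sampled with seed ``seed + r``, Gram
    matrices are built once over all instances and sliced per fold, an MKL
    model is trained on each training split and its decision values are
    scored on the held-out fold.  Folds missing a class are skipped and
    counted.  The entire procedure is reproducible from ``seed``.
    """
    if folds < 2 or repeats < 1:
        raise ValueError("need folds >= 2 and repeats >= 1")
    mkl_kwargs = mkl_kwargs or {}
    max_spec = WindowSpec.union([c.spec for c in kernel_configs])
    aucs: list[float] = []
    rows = []
    skipped = 0
    for rep in range(repeats):
        inst_set = build_instances(substrates, max_spec, neg_ratio,
                                   rng_seed=seed + rep)
        insts = inst_set.instances
        y = inst_set.labels
        K_arrays = [build_matrix(inst_set, cfg, max_spec).values
                    for cfg in kernel_configs]
        fold_seed = (seed * 1009 + rep) % (2 ** 31)
        if split_by_sequence:
            groups = np.array([i.source_id for i in insts])
            splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                            random_state=fold_seed)
            split = splitter.split(np.zeros(len(y)), y > 0, groups)
        else:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                       random_state=fold_seed)
            split = splitter.split(np.zeros(len(y)), y > 0)
        for fold_i, (tr, te) in enumerate(split):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                skipped += 1
                continue
            scores = _score_fold(K_arrays, y, tr, te, C, mkl_kwargs)
            auc = roc_auc(scores, y[te])
            aucs.append(auc)
            rows.append({"repeat": rep, "fold": fold_i, "auc": auc})
    summary = " + ".join(c.summary() for c in kernel_configs) + f" C={C:g}"
    return CVReport(auc_values=aucs, config_summary=summary, seed=seed,
                    skipped_folds=skipped, fold_table=pd.DataFrame(rows))


def paired_ttest(report_a, report_b) -> tuple[float, float]:
    """Two-sample pooled-variance t-test between two sets of fold AUCs from
    matched protocols; returns (t, two-sided p)."""
    a = np.asarray(report_a.auc_values if isinstance(report_a, CVReport)
                   else report_a, dtype=float)
    b = np.asarray(report_b.auc_values if isinstance(report_b, CVReport)
                   else report_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("AUC lists must have equal length")
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else \
            (float(np.inf if a.mean() > b.mean() else -np.inf), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class GridSpec:
    """Search ranges for the SVM/kernel hyperparameters.

    Integer parameters (string order d, spectrum order d', gaps g) are
    enumerated exhaustively; continuous parameters (cost C, rbf width sigma)
    use two successive grids of decreasing step: a coarse log-spaced pass
    over the full range, then a fine linear pass around the coarse optimum.
    """

    c_range: tuple[float, float] = (0.1, 10.0)
    sigma_range: tuple[float, float] = (0.001, 1000.0)
    d_range: tuple[int, int] = (1, 6)
    dprime_range: tuple[int, int] = (1, 10)
    g_range: tuple[int, int] = (0, 3)
    coarse_points: int = 5
    fine_points: int = 5


@dataclass
class GridSearchResult:
    best_C: float
    best_configs: list[KernelConfig]
    report: CVReport
    trace: list[tuple[str, float, float]] = field(default_factory=list)


def _two_stage(lo, hi, coarse, fine, evaluate):
    """Coarse log-spaced then fine linear refinement; ties to smaller values."""
    cand = np.geomspace(lo, hi, coarse)
    best_v, best_auc = None, -np.inf
    for v in cand:
        auc = evaluate(float(v))
        if auc > best_auc:
            best_v, best_auc = float(v), auc
    i = int(np.argmin(np.abs(cand - best_v)))
    f_lo = cand[max(i - 1, 0)]
    f_hi = cand[min(i + 1, len(cand) - 1)]
    for v in np.linspace(f_lo, f_hi, fine):
        auc = evaluate(float(v))
        if auc > best_auc:
            best_v, best_auc = float(v), auc
    return best_v, best_auc


def grid_search(substrates, grid: GridSpec, base_configs: list[KernelConfig],
                seed: int = 0, C: float = 1.0, folds: int = 10,
                repeats: int = 2, neg_ratio: int = 10) -> GridSearchResult:
    """Hyperparameter search maximizing mean CV AUC.

    One pass over parameter blocks with the others frozen: first the cost C
    (two-stage refinement), then each kernel's own parameters — rbf width
    sigma (two-stage), string order d and spectrum (d', g) (exhaustive).
    Ties are broken toward smaller parameter values by strict improvement
    over candidates enumerated in increasing order.
    """
    configs = list(base_configs)
    trace: list[tuple[str, float, float]] = []

    def run(cfgs, C_val) -> float:
        rep = cross_validate(substrates, cfgs, C=C_val, folds=folds,
                             repeats=repeats, seed=seed, neg_ratio=neg_ratio)
        return rep.mean_auc

    best_C, auc = _two_stage(grid.c_range[0], grid.c_range[1],
                             grid.coarse_points, grid.fine_points,
                             lambda c: run(configs, c))
    trace.append(("C", best_C, auc))

    for ki, cfg in enumerate(configs):
        def with_cfg(new_cfg):
            trial = list(configs)
            trial[ki] = new_cfg
            return trial

        if cfg.kind == "rbf":
            best_sigma, auc = _two_stage(
                grid.sigma_range[0], grid.sigma_range[1],
                grid.coarse_points, grid.fine_points,
                lambda s: run(with_cfg(cfg.replace(sigma=s)), best_C))
            configs[ki] = cfg.replace(sigma=best_sigma)
            trace.append((f"kernel{ki}.sigma", best_sigma, auc))
        elif cfg.kind == "string":
            best_d, best_auc = None, -np.inf
            d_hi = min(grid.d_range[1], cfg.spec.width)
            for d in range(grid.d_range[0], d_hi + 1):
                a = run(with_cfg(cfg.replace(order_d=d)), best_C)
                if a > best_auc:
                    best_d, best_auc = d, a
            configs[ki] = cfg.replace(order_d=best_d)
            trace.append((f"kernel{ki}.d", best_d, best_auc))
        elif cfg.kind == "spectrum":
            best_pair, best_auc = None, -np.inf
            for dp in range(grid.dprime_range[0], grid.dprime_range[1] + 1):
                for g in range(grid.g_range[0], grid.g_range[1] + 1):
                    a = run(with_cfg(cfg.replace(order_dprime=dp, gaps_g=g)),
                            best_C)
                    if a > best_auc:
                        best_pair, best_auc = (dp, g), a
            configs[ki] = cfg.replace(order_dprime=best_pair[0],
                                      gaps_g=best_pair[1])
            trace.append((f"kernel{ki}.dprime_g", float(best_pair[0]), best_auc))

    report = cross_validate(substrates, configs, C=best_C, folds=folds,
                            repeats=repeats, seed=seed, neg_ratio=neg_ratio)
    return GridSearchResult(best_C=best_C, best_configs=configs,
                            report=report, trace=trace)


def window_sweep(substrates, kernel_config: KernelConfig, left_range,
                 right_range, seed: int = 0, C: float = 1.0, folds: int = 5,
                 repeats: int = 1, neg_ratio: int = 10) -> pd.DataFrame:
    """Mean CV AUC for every (left, right) window extension pair of a single
    kernel; rows are left extensions, columns right extensions."""
    table = pd.DataFrame(index=list(left_range), columns=list(right_range),
                         dtype=float)
    for left, right in itertools.product(left_range, right_range):
        cfg = kernel_config.replace(spec=WindowSpec(left, right))
        rep = cross_validate(substrates, [cfg], C=C, folds=folds,
                             repeats=repeats, seed=seed, neg_ratio=neg_ratio)
        table.loc[left, right] = rep.mean_auc
    table.index.name = "left"
    table.columns.name = "right"
    return table


def optimize_windows(substrates, kernel_configs: list[KernelConfig],
                     seed: int = 0, C: float = 1.0,
                     left_range=range(1, 21), right_range=range(1, 21),
                     folds: int = 5, repeats: int = 1, neg_ratio: int = 10,
                     tol: float = 1e-3, max_sweeps: int = 10):
    """Coordinate descent on per-kernel window extensions.

    Sweeps repeatedly over sub-kernels, grid-searching one kernel's
    (left, right) pair with all others frozen, until a full sweep improves
    the top mean AUC by less than ``tol`` or the sweep cap is reached.
    Returns (list of WindowSpec, final CVReport, objective per sweep).
    """
    configs = list(kernel_configs)

    def run(cfgs) -> float:
        return cross_validate(substrates, cfgs, C=C, folds=folds,
                              repeats=repeats, seed=seed,
                              neg_ratio=neg_ratio).mean_auc

    best = run(configs)
    objectives = [best]
    for _ in range(max_sweeps):
        improved = best
        for ki in range(len(configs)):
            best_spec = configs[ki].spec
            for left, right in itertools.product(left_range, right_range):
                spec = WindowSpec(left, right)
                if spec == configs[ki].spec:
                    continue
                trial = list(configs)
                trial[ki] = configs[ki].replace(spec=spec)
                auc = run(trial)
                if auc > improved:
                    improved, best_spec = auc, spec
            configs[ki] = configs[ki].replace(spec=best_spec)
        objectives.append(improved)
        if improved - best < tol:
            best = improved
            break
        best = improved
    report = cross_validate(substrates, configs, C=C, folds=folds,
                            repeats=repeats, seed=seed, neg_ratio=neg_ratio)
    return [c.spec for c in configs], report, objectives
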