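"""Dysbiosis statistics.

Covariate-adjusted per-feature linear models on transformed relative
abundance, Benjamini-Hochberg FDR control, Spearman co-occurrence
networks (retain FDR < 0.05 and |rho| > 0.1), and stratified tenfold
cross-validated random-forest classification AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from gutmaz.io_core import OtuTable, relative_abundance

__all__ = [
    "AssociationResult",
    "CorrelationNetwork",
    "ClassifierEval",
    "bh_fdr",
    "associate_features",
    "spearman_network",
    "rf_classify_auc",
]


@dataclass
class AssociationResult:
    feature: str
    coefficient: float
    std_error: float
    p_value: float
    q_value: float
    covariates: tuple[str, ...]


@dataclass
class NetworkEdge:
    genus_a: str
    genus_b: str
    rho: float
    q_value: float

    @property
    def sign(self) -> int:
        return 1 if self.rho > 0 else -1


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: list[NetworkEdge]

    @property
    def n_positive(self) -> int:
        return sum(1 for e in self.edges if e.sign > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e.sign < 0)

    def to_edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genus_a": e.genus_a,
                    "genus_b": e.genus_b,
                    "rho": e.rho,
                    "q": e.q_value,
                    "sign": e.sign,
                }
                for e in self.edges
            ]
        )


@dataclass
class ClassifierEval:
    feature_set: str
    fold_aucs: list[float]
    mean_auc: float
    n_trees: int
    fold_assignment: np.ndarray = field(default_factory=lambda: np.array([]))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min over j >= i of min(m * p_(j) / j, 1) for sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _arcsin_sqrt(x: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def associate_features(
    feature_table: OtuTable | pd.DataFrame,
    group: Sequence,
    covariates: pd.DataFrame | None = None,
    transform: str = "arcsin_sqrt",
) -> list[AssociationResult]:
    """Per-feature linear model of transformed abundance on group + covariates.

    The group coefficient (binary 0/1 or first-vs-rest categorical
    contrast), its standard error, two-sided p-value and BH q-value are
    reported per feature.
    """
    if isinstance(feature_table, OtuTable):
        rel = relative_abundance(feature_table)
        names = feature_table.otu_ids
    else:
        rel = feature_table.to_numpy(dtype=float)
        names = list(feature_table.columns)
    if transform == "arcsin_sqrt":
        y_all = _arcsin_sqrt(rel)
    elif transform == "log_tss":
        y_all = np.log10(rel + 1e-6)
    elif transform == "none":
        y_all = rel
    else:
        raise ValueError(f"unknown transform {transform!r}")

    group = np.asarray(group)
    uniq = np.unique(group)
    if len(uniq) < 2:
        raise ValueError("group must have at least 2 levels")
    g = (group == uniq[-1]).astype(float)  # last level vs rest

    n = len(g)
    cols = [np.ones(n), g]
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov_names = tuple(covariates.columns)
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype == object or str(v.dtype) == "category":
                for lev in sorted(set(v))[1:]:
                    cols.append((v == lev).to_numpy(dtype=float))
            else:
                cols.append(v.to_numpy(dtype=float))
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient ({rank} < {x.shape[1]}); "
            f"check for collinear covariates among {cov_names}"
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T
    dof = n - x.shape[1]
    results = []
    p_raw = []
    for j, name in enumerate(names):
        y = y_all[:, j]
        beta = hat @ y
        resid = y - x @ beta
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        if se == 0:
            tstat, p = 0.0, 1.0
        else:
            tstat = beta[1] / se
            p = float(2 * stats.t.sf(abs(tstat), dof))
        results.append((name, float(beta[1]), se, p))
        p_raw.append(p)
    q = bh_fdr(p_raw)
    return [
        AssociationResult(name, coef, se, p, float(qv), cov_names)
        for (name, coef, se, p), qv in zip(results, q)
    ]


def spearman_network(
    genus_table: OtuTable | pd.DataFrame,
    group_mask: Sequence[bool] | None = None,
    fdr: float = 0.05,
    min_abs_rho: float = 0.1,
) -> CorrelationNetwork:
    """Genus co-occurrence network.

    All genus pairs are tested by Spearman correlation within the
    selected group; BH correction is applied across pairs and only
    edges with ``q < fdr`` and ``|rho| > min_abs_rho`` are retained.
    """
    if isinstance(genus_table, OtuTable):
        rel = relative_abundance(genus_table)
        names = genus_table.otu_ids
    else:
        rel = genus_table.to_numpy(dtype=float)
        names = list(genus_table.columns)
    if group_mask is not None:
        mask = np.asarray(group_mask, dtype=bool)
        rel = rel[mask]
    if rel.shape[0] < 10:
        raise ValueError(
            f"need >= 10 samples in the group, got {rel.shape[0]}"
        )
    constant = rel.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "constant genera skipped in network: "
            f"{[names[j] for j in np.flatnonzero(constant)][:5]}"
        )
    pairs = []
    p_raw = []
    for i, j in combinations(range(len(names)), 2):
        if constant[i] or constant[j]:
            continue
        rho, p = stats.spearmanr(rel[:, i], rel[:, j])
        pairs.append((i, j, float(rho)))
        p_raw.append(float(p))
    q = bh_fdr(p_raw)
    edges = [
        NetworkEdge(names[i], names[j], rho, float(qv))
        for (i, j, rho), qv in zip(pairs, q)
        if qv < fdr and abs(rho) > min_abs_rho
    ]
    return CorrelationNetwork(list(names), edges)


def rf_classify_auc(
    feature_table: OtuTable | np.ndarray,
    labels: Sequence,
    n_folds: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
    feature_set: str = "features",
) -> ClassifierEval:
    """Stratified k-fold cross-validated random-forest AUC.

    Mean out-of-fold AUC over ``n_folds`` stratified folds with an
    ``n_trees``-tree forest; per-fold AUCs and the seeded fold
    assignment are retained.
    """
    if isinstance(feature_table, OtuTable):
        x = relative_abundance(feature_table)
    else:
        x = np.asarray(feature_table, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(uniq)}")
    y = (labels == uniq[-1]).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(len(y), dtype=int)
    aucs = []
    for k, (train, test) in enumerate(skf.split(x, y)):
        fold_assignment[test] = k
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + k, n_jobs=1
        )
        clf.fit(x[train], y[train])
        scores = clf.predict_proba(x[test])[:, 1]
        aucs.append(float(roc_auc_score(y[test], scores)))
    return ClassifierEval(
        feature_set, aucs, float(np.mean(aucs)), n_trees, fold_assignment
    )
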