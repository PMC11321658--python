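"""Bootstrap mediation analysis: treatment -> mediator -> outcome.

A genus panel is collapsed into a single mediator score by logistic
regression of the treatment on panel abundances.  Standardized path
coefficients are then estimated by product-of-coefficients:

- ``a``: mediator ~ treatment + covariates (OLS);
- ``b``, ``c'``: outcome ~ mediator + treatment + covariates, with a
  linear-probability model by default (so total = c' + a*b holds as an
  exact OLS identity) or a logistic model whose coefficients are on the
  log-odds scale;
- indirect effect = ``a * b`` with a percentile bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from gutmaz.io_core import OtuTable, relative_abundance

__all__ = [
    "MediationModelSpec",
    "MediationResult",
    "build_mediator_score",
    "fit_mediation",
]


@dataclass
class MediationModelSpec:
    treatment: str = "treatment"
    outcome: str = "outcome"
    mediator: str = "mediator"
    covariates: tuple[str, ...] = ("age", "bmi", "sex", "uccs", "district")
    n_boot: int = 5000
    seed: int = 0
    outcome_model: str = "linear"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.outcome_model not in ("linear", "logistic"):
            raise ValueError(f"unknown outcome_model {self.outcome_model!r}")


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    ci: dict[str, tuple[float, float]]
    p_indirect: float
    n_boot: int
    outcome_model: str
    n_redrawn: int = 0
    mediator_auc: float | None = None


def build_mediator_score(
    genus_table: OtuTable | pd.DataFrame,
    treatment_labels: Sequence,
    panel: Sequence[str],
    ridge_c: float = 1e6,
) -> tuple[np.ndarray, float]:
    """Logistic panel score: P(treatment | panel abundances).

    Returns ``(scores, auc)``.  Near-perfect separation is handled by
    refitting with a stronger ridge penalty (warning emitted); scores
    stay strictly inside (0, 1).
    """
    if isinstance(genus_table, OtuTable):
        rel = relative_abundance(genus_table)
        names = genus_table.otu_ids
    else:
        rel = genus_table.to_numpy(dtype=float)
        names = list(genus_table.columns)
    idx = {g: j for j, g in enumerate(names)}
    missing = [g for g in panel if g not in idx]
    if missing:
        raise KeyError(f"panel genera absent from table: {missing[:5]}")
    x = rel[:, [idx[g] for g in panel]]
    t = np.asarray(treatment_labels)
    uniq = np.unique(t)
    if len(uniq) != 2:
        raise ValueError("treatment must have exactly 2 classes")
    y = (t == uniq[-1]).astype(int)
    # scale features so the penalty acts comparably across genera
    sd = x.std(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=ridge_c, max_iter=2000).fit(xs, y)
        separated = roc_auc_score(y, clf.predict_proba(xs)[:, 1]) == 1.0
    if separated:
        warnings.warn(
            "perfect separation detected; refitting with a ridge penalty "
            "(C=1.0)",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = LogisticRegression(C=1.0, max_iter=2000).fit(xs, y)
    scores = clf.predict_proba(xs)[:, 1]
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    auc = float(roc_auc_score(y, scores))
    return scores, auc


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(x, y, rcond=None)[0]


def _logit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Newton-IRLS logistic fit with a tiny ridge for stability."""
    beta = np.zeros(x.shape[1])
    for _ in range(50):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        xtw = x.T * w
        h = xtw @ x + 1e-8 * np.eye(x.shape[1])
        g = x.T @ (y - p) - 1e-8 * beta
        step = np.linalg.solve(h, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def _paths(
    t: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    outcome_model: str,
) -> tuple[float, float, float, float]:
    """(a, b, c', total) on one dataset; inputs already standardized."""
    n = len(t)
    ones = np.ones((n, 1))
    x_med = np.column_stack([ones, t, c])
    a = float(_ols(x_med, m)[1])
    x_out = np.column_stack([ones, m, t, c])
    if outcome_model == "linear":
        beta = _ols(x_out, y)
        b, c_prime = float(beta[1]), float(beta[2])
        total = float(_ols(np.column_stack([ones, t, c]), y)[1])
    else:
        beta = _logit(x_out, y)
        b, c_prime = float(beta[1]), float(beta[2])
        total = c_prime + a * b
    return a, b, c_prime, total


def fit_mediation(
    spec: MediationModelSpec,
    data: pd.DataFrame,
) -> MediationResult:
    """Estimate standardized mediation paths with a percentile bootstrap.

    ``data`` must contain the spec's treatment (0/1), mediator, outcome
    (0/1) and covariate columns.  The mediator, treatment and continuous
    covariates are standardized on the full sample; bootstrap resamples
    rows with replacement, redrawing (counted, capped) any resample that
    loses a treatment or outcome class.  The two-sided p-value for the
    indirect effect is the fraction of bootstrap estimates crossing 0.
    """
    if len(data) < 50:
        raise ValueError(f"need n >= 50 samples, got {len(data)}")
    for col in (spec.treatment, spec.outcome, spec.mediator, *spec.covariates):
        if col not in data.columns:
            raise KeyError(f"column {col!r} missing from data")
    t_raw = data[spec.treatment].to_numpy(dtype=float)
    if set(np.unique(t_raw)) - {0.0, 1.0}:
        raise ValueError("treatment must be coded 0/1")
    y = data[spec.outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    m_raw = data[spec.mediator].to_numpy(dtype=float)
    if m_raw.std() == 0:
        raise ValueError("mediator is constant")

    def z(x: np.ndarray) -> np.ndarray:
        s = x.std()
        return (x - x.mean()) / s if s > 0 else x - x.mean()

    t = z(t_raw)
    m = z(m_raw)
    cov_cols = []
    for cname in spec.covariates:
        v = data[cname]
        if v.dtype == object or str(v.dtype) == "category":
            for lev in sorted(set(v))[1:]:
                cov_cols.append(z((v == lev).to_numpy(dtype=float)))
        else:
            cov_cols.append(z(v.to_numpy(dtype=float)))
    c = np.column_stack(cov_cols) if cov_cols else np.empty((len(t), 0))

    a, b, c_prime, total = _paths(t, m, y, c, spec.outcome_model)
    indirect = a * b

    rng = np.random.default_rng(spec.seed)
    n = len(t)
    boots = np.empty((spec.n_boot, 4))
    n_redrawn = 0
    max_redraws = 10 * spec.n_boot
    for i in range(spec.n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(t_raw[idx])) == 2 and len(np.unique(y[idx])) == 2:
                break
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    "too many degenerate bootstrap resamples; "
                    "check class balance"
                )
        ab, bb, cb, _tot = _paths(t[idx], m[idx], y[idx], c[idx], spec.outcome_model)
        boots[i] = (ab, bb, cb, ab * bb)

    def ci(col: int) -> tuple[float, float]:
        lo, hi = np.percentile(boots[:, col], [2.5, 97.5])
        return float(lo), float(hi)

    ind_boot = boots[:, 3]
    if indirect == 0:
        p_ind = 1.0
    else:
        crossing = float(np.mean(np.sign(ind_boot) != np.sign(indirect)))
        p_ind = min(2.0 * max(crossing, 1.0 / spec.n_boot), 1.0)
    cis = {
        "a": ci(0),
        "b": ci(1),
        "c_prime": ci(2),
        "indirect": ci(3),
    }
    return MediationResult(
        a=a,
        b=b,
        c_prime=c_prime,
        indirect=indirect,
        total=total,
        ci=cis,
        p_indirect=p_ind,
        n_boot=spec.n_boot,
        outcome_model=spec.outcome_model,
        n_redrawn=n_redrawn,
    )
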