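"""LASSO refinement of the candidate union into a scored signature.

The candidate oxylipins pooled over both cohorts are refined by a pure
L1-penalized conditional logistic regression on the discovery cohort,
which drops redundant analytes.  The resulting coefficient vector B
defines the OxyScore

    OxyScore = exp(B . X) / (1 + exp(B . X)),

a per-subject logistic index of MetS case status computed on
standardized log concentrations.  Because the conditional model carries
no intercept, the OxyScore ranks subjects rather than giving a
calibrated probability; classification uses the 0.5 cut by default.

Performance is measured by pooled out-of-fold AUC under k-fold
cross-validation over pairs (pairs are never split), with a DeLong
confidence interval and the cross-validated error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from .clogit import ClogitFit, PenaltySpec, fit_clogit, make_penalty_grid, tune_penalty
from .containers import MatchedStudy
from .preprocess import StandardizationParams


@dataclass
class FittedSignature:
    """Post-LASSO support and coefficients (standardized scale)."""

    analytes: list[str]
    coefficients: pd.Series
    penalty: PenaltySpec
    standardization: Optional[StandardizationParams] = None
    dropped: list[str] = field(default_factory=list)
    fit: Optional[ClogitFit] = field(default=None, repr=False)


@dataclass
class PerformanceReport:
    """Out-of-fold scores and the classification metrics built on them."""

    scores: pd.Series
    labels: pd.Series
    auc: float
    ci_low: float
    ci_high: float
    error_rate: float
    confusion: dict[str, int]
    k: int
    seed: int

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "error_rate": self.error_rate,
            **self.confusion,
            "k": self.k,
        }


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both cases and controls")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def delong_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """DeLong variance for a single AUC; returns (auc, lo, hi) clipped to [0,1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # placement values via midranks
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(neg < pos_i)
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    q = norm.ppf(1 - alpha / 2)
    return auc, max(0.0, auc - q * se), min(1.0, auc + q * se)


def fit_signature(
    discovery: MatchedStudy,
    candidate_union: Sequence[str],
    extra_covariates: Optional[pd.DataFrame] = None,
    penalty: Optional[PenaltySpec] = None,
    seed: int = 0,
    cv_folds: int = 5,
    standardization: Optional[StandardizationParams] = None,
) -> FittedSignature:
    """LASSO-penalized conditional logit restricted to the candidate union.

    ``extra_covariates`` (e.g. clinical criteria columns, standardized,
    indexed by subject id) are appended to the design for the adjusted
    variants.  When ``penalty`` is None the L1 weight is tuned by
    cross-validation over pairs (lambda2 = 0 throughout: pure LASSO).
    """
    union = list(candidate_union)
    if not union:
        raise ValueError("candidate union is empty")
    missing = [a for a in union if a not in discovery.matrix.analytes]
    if missing:
        raise ValueError(f"candidates absent from the matrix: {missing}")
    z, cols = discovery.design(union)
    if extra_covariates is not None:
        extra = extra_covariates.loc[discovery.case_ids].to_numpy(float) - (
            extra_covariates.loc[discovery.control_ids].to_numpy(float)
        )
        z = np.hstack([z, extra])
        cols = cols + list(extra_covariates.columns)
    if penalty is None:
        grid = [
            PenaltySpec(l1, 0.0)
            for l1 in sorted(
                {s.lambda1 for s in make_penalty_grid(z, n_lambda1=8, lambda1_min_ratio=0.02)},
                reverse=True,
            )
        ]
        penalty, _ = tune_penalty(z, grid, folds=min(cv_folds, z.shape[0]), seed=seed)
    fit = fit_clogit(z, penalty, analytes=cols, tol=1e-8)
    _merge_collinear(fit, z, cols, n_analytes=len(union))
    support = fit.support
    if not support:
        warnings.warn("LASSO support is empty: degenerate signature", stacklevel=2)
    dropped = [a for a in cols if a not in support]
    return FittedSignature(
        analytes=support,
        coefficients=fit.coefficients[support],
        penalty=penalty,
        standardization=standardization,
        dropped=dropped,
        fit=fit,
    )


def _merge_collinear(fit, z: np.ndarray, cols: list[str], n_analytes: int) -> None:
    """Resolve exact collinearity in the difference design deterministically.

    The L1 penalty is indifferent to how weight is split across exactly
    collinear (equal or negated) columns, and the proximal solver splits
    it evenly.  The fitted linear predictor is unchanged by pooling the
    split onto one representative, so the support stays minimal: an
    appended covariate wins over an analyte (a clinical criterion that
    duplicates an analyte's information displaces it), otherwise the
    later column folds into the earlier one.
    """
    coefs = fit.coefficients
    active = [j for j, c in enumerate(cols) if coefs.iloc[j] != 0.0]
    consumed: set[int] = set()
    for a_pos, j in enumerate(active):
        if j in consumed:
            continue
        for i in active[a_pos + 1 :]:
            if i in consumed:
                continue
            sign = 0
            if np.allclose(z[:, j], z[:, i], atol=1e-12):
                sign = 1
            elif np.allclose(z[:, j], -z[:, i], atol=1e-12):
                sign = -1
            if sign:
                keep, drop, flip = (i, j, sign) if i >= n_analytes else (j, i, sign)
                coefs.iloc[keep] += flip * coefs.iloc[drop]
                coefs.iloc[drop] = 0.0
                consumed.add(drop)
                if drop == j:
                    break


def oxyscore(signature: FittedSignature, x) -> pd.Series | float:
    """Logistic score exp(B.X)/(1+exp(B.X)) on standardized concentrations.

    ``x`` is a Series (one subject) or DataFrame (subjects x analytes)
    already on the signature's standardized scale.
    """
    b = signature.coefficients
    if isinstance(x, pd.DataFrame):
        missing = [a for a in b.index if a not in x.columns]
        if missing:
            raise ValueError(f"analytes missing from input: {missing}")
        lin = x[b.index].to_numpy(float) @ b.to_numpy()
        return pd.Series(expit(lin), index=x.index, name="oxyscore")
    missing = [a for a in b.index if a not in x.index]
    if missing:
        raise ValueError(f"analytes missing from input: {missing}")
    return float(expit(float(x[b.index] @ b)))


def _confusion(scores: pd.Series, labels: pd.Series, cut: float) -> dict[str, int]:
    pred = scores >= cut
    return {
        "tp": int((pred & labels).sum()),
        "fp": int((pred & ~labels).sum()),
        "tn": int((~pred & ~labels).sum()),
        "fn": int((~pred & labels).sum()),
    }


def evaluate(
    signature: FittedSignature,
    study: MatchedStudy,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    retune: bool = True,
) -> PerformanceReport:
    """k-fold cross-validated performance of the signature on a study.

    Folds partition pairs; within each fold the model is refit on the
    training pairs over the signature's analytes (penalty re-tuned with
    the same policy when ``retune``), and the held-out subjects are
    scored.  AUC is computed on the pooled out-of-fold scores with a
    DeLong interval; the error rate uses the ``threshold`` cut.
    """
    analytes = signature.analytes
    if not analytes:
        raise ValueError("cannot evaluate an empty signature")
    n = study.n_pairs
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} pairs")
    z, cols = study.design(analytes)
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(n) % k
    values = study.matrix.values
    labels = study.labels()
    scores = pd.Series(np.nan, index=values.index, name="oxyscore")
    for f in range(k):
        train = z[fold_of != f]
        if retune:
            grid = [
                PenaltySpec(l1, 0.0)
                for l1 in sorted(
                    {s.lambda1 for s in make_penalty_grid(train, n_lambda1=6, lambda1_min_ratio=0.02)},
                    reverse=True,
                )
            ]
            pen, _ = tune_penalty(train, grid, folds=min(5, train.shape[0]), seed=seed + f)
        else:
            pen = signature.penalty
        fit = fit_clogit(train, pen, analytes=cols, tol=1e-7)
        beta = fit.coefficients.to_numpy()
        held_pairs = np.flatnonzero(fold_of == f)
        held_ids = [study.case_ids[i] for i in held_pairs] + [
            study.control_ids[i] for i in held_pairs
        ]
        lin = values.loc[held_ids, cols].to_numpy(float) @ beta
        scores.loc[held_ids] = expit(lin)
    auc, lo, hi = delong_ci(scores.to_numpy(), labels.to_numpy())
    conf = _confusion(scores, labels, threshold)
    err = (conf["fp"] + conf["fn"]) / len(scores)
    return PerformanceReport(
        scores=scores, labels=labels, auc=auc, ci_low=lo, ci_high=hi,
        error_rate=float(err), confusion=conf, k=k, seed=seed,
    )


def transfer_evaluate(
    signature: FittedSignature,
    study_b: MatchedStudy,
    threshold: float = 0.5,
) -> PerformanceReport:
    """Apparent performance of a frozen signature on an external study.

    No coefficient is refit; ``study_b``'s matrix is expected on its own
    internal standardized scale (apply discovery parameters upstream via
    :func:`oxysig.preprocess.log_standardize` to use the
    discovery-parameter mode instead).
    """
    values = study_b.matrix.values
    scores = oxyscore(signature, values)
    labels = study_b.labels()
    auc, lo, hi = delong_ci(scores.to_numpy(), labels.to_numpy())
    conf = _confusion(scores, labels, threshold)
    err = (conf["fp"] + conf["fn"]) / len(scores)
    return PerformanceReport(
        scores=scores, labels=labels, auc=auc, ci_low=lo, ci_high=hi,
        error_rate=float(err), confusion=conf, k=0, seed=0,
    )


def adjustment_report(
    discovery: MatchedStudy,
    candidate_union: Sequence[str],
    criteria_columns: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Which oxylipins drop out when a clinical criterion joins the model.

    For each criterion column (taken from the subject table and
    standardized), the LASSO signature is refit with that criterion
    appended; the report lists the analytes present in the unadjusted
    support but absent from the adjusted one.
    """
    base = fit_signature(discovery, candidate_union, seed=seed)
    base_support = set(base.analytes)
    rows = []
    for crit in criteria_columns:
        col = discovery.subjects[crit].astype(float)
        col = (col - col.mean()) / col.std(ddof=1)
        adjusted = fit_signature(
            discovery,
            candidate_union,
            extra_covariates=col.to_frame(name=f"crit_{crit}"),
            seed=seed,
        )
        excluded = sorted(base_support - set(adjusted.analytes))
        rows.append(
            dict(
                criterion=crit,
                criterion_selected=f"crit_{crit}" in adjusted.analytes,
                excluded_oxylipins="; ".join(excluded),
                n_excluded=len(excluded),
            )
        )
    return pd.DataFrame(rows).set_index("criterion") if rows else pd.DataFrame(
        columns=["criterion_selected", "excluded_oxylipins", "n_excluded"]
    )
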