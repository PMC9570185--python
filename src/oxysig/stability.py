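"""Bootstrap-enhanced elastic-net selection of candidate oxylipins.

Penalized selection is unstable because the penalty itself is chosen by
cross-validation; repeating the whole tune-and-fit process on bootstrap
resamples of matched pairs and keeping only analytes selected in at
least a threshold fraction of resamples (default 80% of 350) yields a
reproducible candidate set.  An analytical-robustness filter then sets
aside candidates with known storage/interlaboratory problems or heavy
imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clogit import PenaltySpec, _mfista, conditional_loglik, make_penalty_grid
from .containers import MatchedStudy


@dataclass
class StabilityConfig:
    """Knobs of the bootstrap selection loop.

    ``n_boot`` bootstrap resamples of pairs (size = original pair
    count); candidates are analytes selected in >= ``threshold`` of the
    successful resamples.  The elastic-net penalty is re-tuned inside
    every resample by ``cv_folds``-fold cross-validation over a coarse
    data-driven grid (``n_lambda1`` L1 values crossed with
    ``lambda2_values``), because the tuning step is precisely where the
    instability arises.
    """

    n_boot: int = 350
    threshold: float = 0.80
    cv_folds: int = 3
    n_lambda1: int = 5
    lambda1_min_ratio: float = 0.08
    lambda2_values: tuple[float, ...] = (0.5, 4.0)
    max_imputed_fraction: float = 0.5
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 4000

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class SelectionResult:
    """Per-analyte bootstrap selection frequencies and candidate flags."""

    frequencies: pd.Series
    candidates: list[str]
    n_boot: int
    n_failed: int
    threshold: float
    penalties: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    robustness_audit: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "frequency": self.frequencies.sort_values(ascending=False),
            }
        )
        out["candidate"] = out.index.isin(self.candidates)
        return out


def _tune_and_fit(
    z: np.ndarray, config: StabilityConfig, rng, groups: Optional[np.ndarray] = None
) -> tuple[np.ndarray, PenaltySpec, bool]:
    """Re-tune the elastic-net penalty on ``z`` and fit at the winner.

    ``groups`` labels rows that are resampled copies of the same
    original pair; all copies share a CV fold, otherwise duplicates
    leak between train and test and the tuning under-penalizes.
    """
    grid = make_penalty_grid(
        z,
        n_lambda1=config.n_lambda1,
        lambda1_min_ratio=config.lambda1_min_ratio,
        lambda2_values=config.lambda2_values,
    )
    n = z.shape[0]
    if groups is None:
        groups = np.arange(n)
    unique = np.unique(groups)
    folds = min(config.cv_folds, len(unique))
    group_fold = dict(zip(unique[rng.permutation(len(unique))], np.arange(len(unique)) % folds))
    fold_of = np.array([group_fold[g] for g in groups])
    by_l2: dict[float, list[PenaltySpec]] = {}
    for spec in grid:
        by_l2.setdefault(spec.lambda2, []).append(spec)
    for specs in by_l2.values():
        specs.sort(key=lambda s: -s.lambda1)
    scores: dict[PenaltySpec, float] = {spec: 0.0 for spec in grid}
    for f in range(folds):
        train = np.ascontiguousarray(z[fold_of != f])
        test = z[fold_of == f]
        for specs in by_l2.values():
            beta = np.zeros(z.shape[1])
            for spec in specs:
                beta, _, _, _ = _mfista(
                    train, spec.lambda1, spec.lambda2, beta.copy(),
                    config.tol, config.max_iter,
                )
                scores[spec] += conditional_loglik(test, beta)
    best = max(grid, key=lambda s: (round(scores[s], 10), s.lambda1, s.lambda2))
    beta, _, _, converged = _mfista(
        np.ascontiguousarray(z), best.lambda1, best.lambda2,
        np.zeros(z.shape[1]), config.tol, config.max_iter,
    )
    return beta, best, bool(converged)


def bootstrap_select(
    study: MatchedStudy,
    config: StabilityConfig,
    analytes: Optional[Sequence[str]] = None,
) -> SelectionResult:
    """Selection frequencies over bootstrap resamples of matched pairs.

    The resampling unit is the pair (resampling individuals would break
    the conditional likelihood).  Replicates whose final fit fails to
    converge are excluded from the denominator and counted.
    """
    z, cols = (
        study.design(analytes) if isinstance(study, MatchedStudy) else (np.asarray(study), list(analytes))
    )
    n = z.shape[0]
    rng = np.random.default_rng(config.seed)
    selected = np.zeros(len(cols))
    n_failed = 0
    penalty_rows = []
    for b in range(config.n_boot):
        idx = rng.integers(0, n, size=n)
        beta, best, converged = _tune_and_fit(z[idx], config, rng, groups=idx)
        if not converged:
            n_failed += 1
            penalty_rows.append((b, best.lambda1, best.lambda2, False))
            continue
        selected += np.abs(beta) > 1e-12
        penalty_rows.append((b, best.lambda1, best.lambda2, True))
    n_ok = config.n_boot - n_failed
    if n_ok == 0:
        raise RuntimeError("every bootstrap replicate failed to converge")
    if n_failed:
        warnings.warn(f"{n_failed} bootstrap replicates failed to converge", stacklevel=2)
    freq = pd.Series(selected / n_ok, index=cols, name="frequency")
    candidates = list(freq.index[freq >= config.threshold])
    return SelectionResult(
        frequencies=freq,
        candidates=candidates,
        n_boot=n_ok,
        n_failed=n_failed,
        threshold=config.threshold,
        penalties=pd.DataFrame(
            penalty_rows, columns=["bootstrap", "lambda1", "lambda2", "converged"]
        ),
    )


def robustness_filter(
    candidates: Sequence[str],
    metadata: Optional[pd.DataFrame],
    imputation_report: Optional[pd.DataFrame],
    config: StabilityConfig = StabilityConfig(),
) -> tuple[list[str], pd.DataFrame]:
    """Set aside candidates with low analytical robustness.

    Three hard flags per analyte: storage instability
    (``storage_stable`` False), interlaboratory variability
    (``interlab_ok`` False) and imputed fraction above
    ``max_imputed_fraction``.  The default rule is pass-unless-flagged;
    analytes with no metadata pass with a warning (never a silent
    exclusion).
    """
    rows = []
    kept = []
    for analyte in candidates:
        reasons = []
        meta_row = None
        if metadata is not None and analyte in metadata.index:
            meta_row = metadata.loc[analyte]
        if meta_row is None or (
            "storage_stable" not in meta_row.index and "interlab_ok" not in meta_row.index
        ):
            warnings.warn(
                f"no robustness metadata for {analyte!r}; treated as passing",
                stacklevel=2,
            )
        else:
            if "storage_stable" in meta_row.index and meta_row["storage_stable"] is not np.nan:
                if not _truthy(meta_row["storage_stable"], default=True):
                    reasons.append("storage stability")
            if "interlab_ok" in meta_row.index:
                if not _truthy(meta_row["interlab_ok"], default=True):
                    reasons.append("interlaboratory variability")
        frac = 0.0
        if imputation_report is not None and analyte in imputation_report.index:
            frac = float(imputation_report.loc[analyte, "fraction_imputed"])
        if frac > config.max_imputed_fraction:
            reasons.append(
                f"imputed fraction {frac:.2f} > {config.max_imputed_fraction:.2f}"
            )
        if not reasons:
            kept.append(analyte)
        rows.append(
            dict(
                analyte=analyte,
                retained=not reasons,
                reasons="; ".join(reasons),
                fraction_imputed=frac,
            )
        )
    audit = pd.DataFrame(rows).set_index("analyte") if rows else pd.DataFrame(
        columns=["retained", "reasons", "fraction_imputed"]
    )
    return kept, audit


def _truthy(value, default: bool) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return default
    return bool(value)


def run_dual_cohort_selection(
    study_a: MatchedStudy,
    study_b: MatchedStudy,
    config: StabilityConfig,
    analytes: Optional[Sequence[str]] = None,
) -> tuple[SelectionResult, SelectionResult]:
    """Two fully independent selections (one per cohort) on a shared panel."""
    res_a = bootstrap_select(study_a, config, analytes)
    res_b = bootstrap_select(study_b, config, analytes)
    return res_a, res_b
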