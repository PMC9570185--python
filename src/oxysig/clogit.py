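"""Penalized conditional logistic regression for 1:1 matched pairs.

For a matched pair with covariate vectors ``x_case`` and ``x_control``,
the conditional likelihood contribution is

    exp(b . x_case) / (exp(b . x_case) + exp(b . x_control))
      = sigmoid(b . (x_case - x_control)),

so the model reduces to an intercept-free logistic regression on
within-pair differences with unit outcome.  The fitter maximizes

    sum_pairs log sigmoid(b . z_i)  -  lam1 * ||b||_1  -  lam2 * ||b||_2^2

by monotone FISTA (proximal gradient with backtracking and a
non-increase safeguard), which handles the smooth-plus-L1 composite
exactly and returns hard zeros for the L1 part.  The hot loop is
JIT-compiled with numba when available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import MatchedStudy

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty weights: ``lambda1`` (L1), ``lambda2`` (L2)."""

    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be nonnegative")


@dataclass
class ClogitFit:
    """Result of a penalized conditional-logit fit (no intercept)."""

    coefficients: pd.Series
    converged: bool
    objective: float
    n_iter: int
    penalty: PenaltySpec
    objective_trace: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def support(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0.0])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def conditional_loglik(z: np.ndarray, beta: np.ndarray) -> float:
    """Sum over pairs of log sigmoid(beta . z_i)."""
    return float(-np.sum(_softplus(-(z @ beta))))


@njit(cache=False)
def _mfista(z, lam1, lam2, beta0, tol, max_iter):  # pragma: no cover - jitted
    n, p = z.shape
    # Lipschitz estimate for the logistic part: 0.25 * sigma_max(Z)^2
    v = np.ones(p) / np.sqrt(p)
    smax2 = 1.0
    for _ in range(10):
        w = z.T @ (z @ v)
        smax2 = np.sqrt(np.sum(w * w))
        if smax2 == 0.0:
            break
        v = w / smax2
    lip = 0.25 * smax2 + 2.0 * lam2 + 1e-12

    def smooth(b):
        u = z @ b
        s = 0.0
        for i in range(n):
            x = -u[i]
            if x > 0.0:
                s += x + np.log1p(np.exp(-x))
            else:
                s += np.log1p(np.exp(x))
        return s + lam2 * np.sum(b * b)

    x = beta0.copy()
    y = x.copy()
    fx = smooth(x) + lam1 * np.sum(np.abs(x))
    t = 1.0
    trace = np.empty(max_iter)
    n_iter = 0
    converged = False
    for k in range(max_iter):
        u = z @ y
        sig = 1.0 / (1.0 + np.exp(np.minimum(u, 35.0)))
        grad = -(z.T @ sig) + 2.0 * lam2 * y
        fy = smooth(y)
        # backtracking on the step length
        while True:
            step = y - grad / lip
            znew = np.sign(step) * np.maximum(np.abs(step) - lam1 / lip, 0.0)
            d = znew - y
            fz = smooth(znew)
            quad = fy + np.sum(grad * d) + 0.5 * lip * np.sum(d * d)
            if fz <= quad + 1e-12 * (1.0 + np.abs(fy)):
                break
            lip *= 2.0
        obj_z = fz + lam1 * np.sum(np.abs(znew))
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        if obj_z <= fx:
            x_new = znew
            fx_new = obj_z
        else:  # safeguard keeps the objective monotone
            x_new = x
            fx_new = fx
        y = x_new + (t / t_next) * (znew - x_new) + ((t - 1.0) / t_next) * (x_new - x)
        rel = np.abs(fx - obj_z) / max(1.0, np.abs(fx))
        x = x_new
        fx = fx_new
        t = t_next
        lip *= 0.97
        trace[k] = fx
        n_iter = k + 1
        if rel < tol and k > 0:
            converged = True
            break
    return x, trace[:n_iter], n_iter, converged


def _as_design(study, analytes: Optional[Sequence[str]]):
    if isinstance(study, MatchedStudy):
        return study.design(analytes)
    z = np.asarray(study, dtype=float)
    if z.ndim != 2:
        raise ValueError("difference design must be 2-D (pairs x analytes)")
    cols = list(analytes) if analytes is not None else [f"x{j}" for j in range(z.shape[1])]
    return z, cols


def fit_clogit(
    study,
    penalty: PenaltySpec = PenaltySpec(),
    analytes: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    beta0: Optional[np.ndarray] = None,
    keep_trace: bool = False,
) -> ClogitFit:
    """Fit the penalized conditional logit on a study or a difference matrix.

    ``study`` may be a :class:`MatchedStudy` (standardized matrix expected)
    or a ready-made pair-difference matrix.  Non-convergence at
    ``max_iter`` is flagged on the returned fit, never silent.
    """
    z, cols = _as_design(study, analytes)
    if z.shape[0] == 0:
        raise ValueError("no pairs to fit")
    if not np.any(z != 0.0):
        raise ValueError("all within-pair differences are zero")
    constant = ~np.any(z != 0.0, axis=0)
    if constant.any() and penalty.lambda1 == 0.0 and penalty.lambda2 == 0.0:
        names = [cols[j] for j in np.flatnonzero(constant)]
        warnings.warn(
            f"columns identical within every pair get coefficient 0: {names}",
            stacklevel=2,
        )
    b0 = np.zeros(z.shape[1]) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    beta, trace, n_iter, converged = _mfista(
        np.ascontiguousarray(z), float(penalty.lambda1), float(penalty.lambda2), b0,
        float(tol), int(max_iter),
    )
    if penalty.lambda1 == 0.0 and converged:
        # the objective is smooth: polish to gradient-level accuracy
        beta = _newton_polish(z, beta, penalty.lambda2)
    if not converged:
        warnings.warn(
            f"conditional-logit fit did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    beta = np.where(np.abs(beta) < 1e-12, 0.0, beta)
    obj = -conditional_loglik(z, beta) + penalty.lambda1 * np.abs(beta).sum() + (
        penalty.lambda2 * float(beta @ beta)
    )
    return ClogitFit(
        coefficients=pd.Series(beta, index=cols, name="coefficient"),
        converged=bool(converged),
        objective=float(obj),
        n_iter=int(n_iter),
        penalty=penalty,
        objective_trace=np.asarray(trace) if keep_trace else None,
    )


def _newton_polish(
    z: np.ndarray, beta: np.ndarray, lam2: float, tol: float = 1e-11, max_iter: int = 50
) -> np.ndarray:
    """Damped Newton refinement of the smooth objective NLL + lam2*||b||^2."""
    p = z.shape[1]
    beta = beta.copy()
    for _ in range(max_iter):
        u = z @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(u, -35, 35)))
        grad = -(z.T @ (1.0 - mu)) + 2.0 * lam2 * beta
        if np.max(np.abs(grad)) < tol:
            break
        w = mu * (1.0 - mu)
        hess = (z * w[:, None]).T @ z + 2.0 * lam2 * np.eye(p) + 1e-12 * np.eye(p)
        step = np.linalg.solve(hess, grad)
        obj0 = -conditional_loglik(z, beta) + lam2 * float(beta @ beta)
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            if -conditional_loglik(z, cand) + lam2 * float(cand @ cand) <= obj0 + 1e-12:
                break
            scale *= 0.5
        beta = beta - scale * step
    return beta


def newton_refit(z: np.ndarray, tol: float = 1e-10, max_iter: int = 100):
    """Unpenalized Newton-Raphson on the pair-difference likelihood.

    Used for post-selection Wald intervals on the refit support.  Returns
    (beta, covariance).  A tiny ridge stabilizes near-singular Hessians.
    """
    n, p = z.shape
    beta = np.zeros(p)
    cov = np.eye(p)
    for _ in range(max_iter):
        u = z @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(u, -35, 35)))
        grad = z.T @ (1.0 - mu)
        w = mu * (1.0 - mu)
        hess = (z * w[:, None]).T @ z + 1e-10 * np.eye(p)
        cov = np.linalg.inv(hess)
        step = cov @ grad
        # halve the step until the likelihood does not decrease
        ll0 = conditional_loglik(z, beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if conditional_loglik(z, cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
    return beta, cov


def odds_ratios(
    fit: ClogitFit,
    study=None,
    analytes: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-analyte odds ratios (per 1-SD increment) with Wald CIs.

    OR = exp(coefficient) on the standardized scale.  Confidence
    intervals come from an unpenalized conditional-logit refit on the
    selected support (post-selection normal approximation); they require
    the study data and are NaN otherwise or off-support.
    """
    from scipy.stats import norm

    coefs = fit.coefficients
    out = pd.DataFrame(
        {
            "coefficient": coefs,
            "or": np.exp(coefs),
            "ci_low": np.nan,
            "ci_high": np.nan,
            "selected": coefs != 0.0,
        }
    )
    support = fit.support
    if study is not None and support:
        z, cols = _as_design(study, analytes)
        idx = [cols.index(a) for a in support]
        beta, cov = newton_refit(z[:, idx])
        se = np.sqrt(np.diag(cov))
        q = norm.ppf(1 - alpha / 2)
        out.loc[support, "ci_low"] = np.exp(beta - q * se)
        out.loc[support, "ci_high"] = np.exp(beta + q * se)
        out.loc[support, "or_refit"] = np.exp(beta)
    return out


def make_penalty_grid(
    z: np.ndarray,
    n_lambda1: int = 5,
    lambda1_min_ratio: float = 0.08,
    lambda2_values: Sequence[float] = (0.5, 4.0),
) -> list[PenaltySpec]:
    """Data-driven elastic-net grid.

    ``lambda1_max`` is the smallest L1 weight that zeroes every
    coefficient at ``beta = 0`` (half the max absolute column sum of the
    difference matrix); the L1 grid runs geometrically from
    ``lambda1_max`` itself down to ``lambda1_min_ratio * lambda1_max``,
    crossed with ``lambda2_values``.  Starting at ``lambda1_max`` keeps
    the null model on the grid, so that cross-validation can prefer an
    empty fit on noise.
    """
    lam_max = 0.5 * np.max(np.abs(z.sum(axis=0)))
    if lam_max <= 0:
        lam_max = 1.0
    lam1s = np.geomspace(lam_max, lam_max * lambda1_min_ratio, n_lambda1)
    return [PenaltySpec(float(l1), float(l2)) for l2 in lambda2_values for l1 in lam1s]


def tune_penalty(
    study,
    grid: Sequence[PenaltySpec],
    folds: int = 5,
    seed: int = 0,
    analytes: Optional[Sequence[str]] = None,
    tol: float = 1e-6,
    max_iter: int = 4000,
) -> tuple[PenaltySpec, pd.DataFrame]:
    """Cross-validated penalty choice over matched pairs.

    Folds partition pairs (a pair is never split); the winning grid point
    maximizes the mean held-out conditional log-likelihood.  Ties go to
    the sparser model (larger ``lambda1``, then larger ``lambda2``).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    z, _ = _as_design(study, analytes)
    n = z.shape[0]
    if n < folds:
        raise ValueError(f"{n} pairs cannot form {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    for rank, i in enumerate(order):
        fold_of[i] = rank % folds
    # warm-start chains: within each lambda2 level, sweep lambda1 downward
    by_l2: dict[float, list[PenaltySpec]] = {}
    for spec in grid:
        by_l2.setdefault(spec.lambda2, []).append(spec)
    for specs in by_l2.values():
        specs.sort(key=lambda s: -s.lambda1)
    scores = {spec: [] for spec in grid}
    for f in range(folds):
        train = z[fold_of != f]
        test = z[fold_of == f]
        for specs in by_l2.values():
            beta = np.zeros(z.shape[1])
            for spec in specs:
                fit_res, _, _, _ = _mfista(
                    np.ascontiguousarray(train), spec.lambda1, spec.lambda2,
                    beta.copy(), tol, max_iter,
                )
                beta = fit_res
                scores[spec].append(conditional_loglik(test, beta))
    path = pd.DataFrame(
        {
            "lambda1": [s.lambda1 for s in grid],
            "lambda2": [s.lambda2 for s in grid],
            "mean_cv_loglik": [float(np.mean(scores[s])) for s in grid],
        }
    )
    best = max(
        grid,
        key=lambda s: (round(float(np.mean(scores[s])), 12), s.lambda1, s.lambda2),
    )
    return best, path
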