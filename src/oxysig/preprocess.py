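"""Raw concentration tables -> analysis-ready matrix.

Fixed pipeline order: impute -> log -> standardize.  An optional
per-subject total-signal adjustment (each subject's concentrations
divided by their total over the panel) exists to damp between-subject
differences in overall oxylipin load; it is off by default and must be
requested explicitly, since the exact adjustment used upstream of
quantified panels varies between laboratories.

Cross-cohort harmonization restricts two matrices to their shared
analyte panel after canonicalizing names (case, hyphens, parentheses and
the epoxy/Ep spelling variants), so that e.g. ``9(10)-Ep-stearic acid``
and ``9(10)-epoxy-stearic acid`` merge.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OxylipinMatrix


def canonicalize_name(name: str) -> str:
    """Canonical key for analyte-name matching across cohorts."""
    s = str(name).strip().lower()
    s = s.replace("epoxy", "ep")
    s = re.sub(r"[^a-z0-9]", "", s)
    return s


@dataclass
class StandardizationParams:
    """Per-analyte location/scale on the log axis, kept for re-use.

    Fitting-set parameters are retained so an external cohort can be
    placed on the same scale without refitting (coefficients are per
    1-SD increments of log concentration).
    """

    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            bad = self.scale.index[self.scale <= 0].tolist()
            raise ValueError(f"non-positive scale for analytes: {bad}")


def impute(matrix: OxylipinMatrix, strategy: str = "half_min") -> tuple[OxylipinMatrix, pd.DataFrame]:
    """Replace non-detects; default is per-analyte half-minimum.

    Left-censored non-detects sit below the detection limit, so half the
    smallest observed value is the conventional stand-in.  Analytes with
    no observed value at all cannot be imputed and are dropped with a
    warning.  The report's ``fraction_imputed`` feeds the analytical
    robustness filter downstream.
    """
    if strategy != "half_min":
        raise ValueError(f"unknown imputation strategy: {strategy!r}")
    values = matrix.values.copy()
    frac = values.isna().mean()
    dropped = frac.index[frac >= 1.0].tolist()
    if dropped:
        warnings.warn(f"dropping all-missing analytes: {dropped}", stacklevel=2)
        values = values.drop(columns=dropped)
    fill = values.min(skipna=True) / 2.0
    values = values.fillna(fill)
    report = pd.DataFrame(
        {
            "fraction_imputed": frac.drop(index=dropped),
            "fill_value": fill,
            "dropped": False,
        }
    )
    for a in dropped:
        report.loc[a] = [1.0, np.nan, True]
    meta = matrix.metadata.drop(index=[a for a in dropped if a in matrix.metadata.index])
    meta = meta.copy()
    meta.loc[values.columns, "fraction_imputed"] = report.loc[
        values.columns, "fraction_imputed"
    ]
    return OxylipinMatrix(values, meta), report


def log_standardize(
    matrix: OxylipinMatrix, params: StandardizationParams | None = None
) -> tuple[OxylipinMatrix, StandardizationParams]:
    """Natural-log transform then per-analyte centering/scaling.

    With ``params`` given, applies the stored location/scale (no
    refitting) — the contract for scoring an external cohort with a
    signature fitted elsewhere.
    """
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("missing values present: impute before standardizing")
    if (values.to_numpy() <= 0).any():
        raise ValueError("non-positive concentrations cannot be log-transformed")
    logv = np.log(values)
    if params is None:
        center = logv.mean()
        scale = logv.std(ddof=1)
        zero = scale.index[~(scale > 0)].tolist()
        if zero:
            raise ValueError(f"constant analytes have zero scale: {zero}")
        params = StandardizationParams(center=center, scale=scale)
    else:
        missing = [a for a in values.columns if a not in params.center.index]
        if missing:
            raise ValueError(f"no standardization parameters for analytes: {missing}")
    out = (logv - params.center[values.columns]) / params.scale[values.columns]
    return OxylipinMatrix(out, matrix.metadata.copy(), standardized=True), params


def total_signal_adjust(matrix: OxylipinMatrix, panel=None) -> OxylipinMatrix:
    """Optional per-subject scaling by total signal over ``panel``.

    Divides each subject's concentrations by that subject's summed
    concentration across the panel (default: all analytes), expressing
    each analyte as a share of total oxylipin load.
    """
    values = matrix.values
    cols = list(panel) if panel is not None else list(values.columns)
    totals = values[cols].sum(axis=1, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive total signal for subjects: {bad}")
    return OxylipinMatrix(values.div(totals, axis=0), matrix.metadata.copy())


def harmonize(
    matrix_a: OxylipinMatrix, matrix_b: OxylipinMatrix
) -> tuple[OxylipinMatrix, OxylipinMatrix, list[str]]:
    """Restrict both matrices to the shared analyte panel.

    Matching is exact-string after canonicalization; both outputs carry
    identical column order (panel named as in ``matrix_a``).  The panel
    result is symmetric in its inputs.
    """
    canon_a = {canonicalize_name(a): a for a in matrix_a.analytes}
    canon_b = {canonicalize_name(a): a for a in matrix_b.analytes}
    if len(canon_a) != len(matrix_a.analytes) or len(canon_b) != len(matrix_b.analytes):
        raise ValueError("analyte names collide after canonicalization")
    shared = [k for k in canon_a if k in canon_b]
    if not shared:
        raise ValueError("no analytes in common between the two panels")
    cols_a = [canon_a[k] for k in shared]
    cols_b = [canon_b[k] for k in shared]
    out_a = matrix_a.restrict(cols_a)
    out_b = matrix_b.restrict(cols_b)
    # present the common panel under a single naming (panel-a names)
    out_b.values.columns = cols_a
    out_b.metadata.index = [canon_b[k] for k in shared]
    out_b.metadata.index = cols_a
    return out_a, out_b, cols_a


def preprocess_pipeline(
    matrix: OxylipinMatrix,
    params: StandardizationParams | None = None,
    total_adjust: bool = False,
) -> tuple[OxylipinMatrix, StandardizationParams, pd.DataFrame]:
    """impute -> (optional total-signal adjust) -> log -> standardize."""
    imputed, report = impute(matrix)
    if total_adjust:
        imputed = total_signal_adjust(imputed)
    standardized, params = log_standardize(imputed, params)
    return standardized, params, report
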