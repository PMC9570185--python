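"""Univariate screening, volcano statistics and cross-cohort agreement.

All matched-design tests operate on within-pair differences: the
Wilcoxon signed-rank test (exact null distribution up to 25 pairs,
normal approximation with continuity correction above) with
Benjamini-Hochberg step-up adjustment across the analyte family, the
volcano coordinates (standardized case-control difference vs
-log10 adjusted p), Spearman consistency between scores and clinical
criteria with the conventional qualitative cutoffs (r >= 0.5 noteworthy,
r >= 0.7 strong, one-sided), and exact set arithmetic between the two
cohorts' candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MatchedStudy
from .preprocess import canonicalize_name

EXACT_WILCOXON_MAX_N = 25


def paired_wilcoxon_bh(study: MatchedStudy, analytes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-analyte signed-rank test on case-minus-control differences.

    Returns statistic, raw and BH-adjusted p, the case/control
    difference in within-study SD units, and its sign.  Analytes whose
    within-pair differences are all zero get p = 1 by convention and a
    ``degenerate`` flag.
    """
    values = study.matrix.values
    cols = list(analytes) if analytes is not None else list(values.columns)
    case = values.loc[study.case_ids, cols].to_numpy(float)
    ctrl = values.loc[study.control_ids, cols].to_numpy(float)
    diffs = case - ctrl
    n = diffs.shape[0]
    rows = []
    for j, analyte in enumerate(cols):
        d = diffs[:, j]
        d = d[~np.isnan(d)]
        nz = d[d != 0]
        if nz.size == 0:
            rows.append((analyte, 0.0, 1.0, True))
            continue
        method = "exact" if len(nz) <= EXACT_WILCOXON_MAX_N else "approx"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                             method=method)
        rows.append((analyte, float(res.statistic), float(res.pvalue), False))
    out = pd.DataFrame(rows, columns=["analyte", "statistic", "p_raw", "degenerate"])
    out = out.set_index("analyte")
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    # standardized case-control difference on the pooled per-analyte scale
    sd = np.nanstd(values[cols].to_numpy(float), axis=0, ddof=1)
    delta = (np.nanmean(case, axis=0) - np.nanmean(ctrl, axis=0)) / sd
    out["std_difference"] = delta
    out["direction"] = np.sign(out["std_difference"]).astype(int)
    return out


def volcano_table(records: pd.DataFrame, p_line: float = 0.0005) -> pd.DataFrame:
    """Volcano coordinates: x = standardized difference, y = -log10 p_adj.

    ``p_line`` marks the significance threshold line (default 5e-4).
    """
    out = pd.DataFrame(
        {
            "x": records["std_difference"],
            "y": -np.log10(records["p_adj"].clip(lower=np.finfo(float).tiny)),
        },
        index=records.index,
    )
    out["significant"] = records["p_adj"] <= p_line
    return out


def spearman_consistency(
    score_panel: pd.DataFrame,
    criteria_columns: pd.DataFrame,
    alpha: float = 0.05,
    noteworthy: float = 0.5,
    strong: float = 0.7,
) -> pd.DataFrame:
    """Spearman rho between each score and each criterion, with labels.

    Ties get average ranks.  Labels are one-sided exactly as
    conventionally printed: ``strong`` for r >= 0.7, ``noteworthy`` for
    r >= 0.5, ``none`` otherwise or when p >= alpha.
    """
    rows = []
    for score_name, score in score_panel.items():
        for crit_name, crit in criteria_columns.items():
            aligned = pd.concat([score, crit], axis=1, join="inner").dropna()
            rho, p = stats.spearmanr(aligned.iloc[:, 0], aligned.iloc[:, 1])
            if p < alpha and rho >= strong:
                label = "strong"
            elif p < alpha and rho >= noteworthy:
                label = "noteworthy"
            else:
                label = "none"
            rows.append((score_name, crit_name, float(rho), float(p), label))
    return pd.DataFrame(rows, columns=["score", "criterion", "rho", "p", "label"])


@dataclass
class VennSummary:
    """Exact set arithmetic between two candidate lists."""

    set_a: list[str]
    set_b: list[str]
    common: list[str]
    union: list[str]

    def counts(self) -> dict[str, int]:
        return {
            "n_a": len(self.set_a),
            "n_b": len(self.set_b),
            "n_common": len(self.common),
            "n_union": len(self.union),
        }


def venn(set_a: Sequence[str], set_b: Sequence[str]) -> VennSummary:
    """Intersection/union on canonicalized analyte names.

    Original (side-A preferred) spellings are kept in the output lists.
    """
    canon_a = {canonicalize_name(x): x for x in set_a}
    canon_b = {canonicalize_name(x): x for x in set_b}
    common_keys = [k for k in canon_a if k in canon_b]
    union_keys = list(canon_a) + [k for k in canon_b if k not in canon_a]
    prefer = {**canon_b, **canon_a}
    return VennSummary(
        set_a=sorted(canon_a.values()),
        set_b=sorted(canon_b.values()),
        common=sorted(prefer[k] for k in common_keys),
        union=sorted(prefer[k] for k in union_keys),
    )


def direction_concordance(
    univariate_a: pd.DataFrame,
    univariate_b: pd.DataFrame,
    analytes: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of analytes whose case-vs-control sign agrees between cohorts."""
    if analytes is None:
        analytes = [a for a in univariate_a.index if a in univariate_b.index]
    analytes = list(analytes)
    if not analytes:
        raise ValueError("no analytes to compare")
    sa = np.sign(univariate_a.loc[analytes, "std_difference"].to_numpy(float))
    sb = np.sign(univariate_b.loc[analytes, "std_difference"].to_numpy(float))
    return float(np.mean(sa == sb))


def fisher_categorical(table, n_permutations: int = 20000, seed: int = 0) -> float:
    """Fisher-style p-value for a 2 x k contingency table.

    Exact for 2 x 2 (scipy); for k > 2 a seeded Monte-Carlo permutation
    of category labels estimates the probability of a table as or less
    probable than the observed one (the simulated analogue of the
    Freeman-Halton extension).
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t)[1])
    rng = np.random.default_rng(seed)
    row = np.repeat([0, 1], t.sum(axis=1))
    cats = np.concatenate([np.repeat(np.arange(t.shape[1]), t[i]) for i in (0, 1)])

    def log_prob(tab):
        from scipy.special import gammaln

        return -np.sum(gammaln(tab + 1.0))

    obs = log_prob(t)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(cats)
        perm = np.stack(
            [np.bincount(cats[row == i], minlength=t.shape[1]) for i in (0, 1)]
        )
        if log_prob(perm) <= obs + 1e-12:
            hits += 1
    return float((hits + 1) / (n_permutations + 1))


def published_candidate_sets() -> dict[str, list[str]]:
    """The shipped discovery/replication/refined candidate name lists."""
    with resources.as_file(
        resources.files("oxysig.data") / "candidate_oxylipins.csv"
    ) as path:
        df = pd.read_csv(path, comment="#")
    return {name: group["analyte"].tolist() for name, group in df.groupby("set")}
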