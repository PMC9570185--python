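"""Harmonized metabolic-syndrome case definition and severity score.

A subject is a MetS case when at least three of the five harmonized
criteria are met: elevated waist circumference (>=94 cm men, >=80 cm
women), elevated triglycerides (>=150 mg/dL), reduced HDL cholesterol
(<40 mg/dL men, <50 mg/dL women), elevated blood pressure (SBP >= 130
and/or DBP >= 85 mmHg) and elevated fasting glucose (>=100 mg/dL).
Pharmacotherapy for triglycerides, blood pressure or glucose forces the
corresponding criterion to count as satisfied.

The continuous MetS severity z-score is the linear form
``Y + a*waist - b*HDLc + c*SBP + d*log(TG) + e*glucose`` with
demographic-specific coefficients supplied as configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

WAIST_THRESHOLD = {"male": 94.0, "female": 80.0}
TG_THRESHOLD = 150.0
HDLC_THRESHOLD = {"male": 40.0, "female": 50.0}
SBP_THRESHOLD = 130.0
DBP_THRESHOLD = 85.0
GLUCOSE_THRESHOLD = 100.0

CRITERIA = ("waist", "tg", "hdlc", "bp", "glucose")

_REQUIRED = ("sex", "waist", "tg", "hdlc", "sbp", "dbp", "glucose")


def _get(subject: Mapping, key: str):
    try:
        value = subject[key]
    except (KeyError, IndexError):
        raise ValueError(f"missing criterion field: {key!r}") from None
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing criterion field: {key!r}")
    return value


def criteria_flags(subject: Mapping) -> dict[str, bool]:
    """Per-criterion satisfaction, medication flags included.

    Threshold comparisons use the printed inequality senses verbatim
    (>= for waist/TG/BP/glucose, < for HDLc), so boundary values satisfy
    the criteria exactly as written.
    """
    sex = str(_get(subject, "sex")).lower()
    if sex not in WAIST_THRESHOLD:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    for key in _REQUIRED[1:]:
        _get(subject, key)

    def med(flag: str) -> bool:
        return bool(subject.get(flag, False)) if hasattr(subject, "get") else bool(
            subject[flag] if flag in subject else False
        )

    return {
        "waist": float(subject["waist"]) >= WAIST_THRESHOLD[sex],
        "tg": float(subject["tg"]) >= TG_THRESHOLD or med("tg_lowering"),
        "hdlc": float(subject["hdlc"]) < HDLC_THRESHOLD[sex],
        "bp": float(subject["sbp"]) >= SBP_THRESHOLD
        or float(subject["dbp"]) >= DBP_THRESHOLD
        or med("bp_lowering"),
        "glucose": float(subject["glucose"]) >= GLUCOSE_THRESHOLD
        or med("glucose_lowering"),
    }


def classify_mets(subject: Mapping) -> tuple[int, bool]:
    """Criteria count (0..5) and case status (count >= 3)."""
    flags = criteria_flags(subject)
    count = sum(flags.values())
    return count, count >= 3


def classify_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    """Vectorized wrapper: adds ``criteria_count`` and ``is_case`` columns."""
    out = subjects.copy()
    counts, cases = [], []
    for _, row in subjects.iterrows():
        count, is_case = classify_mets(row)
        counts.append(count)
        cases.append(is_case)
    out["criteria_count"] = counts
    out["is_case"] = cases
    return out


def criteria_count_balance(controls) -> dict[int, int]:
    """Histogram of criteria counts over {0,1,2} for a control group.

    Any member meeting >=3 criteria violates the control definition and
    raises.
    """
    hist = {0: 0, 1: 0, 2: 0}
    if isinstance(controls, pd.DataFrame):
        controls = [row for _, row in controls.iterrows()]
    for subject in controls:
        count, is_case = classify_mets(subject)
        if is_case:
            ident = subject.get("id", getattr(subject, "name", "<unknown>"))
            raise ValueError(
                f"control {ident!r} meets {count} criteria (>=3): not a control"
            )
        hist[count] += 1
    return hist


@dataclass
class MetSZCoefficients:
    """Severity-score coefficients keyed by (sex, ethnicity, age group).

    The reference coefficients come from an external severity-score
    calculator and are treated as configuration: the packaged default
    table is a synthetic placeholder (see its header) meant to be
    replaced with calculator output for real analyses.
    """

    table: pd.DataFrame  # indexed by (sex, ethnicity, age_group); columns Y,a,b,c,d,e

    @classmethod
    def from_csv(cls, path) -> "MetSZCoefficients":
        df = pd.read_csv(path, comment="#")
        df = df.set_index(["sex", "ethnicity", "age_group"])
        return cls(df)

    @classmethod
    def default(cls) -> "MetSZCoefficients":
        with resources.as_file(
            resources.files("oxysig.data") / "mets_z_coefficients.csv"
        ) as path:
            return cls.from_csv(path)

    def lookup(self, sex: str, ethnicity: str = "default", age_group: str = "adult") -> pd.Series:
        key = (str(sex).lower(), ethnicity, age_group)
        try:
            return self.table.loc[key]
        except KeyError:
            raise ValueError(
                f"no MetS-z coefficients for key {key}; available: "
                f"{sorted(self.table.index.tolist())}"
            ) from None


def mets_z_score(
    subject: Mapping,
    coeffs: MetSZCoefficients,
    ethnicity: str = "default",
    age_group: str = "adult",
    log_base: float = math.e,
) -> float:
    """Continuous MetS severity: Y + a*waist - b*HDLc + c*SBP + d*log(TG) + e*glucose.

    The log base for TG defaults to the natural log and is configurable.
    """
    row = coeffs.lookup(_get(subject, "sex"), ethnicity, age_group)
    tg = float(_get(subject, "tg"))
    return float(
        row["Y"]
        + row["a"] * float(_get(subject, "waist"))
        - row["b"] * float(_get(subject, "hdlc"))
        + row["c"] * float(_get(subject, "sbp"))
        + row["d"] * (math.log(tg) / math.log(log_base))
        + row["e"] * float(_get(subject, "glucose"))
    )


def mets_z_frame(
    subjects: pd.DataFrame, coeffs: MetSZCoefficients | None = None, **kwargs
) -> pd.Series:
    """MetS-z-score for every row of a subject table."""
    if coeffs is None:
        coeffs = MetSZCoefficients.default()
    return pd.Series(
        {sid: mets_z_score(row, coeffs, **kwargs) for sid, row in subjects.iterrows()},
        name="mets_z",
    )
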