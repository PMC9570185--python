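"""Core in-memory containers shared across the pipeline.

Subjects and analyte concentrations live in pandas objects; these thin
dataclasses add the pairing structure and the invariants the matched
case-control design relies on (one case and one control per pair, unique
analyte names, non-negative concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Columns every subject table must carry to apply the MetS case definition.
CRITERIA_COLUMNS = ("sex", "waist", "sbp", "dbp", "glucose", "tg", "hdlc")

#: Medication flags that force a criterion to count as satisfied.
MEDICATION_COLUMNS = ("tg_lowering", "bp_lowering", "glucose_lowering")


@dataclass
class OxylipinMatrix:
    """Subjects x analytes concentration table (nM).

    ``values`` holds concentrations with NaN marking non-detects; the
    missingness mask is therefore implicit in the values.  ``metadata`` is
    indexed by analyte name and may carry precursor PUFA, biosynthetic
    pathway, analytical-robustness flags and the fraction imputed.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: after log-standardization values are z-scores, not concentrations,
    #: and the non-negativity invariant no longer applies
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate analyte names: {dupes}")
        with np.errstate(invalid="ignore"):
            if not self.standardized and (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative concentrations present")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.values.columns.copy())

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "OxylipinMatrix":
        return OxylipinMatrix(self.values.copy(), self.metadata.copy(), self.standardized)

    def restrict(self, analytes: Sequence[str]) -> "OxylipinMatrix":
        """Column-subset to ``analytes`` (order preserved as given)."""
        missing = [a for a in analytes if a not in self.values.columns]
        if missing:
            raise KeyError(f"analytes not in matrix: {missing}")
        meta = self.metadata.loc[[a for a in analytes if a in self.metadata.index]]
        return OxylipinMatrix(
            self.values.loc[:, list(analytes)].copy(), meta.copy(), self.standardized
        )


@dataclass
class MatchedStudy:
    """A 1:1 matched case-control study: the unit of all resampling.

    ``subjects`` is indexed by subject id and must carry ``is_case`` and
    ``pair_id``; ``pairs`` has one row per pair with ``case_id`` and
    ``control_id``.  ``matrix`` rows align with subject ids.
    """

    subjects: pd.DataFrame
    pairs: pd.DataFrame
    matrix: OxylipinMatrix
    cohort: str = "study"

    def __post_init__(self) -> None:
        ids = pd.concat([self.pairs["case_id"], self.pairs["control_id"]])
        if ids.duplicated().any():
            raise ValueError(
                f"subjects appear in more than one pair: {ids[ids.duplicated()].tolist()}"
            )
        unknown = set(ids) - set(self.subjects.index)
        if unknown:
            raise ValueError(f"pair members missing from subject table: {sorted(unknown)}")
        if "is_case" in self.subjects.columns:
            roles = self.subjects["is_case"]
            bad_case = [c for c in self.pairs["case_id"] if not roles.loc[c]]
            bad_ctrl = [c for c in self.pairs["control_id"] if roles.loc[c]]
            if bad_case or bad_ctrl:
                raise ValueError(
                    f"pair roles inconsistent with is_case flags: cases {bad_case}, "
                    f"controls {bad_ctrl}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def case_ids(self) -> list:
        return list(self.pairs["case_id"])

    @property
    def control_ids(self) -> list:
        return list(self.pairs["control_id"])

    def labels(self) -> pd.Series:
        """Case indicator aligned with the matrix rows."""
        role = pd.Series(False, index=self.matrix.values.index)
        role.loc[self.case_ids] = True
        return role

    def design(self, analytes: Optional[Sequence[str]] = None) -> tuple[np.ndarray, list[str]]:
        """Within-pair difference design matrix (case minus control).

        The conditional likelihood for 1:1 pairs depends on the data only
        through these differences, so this is the canonical fitting input.
        """
        cols = list(analytes) if analytes is not None else self.matrix.analytes
        vals = self.matrix.values.loc[:, cols]
        z = vals.loc[self.case_ids].to_numpy(dtype=float) - vals.loc[
            self.control_ids
        ].to_numpy(dtype=float)
        return z, cols

    def with_matrix(self, matrix: OxylipinMatrix) -> "MatchedStudy":
        return MatchedStudy(self.subjects, self.pairs, matrix, self.cohort)
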