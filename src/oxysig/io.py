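"""File dialects and run configuration.

The primary on-disk dialect is plain CSV: a subject table (one row per
participant, clinical criteria and matching factors as columns), a pair
table (``pair_id, case_id, control_id``) and a wide concentration table
(one row per subject, one column per analyte, empty cells for
non-detects).  A long-format importer
(``subject_id, analyte, concentration``) is provided for panels exported
that way.  Reading validates pair integrity and criteria completeness
with row-level diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .containers import CRITERIA_COLUMNS, MatchedStudy, OxylipinMatrix
from .stability import StabilityConfig
from .synthetic import SimulationConfig

SUBJECTS_FILE = "subjects.csv"
PAIRS_FILE = "pairs.csv"
CONCENTRATIONS_FILE = "concentrations.csv"
ANALYTES_FILE = "analytes.csv"


def round_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up (report formatting convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = 100.0 * count / total
    factor = 10**decimals
    return math.floor(value * factor + 0.5) / factor


def write_study(study: MatchedStudy, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.subjects.to_csv(directory / SUBJECTS_FILE, index_label="id")
    study.pairs.to_csv(directory / PAIRS_FILE, index=False)
    study.matrix.values.to_csv(directory / CONCENTRATIONS_FILE, index_label="id")
    study.matrix.metadata.to_csv(directory / ANALYTES_FILE, index_label="analyte")
    return directory


def read_study(directory, cohort: str = "study") -> MatchedStudy:
    """Load and validate a study from its CSV directory."""
    directory = Path(directory)
    subjects = pd.read_csv(directory / SUBJECTS_FILE, index_col="id")
    pairs = pd.read_csv(directory / PAIRS_FILE)
    values = pd.read_csv(directory / CONCENTRATIONS_FILE, index_col="id")
    analytes_path = directory / ANALYTES_FILE
    metadata = (
        pd.read_csv(analytes_path, index_col="analyte")
        if analytes_path.exists()
        else pd.DataFrame()
    )
    missing_cols = [c for c in CRITERIA_COLUMNS if c not in subjects.columns]
    if missing_cols:
        raise ValueError(f"subject table is missing criteria columns: {missing_cols}")
    for col in CRITERIA_COLUMNS[1:]:
        bad = subjects.index[subjects[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col} for subjects: {bad.tolist()}")
    neg = values.lt(0)
    if neg.any().any():
        where = [
            (sid, a)
            for sid in values.index[neg.any(axis=1)]
            for a in values.columns[neg.loc[sid]]
        ]
        raise ValueError(f"negative concentrations at: {where[:10]}")
    if "is_case" not in subjects.columns:
        from .criteria import classify_frame

        subjects = classify_frame(subjects)
    roles = subjects["is_case"]
    for _, row in pairs.iterrows():
        if not roles.get(row["case_id"], False):
            raise ValueError(
                f"pair {row['pair_id']}: case member {row['case_id']!r} is not a case"
            )
        if roles.get(row["control_id"], True):
            raise ValueError(
                f"pair {row['pair_id']}: control member {row['control_id']!r} is not a control"
            )
    return MatchedStudy(subjects, pairs, OxylipinMatrix(values, metadata), cohort=cohort)


def read_long_concentrations(path) -> pd.DataFrame:
    """Long (subject_id, analyte, concentration) -> wide table."""
    long = pd.read_csv(path)
    required = {"subject_id", "analyte", "concentration"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"long-format file missing columns: {sorted(missing)}")
    return long.pivot(index="subject_id", columns="analyte", values="concentration")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    workdir: str = "oxysig-run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    simulation_b: Optional[SimulationConfig] = None
    n_common: Optional[int] = None
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    k_folds: int = 10
    total_adjust: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = SimulationConfig(**_tuplify(raw["simulation"]))
        if raw.get("simulation_b") is not None and isinstance(raw["simulation_b"], dict):
            raw["simulation_b"] = SimulationConfig(**_tuplify(raw["simulation_b"]))
        if "stability" in raw and isinstance(raw["stability"], dict):
            raw["stability"] = StabilityConfig(**_tuplify(raw["stability"]))
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _tuplify(raw: dict) -> dict:
    out = dict(raw)
    for key in ("control_balance", "lambda2_values"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    if out.get("block_structure") is not None:
        out["block_structure"] = [tuple(b) for b in out["block_structure"]]
    return out
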