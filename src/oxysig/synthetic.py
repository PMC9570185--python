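"""Synthetic matched case-control cohorts with oxylipin panels.

The generator emulates the data structure the analysis assumes: 1:1
pairs matched on sex, age class, smoking and physical activity; five
clinical criteria driven by a scalar latent severity; log-normal analyte
concentrations with pathway-block correlation; and a minority of
"signal" analytes whose log concentrations shift with severity, so that
cases and controls differ by a configurable number of SD units.

A single latent severity per subject drives both the criteria
exceedances and the signal-analyte shifts, which reproduces the kind of
coupling seen between a concentration-based risk score and a clinical
severity score.  Controls are balanced over criteria counts {0,1,2} by
construction (rejection sampling with a bounded number of attempts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import criteria
from .containers import MatchedStudy, OxylipinMatrix

#: Latent-severity means; the case mean is placed so the expected case
#: criteria count is ~3.6, matching typical case-group prevalences.
CONTROL_SEVERITY_MEAN = {0: -1.5, 1: -0.75, 2: 0.0}
CONTROL_SEVERITY_SD = 0.3
CASE_SEVERITY_MEAN = 0.55
CASE_SEVERITY_SD = 0.5

#: Per-criterion offsets on the severity scale; ordered so that waist is
#: the most prevalent criterion and low HDLc the least, as in typical
#: MetS case groups.
CRITERION_OFFSETS = {"waist": -0.5, "bp": -0.3, "glucose": 0.0, "tg": 0.3, "hdlc": 0.6}

_MAX_ATTEMPTS = 1000


def default_panel(n_analytes: int) -> list[str]:
    """First ``n_analytes`` names from the packaged oxylipin catalog.

    Panels larger than the catalog are padded with systematic names.
    """
    catalog = load_annotations()
    names = list(catalog.index)
    if n_analytes <= len(names):
        return names[:n_analytes]
    extra = [f"OXY-{i:03d}" for i in range(n_analytes - len(names))]
    return names + extra


def load_annotations() -> pd.DataFrame:
    with resources.as_file(
        resources.files("oxysig.data") / "oxylipin_annotations.csv"
    ) as path:
        df = pd.read_csv(path, comment="#")
    return df.set_index("analyte")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``effect_sizes`` is the standardized log-concentration shift of each
    signal analyte (case minus control, in SD units); a scalar applies
    to all signals.  ``criteria_effect`` is the logistic slope linking
    latent severity to each criterion's exceedance probability.
    ``control_balance`` gives the target proportions of controls with
    0, 1 and 2 criteria.  ``censor_frac`` left-censors the lowest
    fraction of each analyte's concentrations to non-detects.
    """

    n_pairs: int = 137
    n_analytes: int = 54
    n_signal: int = 5
    effect_sizes: float | Sequence[float] = 0.8
    block_structure: Optional[list[tuple[int, float]]] = None
    noise_sd: float = 1.0
    criteria_effect: float = 2.0
    control_balance: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    censor_frac: float = 0.05
    seed: int = 0
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_signal > self.n_analytes:
            raise ValueError("n_signal cannot exceed n_analytes")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")
        if abs(sum(self.control_balance) - 1.0) > 1e-9 or min(self.control_balance) < 0:
            raise ValueError("control_balance proportions must be nonnegative and sum to 1")
        if self.block_structure is None:
            self.block_structure = [(6, 0.5)] * (self.n_analytes // 6)
        total = sum(size for size, _ in self.block_structure)
        if total > self.n_analytes:
            raise ValueError("block sizes exceed the analyte count")
        for size, rho in self.block_structure:
            if size < 1:
                raise ValueError("block sizes must be positive")
            if not 0 <= rho < 1:
                raise ValueError("within-block correlations must lie in [0, 1)")

    @property
    def effects(self) -> np.ndarray:
        e = np.asarray(self.effect_sizes, dtype=float)
        if e.ndim == 0:
            e = np.repeat(float(e), self.n_signal)
        if e.size != self.n_signal:
            raise ValueError("effect_sizes length must equal n_signal")
        return e


@dataclass
class SyntheticStudy:
    """A generated cohort plus the ground truth of its signal analytes."""

    matched_study: MatchedStudy
    truth: dict[str, float]
    severity: pd.Series

    @property
    def signal_analytes(self) -> list[str]:
        return list(self.truth)


def _correlation_matrix(config: SimulationConfig) -> np.ndarray:
    r = np.eye(config.n_analytes)
    start = 0
    for size, rho in config.block_structure:
        r[start : start + size, start : start + size] = rho
        np.fill_diagonal(r[start : start + size, start : start + size], 1.0)
        start += size
    return r


def _truncnorm(rng, mean, sd, low=-np.inf, high=np.inf):
    """One draw from a truncated normal via the inverse CDF."""
    from scipy.stats import truncnorm as _tn

    a, b = (low - mean) / sd, (high - mean) / sd
    return float(_tn.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def _criteria_values(rng, sex: str, flags: dict[str, bool]) -> dict[str, float]:
    """Clinical values consistent with the satisfied/unsatisfied flags.

    Means/SDs approximate a middle-aged European cohort; every value is
    drawn from a normal truncated to the correct side of its threshold.
    """
    w_thr = criteria.WAIST_THRESHOLD[sex]
    h_thr = criteria.HDLC_THRESHOLD[sex]
    out = {}
    if flags["waist"]:
        out["waist"] = _truncnorm(rng, w_thr + 10, 12, low=w_thr)
    else:
        out["waist"] = _truncnorm(rng, w_thr - 10, 9, high=w_thr - 1e-6)
    if flags["tg"]:
        out["tg"] = _truncnorm(rng, 185, 60, low=criteria.TG_THRESHOLD)
    else:
        out["tg"] = _truncnorm(rng, 95, 35, low=30, high=criteria.TG_THRESHOLD - 1e-6)
    if flags["hdlc"]:
        out["hdlc"] = _truncnorm(rng, h_thr - 8, 6, low=15, high=h_thr - 1e-6)
    else:
        out["hdlc"] = _truncnorm(rng, 66, 14, low=h_thr)
    if flags["bp"]:
        out["sbp"] = _truncnorm(rng, 145, 15, low=criteria.SBP_THRESHOLD)
        out["dbp"] = _truncnorm(rng, 88, 9, low=50)
    else:
        out["sbp"] = _truncnorm(rng, 120, 10, low=85, high=criteria.SBP_THRESHOLD - 1e-6)
        out["dbp"] = _truncnorm(rng, 77, 7, low=45, high=criteria.DBP_THRESHOLD - 1e-6)
    if flags["glucose"]:
        out["glucose"] = _truncnorm(rng, 109, 15, low=criteria.GLUCOSE_THRESHOLD)
    else:
        out["glucose"] = _truncnorm(
            rng, 90, 8, low=60, high=criteria.GLUCOSE_THRESHOLD - 1e-6
        )
    return out


def _draw_flags(rng, severity: float, slope: float) -> dict[str, bool]:
    probs = {
        name: 1.0 / (1.0 + np.exp(-slope * (severity - off)))
        for name, off in CRITERION_OFFSETS.items()
    }
    return {name: bool(rng.uniform() < p) for name, p in probs.items()}


def _subject_criteria(rng, config, role: str, target_count: int):
    """Severity + criterion flags consistent with the subject's role.

    Cases need >= 3 satisfied criteria; controls need exactly
    ``target_count`` (their balance stratum).  Rejection sampling with a
    bounded attempt budget; severity itself is refreshed every 50
    attempts to escape unlucky draws.
    """
    for attempt in range(_MAX_ATTEMPTS):
        if attempt % 50 == 0:
            if role == "case":
                severity = rng.normal(CASE_SEVERITY_MEAN, CASE_SEVERITY_SD)
            else:
                severity = rng.normal(
                    CONTROL_SEVERITY_MEAN[target_count], CONTROL_SEVERITY_SD
                )
        flags = _draw_flags(rng, severity, config.criteria_effect)
        count = sum(flags.values())
        if role == "case" and count >= 3:
            return severity, flags
        if role == "control" and count == target_count:
            return severity, flags
    raise RuntimeError(
        f"could not generate a {role} with criteria count "
        f"{'>=3' if role == 'case' else target_count} in {_MAX_ATTEMPTS} attempts; "
        "the control_balance / criteria_effect configuration is infeasible"
    )


def _severity_scale(config: SimulationConfig) -> tuple[float, float]:
    """Affine map putting case/control mean severities at +0.5 / -0.5."""
    mean_control = float(
        np.dot(config.control_balance, [CONTROL_SEVERITY_MEAN[c] for c in (0, 1, 2)])
    )
    denom = CASE_SEVERITY_MEAN - mean_control
    center = 0.5 * (CASE_SEVERITY_MEAN + mean_control)
    return center, denom


def generate_study(
    config: SimulationConfig,
    panel: Optional[Sequence[str]] = None,
    signal_analytes: Optional[Sequence[str]] = None,
) -> SyntheticStudy:
    """Generate one matched case-control cohort.

    All randomness flows from ``config.seed``; identical configs give
    identical studies.  ``panel`` and ``signal_analytes`` override the
    default catalog-based naming (used for two-cohort generation).
    """
    rng = np.random.default_rng(config.seed)
    panel = list(panel) if panel is not None else default_panel(config.n_analytes)
    if len(panel) != config.n_analytes:
        raise ValueError("panel length must equal n_analytes")
    if signal_analytes is None:
        signal_idx = rng.choice(config.n_analytes, size=config.n_signal, replace=False)
        signal_analytes = [panel[i] for i in sorted(signal_idx)]
    else:
        signal_analytes = list(signal_analytes)
        if len(signal_analytes) != config.n_signal:
            raise ValueError("signal_analytes length must equal n_signal")
        missing = [a for a in signal_analytes if a not in panel]
        if missing:
            raise ValueError(f"signal analytes outside the panel: {missing}")
    effects = config.effects
    truth = dict(zip(signal_analytes, effects.tolist()))

    # control balance strata, as even as the proportions allow
    counts = np.floor(np.asarray(config.control_balance) * config.n_pairs).astype(int)
    while counts.sum() < config.n_pairs:
        counts[int(np.argmax(np.asarray(config.control_balance) * config.n_pairs - counts))] += 1
    strata = np.repeat([0, 1, 2], counts)
    rng.shuffle(strata)

    rows, severities, pair_rows = [], {}, []
    for p in range(config.n_pairs):
        sex = "male" if rng.uniform() < 0.39 else "female"
        age = float(np.clip(rng.normal(54, 8), 30, 70))
        age_class = int(age) // 2 * 2
        smoking = rng.choice(["never", "former", "current"], p=[0.5, 0.3, 0.2])
        activity = rng.choice(["low", "moderate", "intense"], p=[0.2, 0.4, 0.4])
        season = rng.choice(["winter", "spring", "summer", "fall"])
        menopause = (
            "not_applicable" if sex == "male" else rng.choice(["no", "yes"], p=[0.4, 0.6])
        )
        shared = dict(
            sex=sex,
            age=round(age, 1),
            age_class=age_class,
            smoking=smoking,
            activity=activity,
            season=season,
            menopause=menopause,
            cohort=config.cohort,
        )
        target = int(strata[p])
        for role in ("case", "control"):
            sid = f"{config.cohort}-P{p:04d}-{role}"
            sev, flags = _subject_criteria(
                rng, config, role, target if role == "control" else -1
            )
            values = _criteria_values(rng, sex, flags)
            rows.append(
                dict(
                    id=sid,
                    pair_id=p,
                    role=role,
                    tg_lowering=False,
                    bp_lowering=False,
                    glucose_lowering=False,
                    **shared,
                    **values,
                )
            )
            severities[sid] = sev
        pair_rows.append(
            dict(
                pair_id=p,
                case_id=f"{config.cohort}-P{p:04d}-case",
                control_id=f"{config.cohort}-P{p:04d}-control",
            )
        )

    subjects = pd.DataFrame(rows).set_index("id")
    subjects = criteria.classify_frame(subjects)
    roles = subjects.pop("role")
    bad = subjects.index[(roles == "case") != subjects["is_case"]]
    if len(bad):  # construction guarantees this; guard against regressions
        raise AssertionError(f"generated labels inconsistent with roles: {list(bad)}")
    pairs = pd.DataFrame(pair_rows)

    # log-concentrations: block-correlated MVN plus severity-coupled shifts
    n_sub = len(subjects)
    corr = _correlation_matrix(config)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(config.n_analytes))
    base = rng.normal(1.0, 1.0, size=config.n_analytes)  # per-analyte log-mean (nM)
    noise = rng.standard_normal((n_sub, config.n_analytes)) @ chol.T * config.noise_sd
    logc = base[None, :] + noise
    center, denom = _severity_scale(config)
    sev = np.array([severities[s] for s in subjects.index])
    sev_std = (sev - center) / denom
    for analyte, eff in truth.items():
        j = panel.index(analyte)
        logc[:, j] += eff * config.noise_sd * sev_std
    conc = np.exp(logc)
    values = pd.DataFrame(conc, index=subjects.index, columns=panel)

    if config.censor_frac > 0:
        limits = values.quantile(config.censor_frac)
        values = values.mask(values.lt(limits, axis=1))

    catalog = load_annotations()
    meta = catalog.reindex(panel)[["precursor", "pathway"]]
    matrix = OxylipinMatrix(values, meta)
    study = MatchedStudy(subjects, pairs, matrix, cohort=config.cohort)
    return SyntheticStudy(
        matched_study=study,
        truth=truth,
        severity=pd.Series(severities, name="severity"),
    )


def generate_two_cohorts(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    n_common: int,
) -> tuple[SyntheticStudy, SyntheticStudy]:
    """Two cohorts whose panels overlap in exactly ``n_common`` analytes.

    Shared signal analytes live on the common panel with identical
    effects in both cohorts (inconsistent shared effects raise); any
    surplus signals of one cohort are placed on its specific panel.
    """
    if n_common > min(config_a.n_analytes, config_b.n_analytes):
        raise ValueError("n_common exceeds a panel size")
    n_specific_a = config_a.n_analytes - n_common
    n_specific_b = config_b.n_analytes - n_common
    names = default_panel(n_common + n_specific_a + n_specific_b)
    common = names[:n_common]
    panel_a = common + names[n_common : n_common + n_specific_a]
    panel_b = common + names[n_common + n_specific_a :]

    n_shared = min(config_a.n_signal, config_b.n_signal)
    if n_shared > n_common:
        raise ValueError("more shared signals than common analytes")
    eff_a, eff_b = config_a.effects, config_b.effects
    if not np.allclose(eff_a[:n_shared], eff_b[:n_shared]):
        raise ValueError(
            "inconsistent signal effects on the common panel: "
            f"{eff_a[:n_shared]} vs {eff_b[:n_shared]}"
        )
    rng = np.random.default_rng(config_a.seed)
    shared_signals = [common[i] for i in sorted(rng.choice(n_common, n_shared, replace=False))]

    def extras(panel, specific, k, rng_seed):
        if k == 0:
            return []
        if k > len(specific):
            raise ValueError("not enough cohort-specific analytes for surplus signals")
        r = np.random.default_rng(rng_seed)
        return [specific[i] for i in sorted(r.choice(len(specific), k, replace=False))]

    sig_a = shared_signals + extras(panel_a, panel_a[n_common:], config_a.n_signal - n_shared, config_a.seed + 1)
    sig_b = shared_signals + extras(panel_b, panel_b[n_common:], config_b.n_signal - n_shared, config_b.seed + 2)
    study_a = generate_study(config_a, panel=panel_a, signal_analytes=sig_a)
    study_b = generate_study(config_b, panel=panel_b, signal_analytes=sig_b)
    overlap = set(panel_a) & set(panel_b)
    assert len(overlap) == n_common
    return study_a, study_b
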