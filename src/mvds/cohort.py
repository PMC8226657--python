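"""Synthetic VFSS-rated stroke cohorts.

No patient-level data from the motivating study are public, so downstream
analyses are exercised on simulated cohorts that carry the study's
statistical structure:

* a single latent dysphagia severity per patient drives all 9 mVDS items
  (ordinal levels obtained by thresholding severity plus per-item noise),
  inducing the positive inter-item correlation a severity scale presumes;
* item thresholds are anchored to the published per-item score marginals,
  and the latent mean is then calibrated numerically so the expected total
  matches the published cohort mean total (36.277 points);
* two raters observe the same true levels through independent
  misclassification noise (each item level slips by ±1 with probability
  ``rater_noise``), yielding high but imperfect inter-rater reliability;
* oral-feeding selection and aspiration pneumonia are Bernoulli outcomes of
  the true total score with the published logistic slopes (−0.114 and
  +0.051 per point); intercepts are root-found so the marginal oral rate is
  42/56 and pneumonia prevalence 0.25;
* demographics (age, sex, MMSE, MBI, days since onset) are passengers drawn
  from normal/log-normal approximations of the published table and enter no
  model.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, ndtri
from scipy.stats import norm

from .scale import (
    MVDS_ITEM_IDS,
    PASGrade,
    RatingProfile,
    ScaleDefinition,
    load_scale_definition,
    pas_to_aspiration_level,
    score_profile,
)

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "CohortSchemaError",
    "default_config",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]


class CohortSchemaError(ValueError):
    """A cohort CSV or config violates the documented schema."""


# Per-item P(level >= l), anchored to the published per-item score means
# (the aspiration marginal also reproduces the published PAS mean ~3.8).
_TARGET_EXCEEDANCE: dict[str, tuple[float, ...]] = {
    "lip_closure": (0.053,),
    "mastication": (0.357,),
    "oral_transit_time": (0.143,),
    "triggering_pharyngeal_swallow": (0.983,),
    "epiglottis_inversion": (0.035,),
    "valleculae_residue": (0.90, 0.20, 0.08),
    "pyriformis_residue": (0.47, 0.13, 0.04),
    "pharyngeal_wall_coating": (0.196,),
    "aspiration": (0.85, 0.30),
}

_TARGET_MEAN_TOTAL = 36.277  # published cohort mean total score
_TARGET_ORAL_RATE = 42 / 56  # inferred from published sens/spec counts
_TARGET_PNEUMONIA_RATE = 0.25  # package choice; see methods note
_CALIBRATION_SEED = 20210527  # internal, independent of user seeds
_CALIBRATION_N = 20000


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_patients: int = 56
    prop_supratentorial: float = 38 / 56
    severity_mean: float = 0.0
    severity_sd: float = 1.0
    item_noise_sd: float = 1.0
    item_thresholds: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    rater_noise: float = 0.11
    beta_feeding: float = -0.114
    beta_pneumonia: float = 0.051
    intercept_feeding: float = 0.0
    intercept_pneumonia: float = 0.0
    prop_male: float = 33 / 56
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "item_thresholds",
            {k: tuple(float(x) for x in v) for k, v in dict(self.item_thresholds).items()},
        )
        self.validate()

    def validate(self, scale: ScaleDefinition | None = None) -> None:
        if self.n_patients < 2:
            raise CohortSchemaError("n_patients must be >= 2")
        for name in ("prop_supratentorial", "rater_noise", "prop_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortSchemaError(f"{name} must be in [0, 1], got {v}")
        if self.severity_sd <= 0 or self.item_noise_sd < 0:
            raise CohortSchemaError("severity_sd must be > 0 and item_noise_sd >= 0")
        scale = scale or load_scale_definition()
        missing = [i for i in scale.item_ids if i not in self.item_thresholds]
        if missing:
            raise CohortSchemaError(f"item_thresholds missing items: {missing}")
        for it in scale.items:
            t = self.item_thresholds[it.item_id]
            if len(t) != it.n_levels - 1:
                raise CohortSchemaError(
                    f"item {it.item_id!r}: needs {it.n_levels - 1} thresholds, got {len(t)}"
                )
            if any(b <= a for a, b in zip(t, t[1:])):
                raise CohortSchemaError(
                    f"item {it.item_id!r}: thresholds must be strictly increasing"
                )

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["item_thresholds"] = {k: list(v) for k, v in self.item_thresholds.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise CohortSchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, Mapping):
            raise CohortSchemaError("config file is not a mapping")
        return cls.from_dict(d)


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient: true state, two rater views, outcomes, passengers."""

    patient_id: int
    subgroup: str  # "supratentorial" | "infratentorial"
    rater1: RatingProfile
    rater2: RatingProfile
    true_profile: RatingProfile  # the noise-free levels both raters observe
    pas: PASGrade
    true_score: float
    feeding: str  # "oral" | "non_oral"
    pneumonia: str  # "yes" | "no"
    age: int
    sex: str
    mmse: int
    mbi: int
    duration_days: int


def _default_thresholds(severity_sd: float, item_noise_sd: float) -> dict[str, tuple[float, ...]]:
    """Thresholds on the latent scale reproducing the target level marginals
    when severity is N(0, severity_sd)."""
    s_eff = float(np.hypot(severity_sd, item_noise_sd))
    return {
        item: tuple(-ndtri(p) * s_eff for p in probs)
        for item, probs in _TARGET_EXCEEDANCE.items()
    }


def _expected_total(
    mean: float,
    thresholds: Mapping[str, Sequence[float]],
    s_eff: float,
    scale: ScaleDefinition,
) -> float:
    """Closed-form E[total score] when severity is N(mean, ·) with effective
    per-item SD ``s_eff`` (weight increments times level exceedances)."""
    total = 0.0
    for it in scale.items:
        w = it.weights
        for lev, t in enumerate(thresholds[it.item_id], start=1):
            total += (w[lev] - w[lev - 1]) * norm.sf(t, loc=mean, scale=s_eff)
    return total


def _sample_true_scores(cfg: CohortConfig, n: int, seed: int) -> np.ndarray:
    """True total scores only — used for intercept calibration."""
    scale = load_scale_definition()
    rng = np.random.default_rng(seed)
    sev = rng.normal(cfg.severity_mean, cfg.severity_sd, n)
    totals = np.zeros(n)
    for it in scale.items:
        u = sev + rng.normal(0.0, cfg.item_noise_sd, n)
        levels = np.searchsorted(np.asarray(cfg.item_thresholds[it.item_id]), u, side="right")
        totals += np.asarray(it.weights)[levels]
    return totals


def _calibrate_intercept(beta: float, target_rate: float, scores: np.ndarray) -> float:
    """Root-find the logistic intercept giving the target marginal event rate."""

    def gap(a: float) -> float:
        return float(np.mean(expit(a + beta * scores))) - target_rate

    return float(brentq(gap, -60.0, 60.0, xtol=1e-10))


@lru_cache(maxsize=1)
def _calibrated_defaults() -> CohortConfig:
    scale = load_scale_definition()
    base = CohortConfig.__dataclass_fields__
    severity_sd = base["severity_sd"].default
    item_noise_sd = base["item_noise_sd"].default
    thresholds = _default_thresholds(severity_sd, item_noise_sd)
    s_eff = float(np.hypot(severity_sd, item_noise_sd))
    mean = float(
        brentq(
            lambda m: _expected_total(m, thresholds, s_eff, scale) - _TARGET_MEAN_TOTAL,
            -3.0,
            3.0,
            xtol=1e-10,
        )
    )
    cfg = CohortConfig(severity_mean=mean, item_thresholds=thresholds)
    scores = _sample_true_scores(cfg, _CALIBRATION_N, _CALIBRATION_SEED)
    return dataclasses.replace(
        cfg,
        intercept_feeding=_calibrate_intercept(cfg.beta_feeding, _TARGET_ORAL_RATE, scores),
        intercept_pneumonia=_calibrate_intercept(
            cfg.beta_pneumonia, _TARGET_PNEUMONIA_RATE, scores
        ),
    )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The calibrated study-condition config (n=56, 38:18 split, published
    logistic slopes), with ``seed`` and any field overrides applied."""
    return dataclasses.replace(_calibrated_defaults(), seed=seed, **overrides)


def generate_cohort(
    config: CohortConfig, scale: ScaleDefinition | None = None
) -> list[PatientRecord]:
    """Draw a cohort. Deterministic given ``config`` (including its seed)."""
    scale = scale or load_scale_definition()
    config.validate(scale)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    sev = rng.normal(config.severity_mean, config.severity_sd, n)
    true_levels = np.zeros((n, len(scale.items)), dtype=int)
    for j, it in enumerate(scale.items):
        u = sev + rng.normal(0.0, config.item_noise_sd, n)
        true_levels[:, j] = np.searchsorted(
            np.asarray(config.item_thresholds[it.item_id]), u, side="right"
        )

    # PAS consistent with the true aspiration level; uniform within its band
    asp_j = list(scale.item_ids).index("aspiration")
    pas_pen = rng.integers(2, 6, n)
    pas_asp = rng.integers(6, 9, n)
    asp_level = true_levels[:, asp_j]
    pas = np.where(asp_level == 0, 1, np.where(asp_level == 1, pas_pen, pas_asp))

    # independent ±1 misclassification per rater and item, clamped
    rater_levels = []
    for _r in range(2):
        lev = true_levels.copy()
        flip = rng.random((n, len(scale.items))) < config.rater_noise
        direction = rng.integers(0, 2, (n, len(scale.items))) * 2 - 1
        lev = lev + flip * direction
        for j, it in enumerate(scale.items):
            lev[:, j] = np.clip(lev[:, j], 0, it.n_levels - 1)
        rater_levels.append(lev)

    weights = [np.asarray(it.weights) for it in scale.items]
    true_score = np.sum(
        [w[true_levels[:, j]] for j, w in enumerate(weights)], axis=0
    )

    p_oral = expit(config.intercept_feeding + config.beta_feeding * true_score)
    oral = rng.random(n) < p_oral
    p_pna = expit(config.intercept_pneumonia + config.beta_pneumonia * true_score)
    pna = rng.random(n) < p_pna
    supra = rng.random(n) < config.prop_supratentorial

    age = np.clip(np.rint(rng.normal(70.96, 14.456, n)), 18, 100).astype(int)
    male = rng.random(n) < config.prop_male
    mmse = np.clip(np.rint(rng.normal(15.25, 10.04, n)), 0, 30).astype(int)
    mbi = np.clip(np.rint(rng.normal(29.60, 21.62, n)), 0, 100).astype(int)
    duration = np.maximum(
        1, np.rint(rng.lognormal(np.log(255.0), 1.004, n))
    ).astype(int)

    ids = list(scale.item_ids)
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=i + 1,
                subgroup="supratentorial" if supra[i] else "infratentorial",
                rater1=RatingProfile({ids[j]: int(rater_levels[0][i, j]) for j in range(len(ids))}),
                rater2=RatingProfile({ids[j]: int(rater_levels[1][i, j]) for j in range(len(ids))}),
                true_profile=RatingProfile({ids[j]: int(true_levels[i, j]) for j in range(len(ids))}),
                pas=PASGrade(int(pas[i])),
                true_score=float(true_score[i]),
                feeding="oral" if oral[i] else "non_oral",
                pneumonia="yes" if pna[i] else "no",
                age=int(age[i]),
                sex="male" if male[i] else "female",
                mmse=int(mmse[i]),
                mbi=int(mbi[i]),
                duration_days=int(duration[i]),
            )
        )
    return records


_META_COLUMNS = [
    "patient_id",
    "subgroup",
    "age",
    "sex",
    "mmse",
    "mbi",
    "duration_days",
    "pas",
    "true_score",
    "feeding",
    "pneumonia",
]
COHORT_COLUMNS: list[str] = (
    _META_COLUMNS
    + [f"r1_{i}" for i in MVDS_ITEM_IDS]
    + [f"r2_{i}" for i in MVDS_ITEM_IDS]
    + [f"true_{i}" for i in MVDS_ITEM_IDS]
)

_SUBGROUPS = {"supratentorial", "infratentorial"}
_FEEDING = {"oral", "non_oral"}
_YESNO = {"yes", "no"}


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "subgroup": r.subgroup,
            "age": r.age,
            "sex": r.sex,
            "mmse": r.mmse,
            "mbi": r.mbi,
            "duration_days": r.duration_days,
            "pas": r.pas.value,
            "true_score": r.true_score,
            "feeding": r.feeding,
            "pneumonia": r.pneumonia,
        }
        for i in MVDS_ITEM_IDS:
            row[f"r1_{i}"] = r.rater1.levels[i]
            row[f"r2_{i}"] = r.rater2.levels[i]
            row[f"true_{i}"] = r.true_profile.levels[i]
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(
    df: pd.DataFrame, scale: ScaleDefinition | None = None
) -> list[PatientRecord]:
    """Validate a cohort table and rebuild records; raises
    :class:`CohortSchemaError` naming the offending column/row."""
    scale = scale or load_scale_definition()
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing columns: {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise CohortSchemaError(f"cohort table has unknown columns: {unknown}")

    def _int(row_i, col, value):
        f = float(value)
        if not float(f).is_integer():
            raise CohortSchemaError(f"row {row_i}: column {col!r} value {value!r} is not an integer")
        return int(f)

    records = []
    for row_i, (_, row) in enumerate(df.iterrows()):
        if row["subgroup"] not in _SUBGROUPS:
            raise CohortSchemaError(f"row {row_i}: bad subgroup {row['subgroup']!r}")
        if row["feeding"] not in _FEEDING:
            raise CohortSchemaError(f"row {row_i}: bad feeding {row['feeding']!r}")
        if row["pneumonia"] not in _YESNO:
            raise CohortSchemaError(f"row {row_i}: bad pneumonia {row['pneumonia']!r}")
        profiles = []
        for rater in ("r1", "r2", "true"):
            levels = {}
            for it in scale.items:
                col = f"{rater}_{it.item_id}"
                lev = _int(row_i, col, row[col])
                if not 0 <= lev < it.n_levels:
                    raise CohortSchemaError(
                        f"row {row_i}: item {it.item_id!r} ({col}) level {lev} "
                        f"out of range 0..{it.n_levels - 1}"
                    )
                levels[it.item_id] = lev
            profiles.append(RatingProfile(levels))
        pas_v = _int(row_i, "pas", row["pas"])
        if not 1 <= pas_v <= 8:
            raise CohortSchemaError(f"row {row_i}: PAS grade {pas_v} out of range 1..8")
        records.append(
            PatientRecord(
                patient_id=_int(row_i, "patient_id", row["patient_id"]),
                subgroup=str(row["subgroup"]),
                rater1=profiles[0],
                rater2=profiles[1],
                true_profile=profiles[2],
                pas=PASGrade(pas_v),
                true_score=float(row["true_score"]),
                feeding=str(row["feeding"]),
                pneumonia=str(row["pneumonia"]),
                age=_int(row_i, "age", row["age"]),
                sex=str(row["sex"]),
                mmse=_int(row_i, "mmse", row["mmse"]),
                mbi=_int(row_i, "mbi", row["mbi"]),
                duration_days=_int(row_i, "duration_days", row["duration_days"]),
            )
        )
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path, scale: ScaleDefinition | None = None) -> list[PatientRecord]:
    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise CohortSchemaError(f"cannot read cohort CSV {path}: {exc}") from exc
    return frame_to_cohort(df, scale=scale)


def rater_total_scores(
    records: Sequence[PatientRecord], scale: ScaleDefinition | None = None
) -> pd.DataFrame:
    """Total mVDS score per patient and rater, plus their mean.

    Returns a DataFrame with columns ``r1_total``, ``r2_total``, ``mean_total``.
    """
    scale = scale or load_scale_definition()
    r1 = [score_profile(r.rater1, scale).total for r in records]
    r2 = [score_profile(r.rater2, scale).total for r in records]
    out = pd.DataFrame({"r1_total": r1, "r2_total": r2})
    out["mean_total"] = (out["r1_total"] + out["r2_total"]) / 2
    return out


def check_pas_consistency(records: Sequence[PatientRecord]) -> bool:
    """True iff every patient's PAS grade maps onto their true aspiration level
    (rater profiles may disagree; the contract is on the noise-free truth)."""
    return all(
        pas_to_aspiration_level(r.pas) == r.true_profile.levels["aspiration"]
        for r in records
    )
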