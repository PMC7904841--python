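"""Seeded synthetic cohorts for the peritonsillar-abscess calprotectin study design.

The patient-level data behind the study (179 patients in six tonsil-related
diagnosis groups plus 15 healthy controls, with paired serum/saliva
calprotectin measured by the QUANTUM BLUE rapid test and by ELISA) is not
public.  This module generates cohorts with the statistical structure the
downstream analysis assumes:

* right-skewed (log-normal) calprotectin concentrations per (group, fluid),
  calibrated so that large-sample group means of the rapid-test channel
  approximate the published group means;
* a two-channel measurement model ``qbt = latent * bias * exp(eps_q)``,
  ``elisa = latent * exp(eps_e)`` with independent log-scale noises, giving
  the rapid test a slight positive bias over ELISA and an excellent rank
  correlation between the channels;
* per-group Bernoulli symptom prevalences chosen so simulated mean adjusted
  PTA scores fall near the published group means.

Identical :class:`CohortConfig` (including seed) yields a bit-identical cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SYMPTOMS",
    "FLUIDS",
    "COHORT_CSV_COLUMNS",
    "LogNormalParams",
    "CohortConfig",
    "PatientRecord",
    "default_config",
    "generate_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "records_from_frame",
]

#: Diagnosis groups, in the fixed generation order.
GROUPS = (
    "control",
    "tonsil_hyperplasia",
    "recurrent_tonsillitis",
    "acute_tonsillitis",
    "mononucleosis",
    "peritonsillitis",
    "pta",
)

#: The four clinical criteria of the PTA score.
SYMPTOMS = ("trismus", "halitosis", "uvula_edema", "unilateral_swelling")

FLUIDS = ("serum", "saliva")

#: Exact cohort CSV header (booleans as 0/1, missing as empty field, ng/ml).
COHORT_CSV_COLUMNS = [
    "patient_id",
    "group",
    "age",
    "sex",
    "trismus",
    "halitosis",
    "uvula_edema",
    "unilateral_swelling",
    "serum_qbt",
    "serum_elisa",
    "saliva_qbt",
    "saliva_elisa",
]


@dataclass(frozen=True)
class LogNormalParams:
    """Location/scale of a log-normal latent concentration (natural-log scale)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"log-normal sigma must be > 0, got {self.sigma}")

    @property
    def mean(self) -> float:
        """Arithmetic mean of the log-normal, exp(mu + sigma^2/2)."""
        return math.exp(self.mu + self.sigma**2 / 2.0)

    @staticmethod
    def from_mean_cv(mean: float, cv: float) -> "LogNormalParams":
        """Back-solve (mu, sigma) from an arithmetic mean and coefficient of variation."""
        if mean <= 0 or cv <= 0:
            raise ValueError("mean and cv must be positive")
        sigma2 = math.log(1.0 + cv**2)
        return LogNormalParams(mu=math.log(mean) - sigma2 / 2.0, sigma=math.sqrt(sigma2))


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``conc_params[group][fluid]`` parameterises the latent true concentration;
    the measured channels are derived from it via ``qbt_bias_factor`` and the
    two log-scale noise SDs.  ``symptom_prev[group][symptom]`` are independent
    Bernoulli probabilities.  ``age_range`` and ``sex_ratio`` (probability of
    male) are descriptive only and never enter the analysis.
    """

    seed: int = 0
    group_sizes: dict = field(default_factory=dict)
    conc_params: dict = field(default_factory=dict)
    qbt_bias_factor: float = 1.15
    qbt_noise_sd: float = 0.35
    elisa_noise_sd: float = 0.25
    symptom_prev: dict = field(default_factory=dict)
    age_range: dict = field(default_factory=dict)
    sex_ratio: dict = field(default_factory=dict)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"group size for {g!r} must be a non-negative integer, got {n}")
        if not self.qbt_bias_factor > 0:
            raise ValueError("qbt_bias_factor must be > 0")
        if self.qbt_noise_sd < 0 or self.elisa_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for g, per_fluid in self.conc_params.items():
            for fl, p in per_fluid.items():
                if fl not in FLUIDS:
                    raise ValueError(f"unknown fluid {fl!r}")
                if not isinstance(p, LogNormalParams):
                    raise TypeError("conc_params values must be LogNormalParams")
        for g, per_sym in self.symptom_prev.items():
            for s, p in per_sym.items():
                if s not in SYMPTOMS:
                    raise ValueError(f"unknown symptom {s!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"symptom prevalence must be in [0,1], got {p}")
        for g, ratio in self.sex_ratio.items():
            if not 0.0 <= ratio <= 1.0:
                raise ValueError("sex_ratio must be in [0,1]")

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conc_params"] = {
            g: {fl: {"mu": p.mu, "sigma": p.sigma} for fl, p in per.items()}
            for g, per in self.conc_params.items()
        }
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["conc_params"] = {
            g: {fl: LogNormalParams(**p) for fl, p in per.items()}
            for g, per in d.get("conc_params", {}).items()
        }
        d["age_range"] = {g: tuple(v) for g, v in d.get("age_range", {}).items()}
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class PatientRecord:
    """One subject: diagnosis group, four binary symptoms, paired two-method
    serum/saliva calprotectin (ng/ml).  Missing fields are ``None``."""

    patient_id: str
    group: str
    age: int
    sex: str
    trismus: Optional[bool]
    halitosis: Optional[bool]
    uvula_edema: Optional[bool]
    unilateral_swelling: Optional[bool]
    serum_qbt: Optional[float]
    serum_elisa: Optional[float]
    saliva_qbt: Optional[float]
    saliva_elisa: Optional[float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"invalid diagnosis group {self.group!r}")
        for name in ("serum_qbt", "serum_elisa", "saliva_qbt", "saliva_elisa"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive when present, got {v}")


# --------------------------------------------------------------------------
# Default calibration
# --------------------------------------------------------------------------

#: Published group sizes: 179 patients + 15 healthy controls.
_DEFAULT_GROUP_SIZES = {
    "control": 15,
    "tonsil_hyperplasia": 16,
    "recurrent_tonsillitis": 71,
    "acute_tonsillitis": 15,
    "mononucleosis": 10,
    "peritonsillitis": 16,
    "pta": 36,
}

# Target rapid-test (QBT) group means in ng/ml.  Control and PTA values are
# the published means; the intermediate groups are plausible interpolations
# (the study prints no concentrations for them) ordered by clinical severity.
_TARGET_QBT_MEAN = {
    "control": {"serum": 780.0, "saliva": 3386.0},
    "tonsil_hyperplasia": {"serum": 900.0, "saliva": 3800.0},
    "recurrent_tonsillitis": {"serum": 1200.0, "saliva": 4500.0},
    "acute_tonsillitis": {"serum": 2500.0, "saliva": 6500.0},
    "mononucleosis": {"serum": 2800.0, "saliva": 7500.0},
    "peritonsillitis": {"serum": 3200.0, "saliva": 9000.0},
    "pta": {"serum": 5745.0, "saliva": 25825.0},
}

# Coefficients of variation.  Where the study prints mean +/- SEM the CV is
# back-solved from SD = SEM * sqrt(n); elsewhere a default of 1.0 (typical for
# inflammatory biomarkers) is used.
_TARGET_CV = {
    "control": {"serum": 0.51, "saliva": 1.30},
    "pta": {"serum": 0.86, "saliva": 1.38},
}
_DEFAULT_CV = 1.0

# Per-group symptom prevalences (trismus, halitosis, uvula edema, unilateral
# swelling).  Not printed in the study; chosen so simulated mean adjusted PTA
# scores approximate the published group means (PTA 4.1, peritonsillitis 2.6,
# acute tonsillitis 1.5).
_DEFAULT_SYMPTOM_PREV = {
    "control": {"trismus": 0.00, "halitosis": 0.02, "uvula_edema": 0.00, "unilateral_swelling": 0.00},
    "tonsil_hyperplasia": {"trismus": 0.02, "halitosis": 0.10, "uvula_edema": 0.02, "unilateral_swelling": 0.01},
    "recurrent_tonsillitis": {"trismus": 0.05, "halitosis": 0.15, "uvula_edema": 0.05, "unilateral_swelling": 0.02},
    "acute_tonsillitis": {"trismus": 0.20, "halitosis": 0.20, "uvula_edema": 0.20, "unilateral_swelling": 0.20},
    "mononucleosis": {"trismus": 0.15, "halitosis": 0.30, "uvula_edema": 0.15, "unilateral_swelling": 0.05},
    "peritonsillitis": {"trismus": 0.45, "halitosis": 0.35, "uvula_edema": 0.45, "unilateral_swelling": 0.40},
    "pta": {"trismus": 0.70, "halitosis": 0.60, "uvula_edema": 0.65, "unilateral_swelling": 0.60},
}

# Descriptive demographics from the published medians/ranges.
_DEFAULT_AGE_RANGE = {
    "control": (26, 59),
    "tonsil_hyperplasia": (2, 32),
    "recurrent_tonsillitis": (7, 59),
    "acute_tonsillitis": (13, 65),
    "mononucleosis": (18, 59),
    "peritonsillitis": (7, 66),
    "pta": (10, 83),
}


def default_config(seed: int = 0) -> CohortConfig:
    """Cohort configuration matching the study's group structure and calibration.

    Latent log-normal parameters are back-solved so that the *measured*
    rapid-test channel (latent x bias x log-normal noise) has the target group
    mean: ``E[qbt] = E[latent] * bias * exp(sd_q^2 / 2)``.
    """
    cfg = CohortConfig(seed=seed, group_sizes=dict(_DEFAULT_GROUP_SIZES))
    meas_factor = cfg.qbt_bias_factor * math.exp(cfg.qbt_noise_sd**2 / 2.0)
    conc = {}
    for g in GROUPS:
        conc[g] = {}
        for fl in FLUIDS:
            cv = _TARGET_CV.get(g, {}).get(fl, _DEFAULT_CV)
            latent_mean = _TARGET_QBT_MEAN[g][fl] / meas_factor
            conc[g][fl] = LogNormalParams.from_mean_cv(latent_mean, cv)
    cfg.conc_params = conc
    cfg.symptom_prev = {g: dict(p) for g, p in _DEFAULT_SYMPTOM_PREV.items()}
    cfg.age_range = dict(_DEFAULT_AGE_RANGE)
    cfg.sex_ratio = {g: 0.47 for g in GROUPS}  # 84 male / 179 patients overall
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a cohort.  One named random stream from ``config.seed``; groups are
    generated in the fixed :data:`GROUPS` order so identical configs give
    identical cohorts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    counter = 0
    for g in GROUPS:
        n = int(config.group_sizes.get(g, 0))
        for _ in range(n):
            counter += 1
            lo, hi = config.age_range.get(g, (18, 65))
            age = int(rng.integers(lo, hi + 1))
            sex = "m" if rng.random() < config.sex_ratio.get(g, 0.5) else "f"

            conc: dict[str, float] = {}
            for fl in FLUIDS:
                p = config.conc_params[g][fl]
                latent = float(rng.lognormal(mean=p.mu, sigma=p.sigma))
                eps_q = float(rng.normal(0.0, config.qbt_noise_sd)) if config.qbt_noise_sd else 0.0
                eps_e = float(rng.normal(0.0, config.elisa_noise_sd)) if config.elisa_noise_sd else 0.0
                conc[f"{fl}_qbt"] = latent * config.qbt_bias_factor * math.exp(eps_q)
                conc[f"{fl}_elisa"] = latent * math.exp(eps_e)

            symptoms = {
                s: bool(rng.random() < config.symptom_prev.get(g, {}).get(s, 0.0))
                for s in SYMPTOMS
            }

            fields: dict = {**symptoms, **conc}
            if config.missing_rate > 0.0:
                for name in list(fields):
                    if rng.random() < config.missing_rate:
                        fields[name] = None

            records.append(
                PatientRecord(
                    patient_id=f"P{counter:04d}",
                    group=g,
                    age=age,
                    sex=sex,
                    **fields,
                )
            )
    return records


# --------------------------------------------------------------------------
# CSV interface
# --------------------------------------------------------------------------


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Tabulate records with the exact cohort CSV column order."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in COHORT_CSV_COLUMNS}
        for s in SYMPTOMS:
            row[s] = None if row[s] is None else int(row[s])
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    """Write the cohort CSV: booleans as 0/1, missing as empty field."""
    df = cohort_to_frame(records)
    # Integer-format boolean columns even when some values are missing.
    for s in SYMPTOMS:
        df[s] = df[s].astype("Int64")
    df.to_csv(path, index=False, float_format="%.6f")


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the expected schema."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending column."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort CSV is missing required column(s): {', '.join(missing)}")
    bad_groups = set(df["group"].dropna()) - set(GROUPS)
    if bad_groups:
        raise CohortSchemaError(f"column 'group' contains invalid values: {sorted(bad_groups)}")
    for col in ("serum_qbt", "serum_elisa", "saliva_qbt", "saliva_elisa"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if ((vals <= 0) & df[col].notna()).any():
            raise CohortSchemaError(f"column {col!r} contains non-positive concentrations")
        df[col] = vals
    return df[COHORT_CSV_COLUMNS]


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Rehydrate :class:`PatientRecord` objects from a validated cohort table."""
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"patient_id": str(row["patient_id"]), "group": row["group"],
                        "age": int(row["age"]), "sex": str(row["sex"])}
        for s in SYMPTOMS:
            v = row[s]
            kwargs[s] = None if pd.isna(v) else bool(int(v))
        for c in ("serum_qbt", "serum_elisa", "saliva_qbt", "saliva_elisa"):
            v = row[c]
            kwargs[c] = None if pd.isna(v) else float(v)
        records.append(PatientRecord(**kwargs))
    return records
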