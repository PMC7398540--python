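"""Person-level ingestion, energy partition, inclusion filtering and BMI classes.

Each agent carries a static demographic profile (sex, age, height) and two
observed weights roughly two years apart, plus a 3-day mean daily energy
intake. Under the equilibrium assumption the intake equals total energy
expenditure (TEE), which splits into resting energy expenditure (REE,
estimated by sex-specific Harris-Benedict-type equations), the thermic
effect of food (TEF, 10% of TEE) and physical-activity energy (the
remainder). Rows with implausible weights, REE/TEE fractions outside
0.60-0.75, or extreme biennial weight change are excluded before
simulation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Person",
    "EnergyProfile",
    "FilterCriteria",
    "FilterReport",
    "read_population",
    "compute_ree",
    "partition_energy",
    "apply_inclusion_filters",
    "classify_bmi",
    "bmi",
]

#: BMI category labels under the Chinese cutoffs (24 and 28 kg/m^2).
UNDERWEIGHT_OR_NORMAL = "underweight-or-normal"
OVERWEIGHT = "overweight"
OBESE = "obese"

#: Chinese BMI cutoffs, lower than the WHO 25/30 because obesity-related
#: disease risk rises at lower BMI in Chinese adults.
BMI_OVERWEIGHT_CUTOFF = 24.0
BMI_OBESE_CUTOFF = 28.0


@dataclasses.dataclass(frozen=True)
class Person:
    """One individual's static profile.

    Attributes
    ----------
    id : object
        Opaque identifier (survey id or synthetic index).
    age : int
        Age in years at baseline.
    sex : str
        ``"male"`` or ``"female"``.
    height_m : float
        Standing height in metres.
    bw0 : float
        Baseline body weight, kg.
    bw1 : float or None
        Follow-up body weight two years later, kg; ``None`` when unobserved.
    ei : float
        3-day mean daily energy intake, kcal/day.
    """

    id: object
    age: int
    sex: str
    height_m: float
    bw0: float
    bw1: Optional[float]
    ei: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.height_m <= 0:
            raise ValueError(f"height_m must be > 0, got {self.height_m}")
        if self.bw0 < 0:
            raise ValueError(f"bw0 must be >= 0, got {self.bw0}")
        if self.ei < 0:
            raise ValueError(f"ei must be >= 0, got {self.ei}")


@dataclasses.dataclass(frozen=True)
class EnergyProfile:
    """Three-component partition of total energy expenditure, kcal/day."""

    ree: float
    tef: float
    pa: float
    tee: float


@dataclasses.dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria applied sequentially to the raw sample."""

    min_age: int = 24
    abnormal_bw: frozenset = frozenset({0.0, 5.8})
    ree_fraction_low: float = 0.60
    ree_fraction_high: float = 0.75
    max_abs_change_rate: float = 0.30
    #: abnormal weights are matched at this precision (kg)
    bw_precision: float = 0.1


@dataclasses.dataclass
class FilterReport:
    """Per-filter exclusion counts; each row is counted at its first failure."""

    n_input: int = 0
    n_excluded_age: int = 0
    n_excluded_bw: int = 0
    n_excluded_ree_fraction: int = 0
    n_excluded_weight_change: int = 0
    n_excluded_missing_bw1: int = 0
    n_included: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(dataclasses.asdict(self)), "count": list(dataclasses.asdict(self).values())}
        )


# ---------------------------------------------------------------------------
# ingestion

_GENDER_MAP = {
    "male": "male", "m": "male", "man": "male", "1": "male",
    "female": "female", "f": "female", "woman": "female", "2": "female",
}

#: Accepted header aliases, lower-cased. The first matching alias wins.
COLUMN_ALIASES = {
    "id": ("id", "idind", "person_id", "pid"),
    "age": ("age", "age_y", "age_years"),
    "sex": ("sex", "gender"),
    "height": ("height", "height_m", "height_cm", "ht"),
    "bw0": ("bw0", "weight", "weight0", "bw_wave8", "weight_2009", "baseline_weight"),
    "bw1": ("bw1", "weight1", "bw_wave9", "weight_2011", "followup_weight"),
    "ei": ("ei", "energy_intake", "intake", "kcal", "energy"),
}


def _resolve_columns(columns: Sequence[str]) -> dict:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for field, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[field] = lower[alias]
                break
    missing = [f for f in ("id", "age", "sex", "height", "bw0", "ei") if f not in resolved]
    if missing:
        raise ValueError(
            f"population table is missing required column(s) {missing}; "
            f"accepted aliases: { {m: COLUMN_ALIASES[m] for m in missing} }"
        )
    return resolved


def _normalize_height(value: float) -> float:
    # heights >= 100 are centimetres (nobody is 100 m tall), < 3 are metres
    return value / 100.0 if value >= 100.0 else value


def read_population(path, fmt: Optional[str] = None) -> list:
    """Read a person-level table from CSV or XLSX into a list of ``Person``.

    Gender strings are normalized to ``male``/``female``; heights are accepted
    in metres or centimetres and normalized to metres. A missing or blank
    follow-up weight becomes ``None``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        df = pd.read_excel(path)
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'xlsx'")
    return persons_from_frame(df)


def persons_from_frame(df: pd.DataFrame) -> list:
    """Convert a dataframe with recognized headers into ``Person`` records."""
    cols = _resolve_columns(df.columns)
    persons = []
    for _, row in df.iterrows():
        rid = row[cols["id"]]
        try:
            sex_raw = str(row[cols["sex"]]).strip().lower()
            sex = _GENDER_MAP.get(sex_raw)
            if sex is None:
                raise ValueError(f"unrecognized gender {sex_raw!r}")
            bw1 = None
            if "bw1" in cols:
                v = row[cols["bw1"]]
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    bw1 = float(v)
            persons.append(
                Person(
                    id=rid,
                    age=int(row[cols["age"]]),
                    sex=sex,
                    height_m=_normalize_height(float(row[cols["height"]])),
                    bw0=float(row[cols["bw0"]]),
                    bw1=bw1,
                    ei=float(row[cols["ei"]]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row with id {rid!r}: {exc}") from exc
    return persons


def persons_to_frame(persons: Iterable[Person]) -> pd.DataFrame:
    """Inverse of :func:`persons_from_frame`, with canonical column names."""
    return pd.DataFrame(
        {
            "id": [p.id for p in persons],
            "age": [p.age for p in persons],
            "sex": [p.sex for p in persons],
            "height_m": [p.height_m for p in persons],
            "bw0": [p.bw0 for p in persons],
            "bw1": [p.bw1 for p in persons],
            "ei": [p.ei for p in persons],
        }
    )


# ---------------------------------------------------------------------------
# energy partition

def compute_ree(sex: str, bw: float, height_cm: float, age: float) -> float:
    """Resting energy expenditure (kcal/day), Harris-Benedict-type equations.

    Height is in centimetres (the coefficient scale of the published
    equations). May return a negative value for extreme inputs; callers
    filter such rows out.
    """
    if sex == "male":
        return 66.5 + 13.6 * bw + 5.0 * height_cm - 6.8 * age
    if sex == "female":
        return 655.1 + 9.5 * bw + 1.8 * height_cm - 4.1 * age
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def partition_energy(person: Person) -> EnergyProfile:
    """Split intake into REE + TEF + activity under the equilibrium assumption.

    At equilibrium TEE equals intake; TEF is 10% of TEE; activity energy is
    the remainder and may be negative for implausible rows (the REE/TEE
    inclusion filter removes those).
    """
    tee = person.ei
    tef = 0.10 * tee
    ree = compute_ree(person.sex, person.bw0, person.height_m * 100.0, person.age)
    pa = tee - ree - tef
    if tee == 0:
        return EnergyProfile(ree=ree, tef=0.0, pa=0.0, tee=0.0)
    return EnergyProfile(ree=ree, tef=tef, pa=pa, tee=tee)


# ---------------------------------------------------------------------------
# inclusion filters

def apply_inclusion_filters(persons, criteria: FilterCriteria = FilterCriteria()):
    """Apply the sequential inclusion filters; each row is counted once.

    Order: (1) minimum age; (2) abnormal baseline weight; (3) REE/TEE
    fraction outside [0.60, 0.75]; (4) biennial weight-change rate outside
    +/-30% (rows lacking a follow-up weight are excluded here with their own
    count). Returns ``(included, FilterReport)``.
    """
    report = FilterReport(n_input=len(persons))
    included = []
    prec = criteria.bw_precision
    for p in persons:
        if p.age < criteria.min_age:
            report.n_excluded_age += 1
            continue
        if any(abs(p.bw0 - a) < prec / 2 for a in criteria.abnormal_bw):
            report.n_excluded_bw += 1
            continue
        profile = partition_energy(p)
        if profile.tee <= 0:
            report.n_excluded_ree_fraction += 1
            continue
        frac = profile.ree / profile.tee
        if not (criteria.ree_fraction_low <= frac <= criteria.ree_fraction_high):
            report.n_excluded_ree_fraction += 1
            continue
        if p.bw1 is None:
            report.n_excluded_missing_bw1 += 1
            continue
        rate = (p.bw1 - p.bw0) / p.bw0
        if not (-criteria.max_abs_change_rate <= rate <= criteria.max_abs_change_rate):
            report.n_excluded_weight_change += 1
            continue
        included.append(p)
    report.n_included = len(included)
    return included, report


# ---------------------------------------------------------------------------
# BMI

def bmi(bw: float, height_m: float) -> float:
    if height_m <= 0:
        raise ValueError(f"height_m must be > 0, got {height_m}")
    return bw / height_m**2


def classify_bmi(bw: float, height_m: float) -> str:
    """Classify BMI under the Chinese cutoffs: overweight [24, 28), obese >= 28."""
    b = bmi(bw, height_m)
    if b >= BMI_OBESE_CUTOFF:
        return OBESE
    if b >= BMI_OVERWEIGHT_CUTOFF:
        return OVERWEIGHT
    return UNDERWEIGHT_OR_NORMAL
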