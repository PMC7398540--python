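"""Synthetic populations with the marginal structure of the study sample.

The generator emulates a community sample of 2197 Chinese adults: ages
24-88, 44.9% male, heights 1.30-1.88 m, mean BMI about 24 kg/m^2 with
36.6% overweight and 13.0% obese under the Chinese cutoffs, and energy
intake consistent with equilibrium (REE between 60% and 75% of total
expenditure). BMI is drawn from a three-component truncated-normal mixture
whose strata are the BMI categories; weight follows as BMI * height^2.
Attributes are sampled independently beyond these constructions — the real
joint distribution of age, BMI and intake is not modelled.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import truncnorm

from .population import (
    Person,
    bmi,
    compute_ree,
    BMI_OVERWEIGHT_CUTOFF,
    BMI_OBESE_CUTOFF,
    persons_to_frame,
)

__all__ = ["SyntheticSpec", "SummaryStats", "generate_population", "marginal_report"]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults reproduce the study sample's marginals."""

    n: int = 2197
    male_fraction: float = 0.449
    age_range: Tuple[int, int] = (24, 88)
    #: per-sex height mean/sd in metres; all heights truncated to height_bounds
    height_mean_male: float = 1.67
    height_mean_female: float = 1.56
    height_sd: float = 0.06
    height_bounds: Tuple[float, float] = (1.30, 1.88)
    #: BMI mixture: strata [15,24), [24,28), [28,45) with weights
    #: (1 - p_overweight - p_obese, p_overweight, p_obese). Component
    #: locations were chosen once so the mixture mean is ~24 kg/m^2.
    p_overweight: float = 0.366
    p_obese: float = 0.130
    bmi_components: Tuple[Tuple[float, float, float, float], ...] = (
        (15.0, 24.0, 21.45, 2.2),  # (low, high, loc, scale)
        (24.0, 28.0, 25.8, 1.6),
        (28.0, 45.0, 29.8, 2.0),
    )
    ree_fraction_range: Tuple[float, float] = (0.60, 0.75)
    #: optional biennial weight change: None keeps bw1 = bw0 (all filters
    #: pass); a (mean, sd) pair adds Gaussian change in kg, truncated so the
    #: +/-30% change-rate filter still passes.
    biennial_change: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must be in [0, 1]")
        if self.p_overweight < 0 or self.p_obese < 0 or self.p_overweight + self.p_obese > 1:
            raise ValueError("BMI stratum probabilities must be >= 0 and sum to <= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be ordered")
        if self.height_bounds[0] >= self.height_bounds[1]:
            raise ValueError("height_bounds must be ordered")


@dataclasses.dataclass(frozen=True)
class SummaryStats:
    n: int
    male_fraction: float
    age_range: Tuple[int, int]
    height_range: Tuple[float, float]
    weight_range: Tuple[float, float]
    mean_bmi: float
    overweight_pct: float
    obese_pct: float


def _truncated_normal(rng, lo, hi, loc, scale, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_population(spec: SyntheticSpec = SyntheticSpec()) -> List[Person]:
    """Draw ``spec.n`` persons; deterministic for a given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if n == 0:
        return []
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    lo, hi = spec.height_bounds
    height = np.empty(n)
    for s, mean in (("male", spec.height_mean_male), ("female", spec.height_mean_female)):
        mask = sex == s
        height[mask] = _truncated_normal(rng, lo, hi, mean, spec.height_sd, mask.sum())

    weights = np.array([1.0 - spec.p_overweight - spec.p_obese, spec.p_overweight, spec.p_obese])
    stratum = rng.choice(3, size=n, p=weights)
    bmi_vals = np.empty(n)
    for k, (blo, bhi, loc, scale) in enumerate(spec.bmi_components):
        mask = stratum == k
        if mask.any():
            bmi_vals[mask] = _truncated_normal(rng, blo, bhi, loc, scale, mask.sum())
    bw0 = bmi_vals * height**2

    frac = rng.uniform(*spec.ree_fraction_range, size=n)
    ree = np.array(
        [compute_ree(s, w, h * 100.0, a) for s, w, h, a in zip(sex, bw0, height, age)]
    )
    tee = ree / frac  # equilibrium: intake equals expenditure
    if spec.biennial_change is None:
        bw1 = bw0.copy()
    else:
        mu, sd = spec.biennial_change
        delta = rng.normal(mu, sd, size=n)
        delta = np.clip(delta, -0.29 * bw0, 0.29 * bw0)
        bw1 = bw0 + delta

    return [
        Person(
            id=i,
            age=int(age[i]),
            sex=str(sex[i]),
            height_m=float(height[i]),
            bw0=round(float(bw0[i]), 3),
            bw1=round(float(bw1[i]), 3),
            ei=round(float(tee[i]), 3),
        )
        for i in range(n)
    ]


def marginal_report(persons) -> SummaryStats:
    """Summary marginals (counts, ranges, mean BMI, prevalence) of a sample."""
    if not persons:
        raise ValueError("marginal_report requires a non-empty population")
    bmis = np.array([bmi(p.bw0, p.height_m) for p in persons])
    heights = np.array([p.height_m for p in persons])
    weights = np.array([p.bw0 for p in persons])
    ages = np.array([p.age for p in persons])
    n = len(persons)
    return SummaryStats(
        n=n,
        male_fraction=sum(p.sex == "male" for p in persons) / n,
        age_range=(int(ages.min()), int(ages.max())),
        height_range=(float(heights.min()), float(heights.max())),
        weight_range=(float(weights.min()), float(weights.max())),
        mean_bmi=float(bmis.mean()),
        overweight_pct=100.0 * float(((bmis >= BMI_OVERWEIGHT_CUTOFF) & (bmis < BMI_OBESE_CUTOFF)).mean()),
        obese_pct=100.0 * float((bmis >= BMI_OBESE_CUTOFF).mean()),
    )


def write_population_csv(persons, path) -> None:
    """Write the canonical CSV schema that :func:`read_population` accepts."""
    persons_to_frame(persons).to_csv(path, index=False)
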