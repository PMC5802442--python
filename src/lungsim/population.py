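"""Synthetic multi-birth-cohort population with smoking histories.

Stands in for Census projections plus a smoking-history generator: each person
gets a birth year (geometric cohort growth), sex, and a smoking career
(initiation age, constant cigarettes/day, cessation age) drawn from
birth-cohort- and sex-specific parameters. Later cohorts initiate less, which
is the mechanism that makes screening yield decline over the simulated horizon.

Competing mortality is a Gompertz baseline multiplied by a smoking-status
hazard ratio, piecewise-constant along the person's own never/current/former
trajectory, sampled exactly by inverting the piecewise cumulative hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._rng import STREAMS, substream
from .config import MortalityParams, PopulationConfig, SmokingParams

NEVER, CURRENT, FORMER = "never", "current", "former"


@dataclass(frozen=True)
class SmokingHistory:
    """Initiation/cessation ages and constant smoking intensity.

    ``initiation_age is None`` means a never smoker (then ``cessation_age``
    must be None and ``cigarettes_per_day`` 0).
    """

    initiation_age: Optional[float] = None
    cessation_age: Optional[float] = None
    cigarettes_per_day: float = 0.0

    def __post_init__(self):
        if self.initiation_age is None:
            if self.cessation_age is not None:
                raise ValueError("never smoker cannot have a cessation age")
            if self.cigarettes_per_day != 0.0:
                raise ValueError("never smoker must have 0 cigarettes/day")
        else:
            if self.cigarettes_per_day <= 0.0:
                raise ValueError("ever smoker must have positive cigarettes/day")
            if self.cessation_age is not None and self.cessation_age <= self.initiation_age:
                raise ValueError("cessation age must exceed initiation age")

    @property
    def is_never(self) -> bool:
        return self.initiation_age is None


def pack_years_at(history: SmokingHistory, age: float) -> float:
    """Cumulative pack-years by ``age`` (one pack = 20 cigarettes/day for a year)."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if history.is_never or age <= history.initiation_age:
        return 0.0
    stop = age if history.cessation_age is None else min(age, history.cessation_age)
    return (history.cigarettes_per_day / 20.0) * (stop - history.initiation_age)


def smoker_status_at(history: SmokingHistory, age: float) -> str:
    """Never/current/former status at an age."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if history.is_never or age < history.initiation_age:
        return NEVER
    if history.cessation_age is None or age < history.cessation_age:
        return CURRENT
    return FORMER


def quit_years_at(history: SmokingHistory, age: float) -> Optional[float]:
    """Years since cessation at ``age``; None unless a former smoker at that age."""
    if smoker_status_at(history, age) != FORMER:
        return None
    return age - history.cessation_age


@dataclass(frozen=True)
class PersonRecord:
    """One simulated individual plus the coupling contract.

    ``adherence_uniform`` is the single uniform draw thresholded by the
    adherence rate (nested-adherence coupling); named random substreams are
    reproducible from ``(master_seed, person_id, stream)``.
    """

    person_id: int
    sex: str                 # "M" / "F"
    birth_year: int
    smoking: SmokingHistory
    adherence_uniform: float
    master_seed: int

    def rng(self, stream: str) -> np.random.Generator:
        return substream(self.master_seed, self.person_id, stream)

    @property
    def substream_seeds(self) -> dict[str, tuple[int, int, int]]:
        return {name: (self.master_seed, self.person_id, code)
                for name, code in STREAMS.items()}

    def age_in(self, year: int) -> int:
        """Age at the start of a calendar year."""
        return year - self.birth_year


def sample_smoking_history(birth_year: int, sex: str, params: SmokingParams,
                           rng: np.random.Generator) -> SmokingHistory:
    """Draw one smoking career for a (birth cohort, sex) cell.

    Ever-smoking is a Bernoulli draw at the cohort's initiation probability;
    initiation age is truncated normal, intensity lognormal, and cessation a
    geometric wait at the annual cessation probability (never realized when
    that probability is 0 or the implied age exceeds ``max_cessation_age``).
    """
    p_init = params.initiation_probability(birth_year, sex)
    if rng.random() >= p_init:
        return SmokingHistory()
    # truncated-normal initiation age by rejection (bounds are wide; cheap)
    while True:
        a = rng.normal(params.init_age_mean, params.init_age_sd)
        if params.init_age_min <= a <= params.init_age_max:
            break
    cpd = float(np.clip(rng.lognormal(math.log(params.cpd_median(sex, birth_year)),
                                      params.cpd_sigma), 1.0, params.cpd_max))
    cessation: Optional[float] = None
    p_quit = params.cessation_probability(birth_year)
    if p_quit > 0.0:
        years_smoked = int(rng.geometric(p_quit))
        cess = a + years_smoked
        if cess <= params.max_cessation_age:
            cessation = cess
    return SmokingHistory(initiation_age=float(a), cessation_age=cessation,
                          cigarettes_per_day=cpd)


def _cohort_distribution(config: PopulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.birth_year_span
    years = np.arange(lo, hi + 1)
    w = np.power(1.0 + config.cohort_growth_rate, years - lo)
    return years, w / w.sum()


def build_population(config: PopulationConfig, params: SmokingParams) -> list[PersonRecord]:
    """Generate the simulated population, reproducible from the master seed."""
    config.validate()
    params.validate()
    birth_years, probs = _cohort_distribution(config)
    cdf = np.cumsum(probs)
    persons: list[PersonRecord] = []
    for pid in range(config.n_persons):
        rng = substream(config.master_seed, pid, "build")
        u_birth, u_sex, u_adh = rng.random(3)
        birth_year = int(birth_years[np.searchsorted(cdf, u_birth, side="right")])
        sex = "M" if u_sex < config.sex_fraction_male else "F"
        smoking = sample_smoking_history(birth_year, sex, params, rng)
        persons.append(PersonRecord(person_id=pid, sex=sex, birth_year=birth_year,
                                    smoking=smoking, adherence_uniform=float(u_adh),
                                    master_seed=config.master_seed))
    return persons


def _invert_piecewise_gompertz(a: float, b: float,
                               segments: list[tuple[float, float, float]],
                               target: float) -> float:
    """Solve H(t) = target for a Gompertz hazard a*exp(b*t) with piecewise
    multipliers; ``segments`` are (t0, t1, multiplier) covering [0, inf)."""
    acc = 0.0
    for t0, t1, m in segments:
        seg = m * (a / b) * (math.exp(b * t1) - math.exp(b * t0)) if math.isfinite(t1) else math.inf
        if acc + seg >= target or not math.isfinite(t1):
            return (1.0 / b) * math.log(math.exp(b * t0) + b * (target - acc) / (a * m))
        acc += seg
    raise AssertionError("unreachable: last segment is unbounded")


def _status_segments(history: SmokingHistory, mort: MortalityParams) -> list[tuple[float, float, float]]:
    if history.is_never:
        return [(0.0, math.inf, mort.hr_never)]
    init = history.initiation_age
    if history.cessation_age is None:
        return [(0.0, init, mort.hr_never), (init, math.inf, mort.hr_current)]
    cess = history.cessation_age
    return [(0.0, init, mort.hr_never), (init, cess, mort.hr_current),
            (cess, math.inf, mort.hr_former)]


def cumulative_other_cause_hazard(history: SmokingHistory, mort: MortalityParams,
                                  age: float) -> float:
    """Closed-form cumulative competing-mortality hazard to ``age``."""
    a, b = mort.gompertz_rate, mort.gompertz_shape
    total = 0.0
    for t0, t1, m in _status_segments(history, mort):
        hi = min(t1, age)
        if hi <= t0:
            break
        total += m * (a / b) * (math.exp(b * hi) - math.exp(b * t0))
    return total


def sample_other_cause_death_age(person: PersonRecord, mort: MortalityParams,
                                 rng: Optional[np.random.Generator] = None,
                                 entry_age: float = 0.0) -> float:
    """Draw the non-lung-cancer death age for one person.

    Conditioning on survival to ``entry_age`` (the person's age at the study
    start) is done exactly by shifting the exponential threshold by the
    cumulative hazard already survived. The result is capped at ``max_age``.
    """
    if rng is None:
        rng = person.rng("other_cause")
    segments = _status_segments(person.smoking, mort)
    target = cumulative_other_cause_hazard(person.smoking, mort, entry_age)
    target += rng.exponential()
    t = _invert_piecewise_gompertz(mort.gompertz_rate, mort.gompertz_shape,
                                   segments, target)
    return min(t, mort.max_age)


def population_to_frame(persons: list[PersonRecord]):
    """Population dump: one row per person (CSV-friendly)."""
    import pandas as pd

    rows = [{
        "person_id": p.person_id, "sex": p.sex, "birth_year": p.birth_year,
        "initiation_age": p.smoking.initiation_age,
        "cessation_age": p.smoking.cessation_age,
        "cigarettes_per_day": p.smoking.cigarettes_per_day,
    } for p in persons]
    return pd.DataFrame(rows)
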