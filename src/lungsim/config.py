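"""Configuration blocks and the YAML loader.

Five blocks — ``population``, ``smoking``, ``mortality``, ``natural_history``,
``screening`` — plus a small ``run`` block (replications). Each block is a frozen
dataclass with explicit invariant checks; the loader fills defaults, rejects
unknown keys, and names the offending field on any violation.

Default parameterization
------------------------
The defaults define the study conditions this package simulates: a US-like
population aged 30-84 followed 2016-2030, smoking prevalence declining across
birth cohorts (the mechanism that erodes screening yield over time), a
smoking-driven lung cancer natural history, and CMS-criteria annual low-dose CT
screening at 45% adherence. The natural-history numbers are transparent
stand-ins chosen for epidemiological plausibility, not estimates calibrated to
trial data; docs/methods.md discusses each.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

STAGES = (1, 2, 3, 4)
STAGE_NAMES = {1: "I", 2: "II", 3: "III", 4: "IV"}
HISTOLOGIES = ("adenocarcinoma", "squamous_cell", "large_cell", "small_cell", "other")


def _check(cond: bool, fld: str, msg: str) -> None:
    if not cond:
        raise ConfigError(fld, msg)


@dataclass(frozen=True)
class PopulationConfig:
    """Multi-birth-cohort population frame."""

    start_year: int = 2016
    end_year: int = 2030
    min_age: int = 30
    max_age: int = 84
    n_persons: int = 20_000
    person_weight: float = 1.0
    sex_fraction_male: float = 0.49
    cohort_growth_rate: float = 0.0   # relative size change per successive birth year
    master_seed: int = 20160101

    def validate(self) -> None:
        _check(self.start_year <= self.end_year, "population.start_year",
               "start_year must be <= end_year")
        _check(self.min_age < self.max_age, "population.min_age",
               "min_age must be < max_age")
        _check(self.n_persons >= 1, "population.n_persons", "n_persons must be >= 1")
        _check(self.person_weight > 0, "population.person_weight",
               "person_weight must be > 0")
        _check(0.0 <= self.sex_fraction_male <= 1.0, "population.sex_fraction_male",
               "must be a probability")
        _check(self.cohort_growth_rate > -1.0, "population.cohort_growth_rate",
               "must exceed -1")

    @property
    def birth_year_span(self) -> tuple[int, int]:
        """Inclusive birth years of anyone aged [min_age, max_age] in the horizon."""
        return (self.start_year - self.max_age, self.end_year - self.min_age)

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass(frozen=True)
class SmokingParams:
    """Parametric smoking-history generator.

    Ever-smoking probability is anchored at the earliest cohort and declines
    linearly in birth year (``init_trend_per_year`` < 0 encodes the falling US
    smoking prevalence across generations). Optional per-decade multipliers
    allow non-linear cohort effects without a full table.
    """

    init_prob_male_anchor: float = 0.65
    init_prob_female_anchor: float = 0.50
    anchor_birth_year: int = 1932
    init_trend_per_year: float = -0.006
    init_prob_floor: float = 0.05
    decade_init_multiplier: dict[int, float] = field(default_factory=dict)

    init_age_mean: float = 17.0
    init_age_sd: float = 3.0
    init_age_min: float = 10.0
    init_age_max: float = 35.0

    cpd_median_male: float = 28.0
    cpd_median_female: float = 20.0
    cpd_sigma: float = 0.45    # lognormal shape
    cpd_max: float = 60.0
    cpd_trend_per_year: float = -0.018   # log decline of median cpd per birth year

    annual_cessation_prob: float = 0.020
    cessation_trend_per_year: float = 0.025  # log increase of quit prob per birth year
    cessation_prob_max: float = 0.25
    max_cessation_age: float = 90.0

    def validate(self) -> None:
        for fld in ("init_prob_male_anchor", "init_prob_female_anchor",
                    "init_prob_floor", "annual_cessation_prob"):
            v = getattr(self, fld)
            _check(0.0 <= v <= 1.0, f"smoking.{fld}", "must be a probability")
        _check(self.init_age_min < self.init_age_max, "smoking.init_age_min",
               "init_age_min must be < init_age_max")
        _check(self.cpd_median_male > 0 and self.cpd_median_female > 0,
               "smoking.cpd_median_male", "cigarettes/day medians must be > 0")
        for dec, m in self.decade_init_multiplier.items():
            _check(m >= 0, f"smoking.decade_init_multiplier.{dec}", "must be >= 0")

    def initiation_probability(self, birth_year: int, sex: str) -> float:
        anchor = (self.init_prob_male_anchor if sex == "M"
                  else self.init_prob_female_anchor)
        p = anchor + self.init_trend_per_year * (birth_year - self.anchor_birth_year)
        decade = (birth_year // 10) * 10
        p *= self.decade_init_multiplier.get(decade, 1.0)
        return float(min(max(p, self.init_prob_floor), 1.0))

    def cpd_median(self, sex: str, birth_year: int | None = None) -> float:
        """Median cigarettes/day, declining for later cohorts (lighter smoking)."""
        base = self.cpd_median_male if sex == "M" else self.cpd_median_female
        if birth_year is None:
            return base
        return base * math.exp(self.cpd_trend_per_year * (birth_year - self.anchor_birth_year))

    def cessation_probability(self, birth_year: int) -> float:
        """Annual quit probability, rising for later cohorts (earlier quitting)."""
        p = self.annual_cessation_prob * math.exp(
            self.cessation_trend_per_year * (birth_year - self.anchor_birth_year))
        return min(p, self.cessation_prob_max)


@dataclass(frozen=True)
class MortalityParams:
    """Competing (non-lung-cancer) mortality: Gompertz baseline x status hazard ratio."""

    gompertz_rate: float = 5.5e-5    # hazard scale at age 0
    gompertz_shape: float = 0.09     # log-hazard slope per year of age
    hr_current: float = 2.3
    hr_former: float = 1.4
    hr_never: float = 1.0
    max_age: float = 100.0

    def validate(self) -> None:
        _check(self.gompertz_rate > 0, "mortality.gompertz_rate", "must be > 0")
        _check(self.gompertz_shape > 0, "mortality.gompertz_shape", "must be > 0")
        for fld in ("hr_current", "hr_former", "hr_never"):
            _check(getattr(self, fld) > 0, f"mortality.{fld}", "must be > 0")
        _check(self.max_age > 0, "mortality.max_age", "must be > 0")


def _stage_dict(default: dict[int, float]) -> Any:
    return field(default_factory=lambda: dict(default))


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Latent cancer onset, progression, detection and survival parameters.

    Survival after diagnosis is a cure-fraction + exponential-residual mixture
    per stage; cure fractions fall and residual death rates rise from stage I
    to IV, so an earlier stage at detection (the stage shift screening buys)
    maps the same survival quantile to a weakly later lung-cancer death.
    """

    onset_base_rate: float = 8.0e-7       # baseline onset hazard scale
    onset_age_slope: float = 0.085        # exponential age slope of onset hazard
    dose_coef: float = 0.19               # log-hazard per cigarette/day (saturating)
    dose_saturation_cpd: float = 30.0
    cessation_decay_rate: float = 0.03    # per-year decay of the smoking excess after quitting
    max_onset_age: float = 100.0

    histology_probs: dict[str, float] = field(default_factory=lambda: {
        "adenocarcinoma": 0.40, "squamous_cell": 0.22, "large_cell": 0.08,
        "small_cell": 0.15, "other": 0.15})
    histology_probs_never: dict[str, float] = field(default_factory=lambda: {
        "adenocarcinoma": 0.62, "squamous_cell": 0.10, "large_cell": 0.06,
        "small_cell": 0.06, "other": 0.16})

    sojourn_mean_years: dict[int, float] = _stage_dict({1: 2.0, 2: 1.0, 3: 1.0})
    small_cell_progression_factor: float = 0.5   # SCLC progresses faster
    clinical_detection_rate: dict[int, float] = _stage_dict(
        {1: 0.12, 2: 0.35, 3: 0.9, 4: 2.0})

    cure_fraction: dict[int, float] = _stage_dict({1: 0.38, 2: 0.22, 3: 0.09, 4: 0.02})
    residual_death_rate: dict[int, float] = _stage_dict({1: 0.25, 2: 0.40, 3: 0.70, 4: 1.40})
    small_cell_cure_factor: float = 0.5
    small_cell_death_rate_factor: float = 1.5

    def validate(self) -> None:
        for name, probs in (("histology_probs", self.histology_probs),
                            ("histology_probs_never", self.histology_probs_never)):
            _check(set(probs) == set(HISTOLOGIES), f"natural_history.{name}",
                   f"must have exactly the categories {sorted(HISTOLOGIES)}")
            _check(abs(sum(probs.values()) - 1.0) <= 1e-9, f"natural_history.{name}",
                   "probabilities must sum to 1")
            _check(all(p >= 0 for p in probs.values()), f"natural_history.{name}",
                   "probabilities must be >= 0")
        for s in (1, 2, 3):
            _check(self.sojourn_mean_years.get(s, 0) > 0,
                   f"natural_history.sojourn_mean_years.{s}", "must be > 0")
        for s in STAGES:
            _check(self.clinical_detection_rate.get(s, -1) >= 0,
                   f"natural_history.clinical_detection_rate.{s}", "must be >= 0")
            _check(0.0 <= self.cure_fraction.get(s, -1) <= 1.0,
                   f"natural_history.cure_fraction.{s}", "must be in [0, 1]")
            _check(self.residual_death_rate.get(s, 0) > 0,
                   f"natural_history.residual_death_rate.{s}", "must be > 0")
        cures = [self.cure_fraction[s] for s in STAGES]
        _check(all(a >= b for a, b in zip(cures, cures[1:])),
               "natural_history.cure_fraction",
               "cure fraction must be non-increasing from stage I to IV")
        _check(self.onset_base_rate >= 0, "natural_history.onset_base_rate", "must be >= 0")
        _check(self.cessation_decay_rate >= 0, "natural_history.cessation_decay_rate",
               "must be >= 0")


@dataclass(frozen=True)
class ScreeningPolicy:
    """CMS low-dose CT screening rules with partial, fixed per-person adherence."""

    min_age: int = 55
    max_age: int = 77
    min_pack_years: float = 30.0
    max_quit_years: float = 15.0     # exclusive: exactly 15 years since quitting is ineligible
    interval_years: int = 1
    adherence_rate: float = 0.45
    start_year: int = 2016
    sensitivity: dict[int, float] = _stage_dict({1: 0.80, 2: 0.85, 3: 0.92, 4: 0.95})
    specificity: float = 0.90

    def validate(self) -> None:
        _check(0.0 <= self.adherence_rate <= 1.0, "screening.adherence_rate",
               "must be in [0, 1]")
        _check(self.min_age <= self.max_age, "screening.min_age",
               "min_age must be <= max_age")
        _check(self.min_pack_years >= 0, "screening.min_pack_years", "must be >= 0")
        _check(self.max_quit_years >= 0, "screening.max_quit_years", "must be >= 0")
        _check(self.interval_years == 1, "screening.interval_years",
               "only annual screening is supported")
        for s in STAGES:
            _check(0.0 <= self.sensitivity.get(s, -1) <= 1.0,
                   f"screening.sensitivity.{s}", "must be a probability")
        _check(0.0 <= self.specificity <= 1.0, "screening.specificity",
               "must be a probability")


@dataclass(frozen=True)
class RunConfig:
    replications: int = 20

    def validate(self) -> None:
        _check(self.replications >= 1, "run.replications", "must be >= 1")


@dataclass(frozen=True)
class FullConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    smoking: SmokingParams = field(default_factory=SmokingParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    screening: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    run: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> None:
        for block in dataclasses.fields(self):
            getattr(self, block.name).validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **block_updates: dict[str, Any]) -> "FullConfig":
        """Return a copy with per-block field updates, e.g. replace(screening={'adherence_rate': 1.0})."""
        new_blocks = {}
        for name, updates in block_updates.items():
            if not hasattr(self, name):
                raise ConfigError(name, "unknown configuration block")
            new_blocks[name] = dataclasses.replace(getattr(self, name), **updates)
        cfg = dataclasses.replace(self, **new_blocks)
        cfg.validate()
        return cfg


_BLOCK_TYPES = {
    "population": PopulationConfig,
    "smoking": SmokingParams,
    "mortality": MortalityParams,
    "natural_history": NaturalHistoryParams,
    "screening": ScreeningPolicy,
    "run": RunConfig,
}

# dict-valued fields whose YAML keys are integers (stages, decades)
_INT_KEY_FIELDS = {"sojourn_mean_years", "clinical_detection_rate", "cure_fraction",
                   "residual_death_rate", "sensitivity", "decade_init_multiplier"}


def config_from_dict(raw: dict[str, Any]) -> FullConfig:
    """Build a validated FullConfig from a nested dict; unknown keys are rejected."""
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "configuration must be a mapping of blocks")
    blocks: dict[str, Any] = {}
    for name, payload in raw.items():
        if name not in _BLOCK_TYPES:
            raise ConfigError(name, "unknown configuration block")
        cls = _BLOCK_TYPES[name]
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in (payload or {}).items():
            if key not in known:
                raise ConfigError(f"{name}.{key}", "unknown configuration key")
            if key in _INT_KEY_FIELDS and isinstance(value, dict):
                value = {int(k): float(v) for k, v in value.items()}
            kwargs[key] = value
        blocks[name] = cls(**kwargs)
    cfg = FullConfig(**blocks)
    cfg.validate()
    return cfg


def load_config(path: str) -> FullConfig:
    """Load and validate a YAML (or JSON — a YAML subset) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


def save_config(cfg: FullConfig, path: str) -> None:
    """Write the full (defaults-filled) configuration back out as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def default_config() -> FullConfig:
    cfg = FullConfig()
    cfg.validate()
    return cfg
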