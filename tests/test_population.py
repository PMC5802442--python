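"""Synthetic population: cohorts, smoking histories, competing mortality."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given
from hypothesis import strategies as hst

import lungsim as ls
from lungsim.config import MortalityParams, PopulationConfig, SmokingParams
from lungsim.errors import ConfigError
from lungsim.population import (FORMER, NEVER, PersonRecord, SmokingHistory,
                                pack_years_at, quit_years_at,
                                sample_other_cause_death_age,
                                sample_smoking_history, smoker_status_at)


def _person(history=None, adherence_u=0.0, seed=1, pid=0, birth_year=1950, sex="M"):
    return PersonRecord(person_id=pid, sex=sex, birth_year=birth_year,
                        smoking=history or SmokingHistory(),
                        adherence_uniform=adherence_u, master_seed=seed)


# ---------------------------------------------------------------- build_population

def test_birth_years_span_matches_age_window():
    cfg = PopulationConfig(n_persons=2000, master_seed=5)
    persons = ls.build_population(cfg, SmokingParams())
    years = {p.birth_year for p in persons}
    assert min(years) >= 2016 - 84 and max(years) <= 2030 - 30


def test_zero_persons_is_a_config_error():
    cfg = PopulationConfig(n_persons=0)
    with pytest.raises(ConfigError, match="n_persons"):
        ls.build_population(cfg, SmokingParams())


def test_birth_year_histogram_uniform_under_zero_growth():
    """Multinomial oracle: with growth 0 the cohort sizes are uniform, so a
    chi-square goodness-of-fit test should not reject at p=0.001."""
    cfg = PopulationConfig(n_persons=40_000, cohort_growth_rate=0.0, master_seed=77)
    persons = ls.build_population(cfg, SmokingParams())
    lo, hi = cfg.birth_year_span
    counts = np.bincount([p.birth_year - lo for p in persons], minlength=hi - lo + 1)
    chi2 = st.chisquare(counts)
    assert chi2.pvalue > 0.001


def test_population_reproducible_bit_for_bit():
    cfg = PopulationConfig(n_persons=1500, master_seed=99)
    a = ls.build_population(cfg, SmokingParams())
    b = ls.build_population(cfg, SmokingParams())
    assert a == b
    c = ls.build_population(dataclasses.replace(cfg, master_seed=100), SmokingParams())
    assert a != c


# ------------------------------------------------------------ smoking histories

def test_zero_initiation_probability_means_all_never_smokers():
    params = SmokingParams(init_prob_male_anchor=0.0, init_prob_female_anchor=0.0,
                          init_trend_per_year=0.0, init_prob_floor=0.0)
    rng = np.random.default_rng(0)
    assert all(sample_smoking_history(1950, "M", params, rng).is_never
               for _ in range(500))


def test_zero_cessation_probability_means_no_former_smokers():
    params = SmokingParams(annual_cessation_prob=0.0, cessation_trend_per_year=0.0,
                          init_prob_male_anchor=1.0, init_trend_per_year=0.0)
    rng = np.random.default_rng(1)
    histories = [sample_smoking_history(1950, "M", params, rng) for _ in range(500)]
    assert all(h.cessation_age is None for h in histories)


def test_ever_smoker_fraction_matches_binomial_oracle():
    params = SmokingParams()
    p = params.initiation_probability(1950, "M")
    rng = np.random.default_rng(42)
    n = 100_000
    ever = sum(not sample_smoking_history(1950, "M", params, rng).is_never
               for _ in range(n))
    se = math.sqrt(p * (1 - p) / n)
    assert abs(ever / n - p) < 3 * se


def test_ever_smoker_prevalence_declines_for_later_cohorts():
    """The central generational mechanism: initiation probability (and hence
    sampled ever-smoker prevalence) is non-increasing in birth year."""
    params = SmokingParams()
    for sex in ("M", "F"):
        probs = [params.initiation_probability(by, sex) for by in range(1932, 2001)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
    rng = np.random.default_rng(3)
    fracs = []
    for by in (1940, 1970, 2000):
        n = 20_000
        fracs.append(sum(not sample_smoking_history(by, "M", params, rng).is_never
                         for _ in range(n)) / n)
    assert fracs[0] > fracs[1] > fracs[2]


# ------------------------------------------------------------------- pack-years

@pytest.mark.parametrize("history, age, expected", [
    (SmokingHistory(20.0, None, 20.0), 50.0, 30.0),     # 1 pack/day for 30 years
    (SmokingHistory(), 70.0, 0.0),                       # never smoker
    (SmokingHistory(18.0, 48.0, 30.0), 60.0, 45.0),      # 1.5 packs/day for 30 years
    (SmokingHistory(20.0, None, 20.0), 20.0, 0.0),       # zero at initiation age
])
def test_pack_years_definition(history, age, expected):
    assert pack_years_at(history, age) == pytest.approx(expected)


def test_pack_years_rejects_negative_age():
    with pytest.raises(ValueError):
        pack_years_at(SmokingHistory(), -1.0)


@pytest.mark.parametrize("age, status, quit", [
    (39.0, "current", None),
    (54.0, "former", 14.0),
    (10.0, "never", None),
])
def test_status_and_quit_years(age, status, quit):
    h = SmokingHistory(18.0, 40.0, 20.0)
    assert smoker_status_at(h, age) == status
    assert quit_years_at(h, age) == quit


def test_never_smoker_status():
    assert smoker_status_at(SmokingHistory(), 70.0) == NEVER


@given(init=hst.floats(10, 35), duration=hst.floats(0.5, 60), cpd=hst.floats(1, 60),
       quits=hst.booleans(), data=hst.data())
def test_pack_years_non_decreasing_in_age(init, duration, cpd, quits, data):
    h = SmokingHistory(init, init + duration if quits else None, cpd)
    ages = sorted(data.draw(hst.lists(hst.floats(0, 120), min_size=2, max_size=8)))
    vals = [pack_years_at(h, a) for a in ages]
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
    assert pack_years_at(h, init) == 0.0


def test_eligibility_quantities_agree_with_per_year_accumulation_oracle():
    """Brute-force per-year accumulation: pack-years at an integer age equal
    the sum of yearly overlaps with the smoking interval, exactly."""
    rng = np.random.default_rng(11)
    params = SmokingParams()
    for _ in range(1000):
        by = int(rng.integers(1932, 2001))
        h = sample_smoking_history(by, "M" if rng.random() < 0.5 else "F", params, rng)
        age = int(rng.integers(30, 90))
        if h.is_never:
            assert pack_years_at(h, age) == 0.0
            assert smoker_status_at(h, age) == NEVER
            continue
        stop = h.cessation_age if h.cessation_age is not None else math.inf
        oracle = sum(max(0.0, min(y + 1.0, age, stop) - max(y, h.initiation_age))
                     for y in range(age)) * h.cigarettes_per_day / 20.0
        assert pack_years_at(h, age) == pytest.approx(oracle, abs=1e-9)
        if age < h.initiation_age:
            assert smoker_status_at(h, age) == NEVER
        elif age < stop:
            assert smoker_status_at(h, age) == "current"
        else:
            assert smoker_status_at(h, age) == FORMER
            assert quit_years_at(h, age) == pytest.approx(age - h.cessation_age)


# ------------------------------------------------------- competing mortality

def test_other_cause_death_matches_gompertz_closed_form():
    """With all hazard ratios 1 the death-age law is pure Gompertz; compare
    sampled draws with scipy's closed-form CDF by a KS test."""
    mort = MortalityParams(hr_current=1.0, hr_former=1.0, hr_never=1.0, max_age=150.0)
    person = _person(SmokingHistory(18.0, 40.0, 20.0), seed=2)
    rng = np.random.default_rng(7)
    draws = np.array([sample_other_cause_death_age(person, mort, rng=rng)
                      for _ in range(20_000)])
    dist = st.gompertz(c=mort.gompertz_rate / mort.gompertz_shape,
                       scale=1.0 / mort.gompertz_shape)
    assert st.kstest(draws, dist.cdf).pvalue > 0.001


def test_smoking_hazard_ratio_shortens_life():
    mort = MortalityParams(hr_current=2.0, hr_never=1.0)
    rng = np.random.default_rng(8)
    current = _person(SmokingHistory(10.0, None, 20.0))
    never = _person(SmokingHistory())
    d_cur = np.array([sample_other_cause_death_age(current, mort, rng=rng)
                      for _ in range(20_000)])
    d_nev = np.array([sample_other_cause_death_age(never, mort, rng=rng)
                      for _ in range(20_000)])
    assert np.median(d_cur) < np.median(d_nev)


def test_death_age_capped_and_entry_conditioned():
    mort = MortalityParams()
    rng = np.random.default_rng(9)
    person = _person(SmokingHistory())
    draws = [sample_other_cause_death_age(person, mort, rng=rng, entry_age=80.0)
             for _ in range(2000)]
    assert all(80.0 <= d <= 100.0 for d in draws)


def test_substreams_reproducible_and_named():
    person = _person(seed=123, pid=45)
    a = person.rng("tumor").random(5)
    b = person.rng("tumor").random(5)
    assert np.array_equal(a, b)
    c = person.rng("survival").random(5)
    assert not np.array_equal(a, c)
    assert set(person.substream_seeds) == {"build", "other_cause", "tumor",
                                           "survival", "detection"}
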