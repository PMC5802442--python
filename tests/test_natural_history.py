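"""Natural history: onset, histology, preclinical progression, survival."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.stats as st

from lungsim.config import HISTOLOGIES, NaturalHistoryParams, STAGES
from lungsim.errors import ConfigError
from lungsim.natural_history import (assign_histology, sample_lc_death_age,
                                     sample_onset_age, sample_preclinical_course,
                                     survival_probability)
from lungsim.population import SmokingHistory

NEVER = SmokingHistory()
HEAVY = SmokingHistory(17.0, None, 40.0)
FORMER = SmokingHistory(17.0, 45.0, 40.0)


def _onsets(history, params, n, seed):
    rng = np.random.default_rng(seed)
    return np.array([a for a in (sample_onset_age(history, params, rng)
                                 for _ in range(n)) if a is not None])


# ------------------------------------------------------------------------ onset

def test_zero_dose_coefficient_removes_smoking_effect():
    params = NaturalHistoryParams(dose_coef=0.0)
    a = _onsets(NEVER, params, 10_000, 1)
    b = _onsets(HEAVY, params, 10_000, 2)
    assert abs(len(a) - len(b)) < 4 * math.sqrt(len(a))
    assert st.ks_2samp(a, b).pvalue > 0.001


def test_zero_baseline_hazard_never_produces_onset():
    params = NaturalHistoryParams(onset_base_rate=0.0)
    rng = np.random.default_rng(3)
    assert all(sample_onset_age(NEVER, params, rng) is None for _ in range(200))


def test_cumulative_incidence_ordering_matches_numeric_integration():
    """current > former > never, with each empirical onset probability within
    3 binomial SEs of a trapezoid integration of its own hazard."""
    params = NaturalHistoryParams()
    ages = np.linspace(0, 100, 4001)

    def oracle(history):
        base = params.onset_base_rate * np.exp(params.onset_age_slope * ages)
        if history.is_never:
            mult = np.ones_like(ages)
        else:
            dose = params.dose_coef * min(history.cigarettes_per_day,
                                          params.dose_saturation_cpd)
            f = np.where(ages >= history.initiation_age, 1.0, 0.0)
            if history.cessation_age is not None:
                post = ages >= history.cessation_age
                f[post] = np.exp(-params.cessation_decay_rate
                                 * (ages[post] - history.cessation_age))
            mult = np.exp(dose * f)
        cum = np.trapezoid(base * mult, ages)
        return 1.0 - math.exp(-cum)

    n = 20_000
    results = {}
    for name, history, seed in (("current", HEAVY, 4), ("former", FORMER, 5),
                                ("never", NEVER, 6)):
        frac = len(_onsets(history, params, n, seed)) / n
        expected = oracle(history)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se, name
        results[name] = (frac, expected)
    assert results["current"][1] > results["former"][1] > results["never"][1]
    assert results["current"][0] > results["former"][0] > results["never"][0]


def test_onset_respects_entry_age_truncation():
    params = NaturalHistoryParams()
    rng = np.random.default_rng(7)
    for _ in range(300):
        a = sample_onset_age(HEAVY, params, rng, entry_age=62.5)
        assert a is None or a >= 62.5


# --------------------------------------------------------------------- histology

def test_degenerate_mixture_always_adenocarcinoma():
    probs = {h: 0.0 for h in HISTOLOGIES} | {"adenocarcinoma": 1.0}
    params = NaturalHistoryParams(histology_probs=probs, histology_probs_never=probs)
    rng = np.random.default_rng(8)
    assert all(assign_histology(HEAVY, params, rng) == "adenocarcinoma"
               for _ in range(200))


def test_histology_frequencies_match_multinomial_oracle():
    params = NaturalHistoryParams()
    rng = np.random.default_rng(9)
    n = 30_000
    draws = [assign_histology(HEAVY, params, rng) for _ in range(n)]
    assert set(draws) == set(HISTOLOGIES)  # all 5 categories, nothing else
    for h in HISTOLOGIES:
        p = params.histology_probs[h]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(draws.count(h) / n - p) < 3 * se


def test_invalid_mixture_is_a_config_error():
    bad = dict(NaturalHistoryParams().histology_probs)
    bad["adenocarcinoma"] += 0.05
    params = NaturalHistoryParams(histology_probs=bad)
    with pytest.raises(ConfigError):
        params.validate()
    with pytest.raises(ConfigError):
        assign_histology(HEAVY, params, np.random.default_rng(0))


# ----------------------------------------------------------- preclinical course

def test_infinite_stage1_detection_hazard_detects_everything_in_stage1():
    params = NaturalHistoryParams(clinical_detection_rate={1: 1e12, 2: 0.3, 3: 0.9, 4: 2.0})
    rng = np.random.default_rng(10)
    for _ in range(200):
        _, age, stage = sample_preclinical_course(60.0, "adenocarcinoma", params, rng)
        assert stage == 1 and age == pytest.approx(60.0, abs=1e-6)


def test_zero_detection_hazards_mean_no_clinical_detection():
    params = NaturalHistoryParams(clinical_detection_rate={s: 0.0 for s in STAGES})
    rng = np.random.default_rng(11)
    _, age, stage = sample_preclinical_course(60.0, "adenocarcinoma", params, rng)
    assert math.isinf(age) and stage is None


def test_stage_at_detection_matches_competing_exponentials_oracle():
    """Closed-form competing-risks oracle: P(detect in stage j) is the product
    of 'progress before detection' odds over earlier stages times the
    detection odds in stage j."""
    params = NaturalHistoryParams()
    rates = {s: 1.0 / params.sojourn_mean_years[s] for s in (1, 2, 3)} | {4: 0.0}
    h = params.clinical_detection_rate
    expected = []
    carry = 1.0
    for s in STAGES:
        p_detect = h[s] / (h[s] + rates[s]) if (h[s] + rates[s]) > 0 else 0.0
        expected.append(carry * p_detect)
        carry *= 1.0 - p_detect
    rng = np.random.default_rng(12)
    n = 20_000
    counts = np.zeros(4)
    for _ in range(n):
        _, _, stage = sample_preclinical_course(60.0, "adenocarcinoma", params, rng)
        counts[stage - 1] += 1
    for s in STAGES:
        se = math.sqrt(expected[s - 1] * (1 - expected[s - 1]) / n)
        assert abs(counts[s - 1] / n - expected[s - 1]) < 3.5 * se, f"stage {s}"


def test_small_cell_progresses_faster():
    params = NaturalHistoryParams()
    rng = np.random.default_rng(13)

    def mean_time_to_stage4(histology):
        times = []
        for _ in range(3000):
            entries, _, _ = sample_preclinical_course(60.0, histology, params, rng)
            times.append(entries[3] - entries[0])
        return np.mean(times)

    assert mean_time_to_stage4("small_cell") < 0.7 * mean_time_to_stage4("adenocarcinoma")


# ---------------------------------------------------------------------- survival

def test_full_cure_means_no_lung_cancer_deaths():
    params = NaturalHistoryParams(cure_fraction={s: 1.0 for s in STAGES})
    for q in np.linspace(0.0, 0.999, 50):
        assert sample_lc_death_age(2, "adenocarcinoma", 65.0, params, q) is None


def test_comonotone_coupling_earlier_stage_never_dies_earlier():
    """Exhaustive quantile-grid check of the stage-shift survival contract."""
    params = NaturalHistoryParams()
    for hist in HISTOLOGIES:
        for q in np.linspace(0.0, 0.999, 500):
            deaths = [sample_lc_death_age(s, hist, 65.0, params, float(q))
                      for s in STAGES]
            vals = [math.inf if d is None else d for d in deaths]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:])), (hist, q)


def test_median_quantile_stage1_outlives_stage4():
    params = NaturalHistoryParams()
    d1 = sample_lc_death_age(1, "adenocarcinoma", 65.0, params, 0.5)
    d4 = sample_lc_death_age(4, "adenocarcinoma", 65.0, params, 0.5)
    assert d1 is None or (d4 is not None and d1 >= d4)


@pytest.mark.parametrize("stage", STAGES)
@pytest.mark.parametrize("hist", ["adenocarcinoma", "small_cell"])
def test_five_year_survival_matches_cure_mixture_closed_form(stage, hist):
    params = NaturalHistoryParams()
    rng = np.random.default_rng(stage * 17 + (hist == "small_cell"))
    n = 20_000
    qs = rng.random(n)
    alive = sum(1 for q in qs
                if (d := sample_lc_death_age(stage, hist, 65.0, params, float(q)))
                is None or d > 70.0)
    expected = survival_probability(stage, hist, params, 5.0)
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(alive / n - expected) < 3.5 * se


def test_survival_quantile_domain_errors():
    params = NaturalHistoryParams()
    for q in (-0.01, 1.0, 1.5):
        with pytest.raises(ValueError):
            sample_lc_death_age(1, "adenocarcinoma", 65.0, params, q)
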