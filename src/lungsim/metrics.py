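"""Outcome metrics: mortality reduction, deaths avoided, life-years gained,
overdiagnosis (two definitions), shares and declines.

Every metric is a pure function of raw counts or of replication aggregates, so
each can be recomputed independently by brute-force tabulation of the event
logs. Printed-style percentages are rounded to 2 decimals, half away from
zero; counts to integers.

``load_reference_aggregates``/``verify_reference_arithmetic`` exercise the
metric definitions against a bundled table of national-scale aggregate counts
from a published projection with the same design (the package's analysis runs
its own synthetic population; the reference table is used only to verify the
metric arithmetic on realistic magnitudes).
"""

from __future__ import annotations

import json
import math
from importlib import resources

import numpy as np
import pandas as pd

from .engine import ReplicationResult
from .errors import UndefinedMetricError


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (what printed tables use), not banker's rounding."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def mortality_reduction(deaths_avoided: float, deaths_no_screen: float) -> float:
    """100 x deaths avoided / no-screening deaths, to 2 decimals."""
    if deaths_no_screen <= 0:
        raise UndefinedMetricError("mortality reduction undefined: no deaths in the "
                                   "no-screening scenario")
    return round_half_away(100.0 * deaths_avoided / deaths_no_screen, 2)


def screened_population_mortality_reduction(result: ReplicationResult) -> float:
    """Mortality reduction restricted to persons screened at least once.

    The screened subset is identified in the screening scenario and, through
    the common-random-numbers pairing, the same persons' no-screening deaths
    form the denominator.
    """
    denom = result.scalars["lc_deaths_no_screen_screened_subset"]
    if result.scalars["screened_persons"] <= 0:
        raise UndefinedMetricError("no person was ever screened")
    avoided = denom - result.scalars["lc_deaths_screen_screened_subset"]
    return mortality_reduction(avoided, denom)


def life_years_gained(result: ReplicationResult) -> float:
    """Weighted life-years gained within the horizon (truncated at horizon end)."""
    return result.scalars["life_years_gained"]


def overdiagnosis_def1(result: ReplicationResult) -> dict[str, float]:
    """Overdiagnoses (screen-detected, eventual non-lung-cancer death) with the
    two reported rates: per 100 deaths avoided and percent of screen-detected."""
    n_over = result.scalars["overdiagnoses"]
    out = {"overdiagnoses": n_over}
    avoided = result.scalars["deaths_avoided"]
    out["per_100_deaths_avoided"] = (round_half_away(100.0 * n_over / avoided, 2)
                                     if avoided > 0 else float("nan"))
    detected = result.scalars["screen_detected"]
    out["pct_of_screen_detected"] = (round_half_away(100.0 * n_over / detected, 2)
                                     if detected > 0 else float("nan"))
    return out


def overdiagnosis_ratio(overdiagnoses: float, deaths_avoided: float) -> float:
    """Overdiagnoses per 100 deaths avoided, to 2 decimals."""
    if deaths_avoided <= 0:
        raise UndefinedMetricError("no deaths avoided")
    return round_half_away(100.0 * overdiagnoses / deaths_avoided, 2)


def overdiagnosis_rate(overdiagnoses: float, screen_detected: float) -> float:
    """Overdiagnoses as a percent of screen-detected diagnoses, to 2 decimals."""
    if screen_detected <= 0:
        raise UndefinedMetricError("no screen-detected diagnoses")
    return round_half_away(100.0 * overdiagnoses / screen_detected, 2)


def excess_diagnosis_rate(screen_arm_cases: float, control_arm_cases: float,
                          screen_arm_total_diagnoses: float) -> float:
    """Excess-diagnosis overdiagnosis measure: 100 x (screening-arm cases minus
    control-arm cases) / screening-arm diagnoses. Here the no-screening
    scenario plays the control arm."""
    if screen_arm_total_diagnoses <= 0:
        raise UndefinedMetricError("no diagnoses in the screening arm")
    return round_half_away(
        100.0 * (screen_arm_cases - control_arm_cases) / screen_arm_total_diagnoses, 2)


def share_decomposition(stratum_counts: dict[str, float]) -> dict[str, float]:
    """Percent share of each stratum in the total, to 2 decimals."""
    total = sum(stratum_counts.values())
    if total <= 0:
        raise UndefinedMetricError("zero total count")
    return {k: round_half_away(100.0 * v / total, 2) for k, v in stratum_counts.items()}


def percent_share(stratum: float, total: float) -> float:
    if total <= 0:
        raise UndefinedMetricError("zero total count")
    return round_half_away(100.0 * stratum / total, 2)


def percent_change(first: float, last: float) -> float:
    """Percent decline from first to last, to 2 decimals."""
    if first <= 0:
        raise UndefinedMetricError("zero initial count")
    return round_half_away(100.0 * (first - last) / first, 2)


def scale_deaths_avoided(deaths_avoided: float, from_rate: float, to_rate: float) -> int:
    """Proportional adherence scaling (the structural linearity of the nested
    coupling): expected deaths avoided scale with the adherence rate."""
    if from_rate <= 0:
        raise UndefinedMetricError("zero adherence rate")
    return int(round_half_away(deaths_avoided * to_rate / from_rate, 0))


def cumulative_mortality_reduction_series(annual_ns_deaths: np.ndarray,
                                          annual_s_deaths: np.ndarray) -> np.ndarray:
    """Cumulative MR trajectory: running avoided over running no-screen deaths (%)."""
    cum_ns = np.cumsum(np.asarray(annual_ns_deaths, dtype=float))
    cum_s = np.cumsum(np.asarray(annual_s_deaths, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cum_ns > 0, 100.0 * (cum_ns - cum_s) / cum_ns, 0.0)


def annual_mortality_reduction_series(annual_ns_deaths: np.ndarray,
                                      annual_s_deaths: np.ndarray) -> np.ndarray:
    ns = np.asarray(annual_ns_deaths, dtype=float)
    s = np.asarray(annual_s_deaths, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ns > 0, 100.0 * (ns - s) / ns, 0.0)


def deaths_avoided_periods(result: ReplicationResult, period_years: int = 5) -> pd.DataFrame:
    """Deaths avoided by smoker type over consecutive periods partitioning the
    horizon, plus the cumulative column (the periods sum exactly to it)."""
    annual = result.annual
    years = np.array(result.years)
    total = (annual["lc_deaths_no_screen"] - annual["lc_deaths_screen"]).to_numpy()
    rows = []
    labels = []
    for i in range(0, len(years), period_years):
        chunk = slice(i, min(i + period_years, len(years)))
        labels.append(f"{years[chunk][0]}-{years[chunk][-1]}")
        rows.append(total[chunk].sum())
    frame = pd.DataFrame({"deaths_avoided": rows}, index=pd.Index(labels, name="period"))
    frame.loc["cumulative"] = total.sum()
    return frame


def metrics_report(result: ReplicationResult) -> dict[str, float]:
    """Headline metrics for one replication (means/CIs come from summarizing
    several of these across replications)."""
    s = result.scalars
    rep: dict[str, float] = {
        "lc_deaths_no_screen": s["lc_deaths_no_screen"],
        "lc_deaths_screen": s["lc_deaths_screen"],
        "deaths_avoided": s["deaths_avoided"],
        "exams_total": s["exams_total"],
        "screen_detected": s["screen_detected"],
        "overdiagnoses": s["overdiagnoses"],
        "life_years_gained": s["life_years_gained"],
        "cases_no_screen": s["cases_no_screen"],
        "cases_screen": s["cases_screen"],
    }
    if s["lc_deaths_no_screen"] > 0:
        rep["mortality_reduction_pct"] = mortality_reduction(
            s["deaths_avoided"], s["lc_deaths_no_screen"])
    if s["screened_persons"] > 0 and s["lc_deaths_no_screen_screened_subset"] > 0:
        rep["screened_population_mr_pct"] = screened_population_mortality_reduction(result)
    od = overdiagnosis_def1(result)
    rep["overdiagnosis_per_100_avoided"] = od["per_100_deaths_avoided"]
    rep["overdiagnosis_pct_of_screen_detected"] = od["pct_of_screen_detected"]
    if s["cases_screen"] > 0:
        rep["excess_diagnosis_rate_pct"] = excess_diagnosis_rate(
            s["cases_screen"], s["cases_no_screen"], s["cases_screen"])
    if s["in_age_range_first_year"] > 0:
        rep["eligible_fraction_first_year_pct"] = percent_share(
            s["eligible_first_year"], s["in_age_range_first_year"])
    if s["in_age_range_last_year"] > 0:
        rep["eligible_fraction_last_year_pct"] = percent_share(
            s["eligible_last_year"], s["in_age_range_last_year"])
    return rep


def metrics_from_scalar_log(scalars: pd.DataFrame) -> pd.DataFrame:
    """Recompute the headline derived metrics from a written engine scalar log
    (one row per replication, as emitted by ``write_reports``)."""
    rows = []
    for _, s in scalars.iterrows():
        row = {"replication_seed": s.get("replication_seed")}
        if s["lc_deaths_no_screen"] > 0:
            row["mortality_reduction_pct"] = mortality_reduction(
                s["lc_deaths_no_screen"] - s["lc_deaths_screen"],
                s["lc_deaths_no_screen"])
        if s["deaths_avoided"] > 0:
            row["overdiagnosis_per_100_avoided"] = overdiagnosis_ratio(
                s["overdiagnoses"], s["deaths_avoided"])
        if s["screen_detected"] > 0:
            row["overdiagnosis_pct_of_screen_detected"] = overdiagnosis_rate(
                s["overdiagnoses"], s["screen_detected"])
        if s["cases_screen"] > 0:
            row["excess_diagnosis_rate_pct"] = excess_diagnosis_rate(
                s["cases_screen"], s["cases_no_screen"], s["cases_screen"])
        row["life_years_gained"] = s["life_years_gained"]
        row["deaths_avoided"] = s["deaths_avoided"]
        rows.append(row)
    return pd.DataFrame(rows)


def adherence_sweep(cfg, rates: list[float], n_replications: int = 3,
                    master_seed: int | None = None) -> pd.DataFrame:
    """Table of (adherence rate, deaths avoided, mortality reduction) evaluated
    on shared populations via the nested-adherence coupling; one row per rate
    with across-replication means and 95% CIs."""
    from ._rng import replication_seeds
    from .engine import run_adherence_sweep_replication, summary_interval

    seed = cfg.population.master_seed if master_seed is None else master_seed
    reps = [run_adherence_sweep_replication(cfg, rates, s)
            for s in replication_seeds(seed, n_replications)]
    all_rows = pd.concat(reps, ignore_index=True)
    rows = []
    for rate, grp in all_rows.groupby("adherence_rate", sort=True):
        row = {"adherence_rate": rate}
        for col in ("deaths_avoided", "mortality_reduction_pct",
                    "life_years_gained", "exams"):
            vals = grp[col].to_numpy()
            if len(vals) >= 2:
                mean, lo, hi = summary_interval(vals)
            else:
                mean, lo, hi = float(vals[0]), float("nan"), float("nan")
            row[col] = mean
            row[f"{col}_ci_lo"], row[f"{col}_ci_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def single_cohort_mode(cfg, birth_year: int, window_years: int = 15,
                       n_replications: int = 3,
                       master_seed: int | None = None) -> pd.DataFrame:
    """Cumulative mortality-reduction trajectory for one birth cohort over a
    15-year observation window (mean across replications per window year)."""
    from .engine import run_single_cohort

    raw = run_single_cohort(cfg, birth_year, window_years=window_years,
                            n_replications=n_replications, master_seed=master_seed)
    grouped = raw.groupby("window_index").agg(
        year=("year", "first"),
        cumulative_mortality_reduction_pct=("cumulative_mortality_reduction_pct", "mean"),
        cum_deaths_avoided=("cum_deaths_avoided", "mean"),
        cum_deaths_no_screen=("cum_deaths_no_screen", "mean"))
    grouped["birth_year"] = birth_year
    return grouped.reset_index()


# ---------------------------------------------------------------------------
# Reference-arithmetic verification
# ---------------------------------------------------------------------------

def load_reference_aggregates() -> dict:
    with resources.files("lungsim.data").joinpath("reference_aggregates.json").open() as fh:
        return json.load(fh)


def verify_reference_arithmetic(agg: dict | None = None) -> dict[str, float]:
    """Recompute every derived quantity from the bundled raw aggregate counts.

    Returns the computed values (percentages to 2 decimals, counts as
    integers); nothing here is stored pre-computed — each number is the output
    of the corresponding metric function applied to raw counts.
    """
    agg = agg or load_reference_aggregates()
    ns = agg["no_screening"]
    sc = agg["screening_45pct_adherence"]
    sweep = agg["adherence_sweep_deaths_avoided"]
    out: dict[str, float] = {}
    out["mortality_reduction_total_pct"] = mortality_reduction(
        sc["deaths_avoided_total"], ns["cum_lc_deaths_total"])
    out["mortality_reduction_current_pct"] = mortality_reduction(
        sc["deaths_avoided_current"], ns["cum_lc_deaths_current"])
    out["mortality_reduction_former_pct"] = mortality_reduction(
        sc["deaths_avoided_former"], ns["cum_lc_deaths_former"])
    out["overdiagnoses_per_100_deaths_avoided"] = overdiagnosis_ratio(
        sc["overdiagnoses"], sc["deaths_avoided_total"])
    out["overdiagnosis_rate_pct"] = overdiagnosis_rate(
        sc["overdiagnoses"], sc["screen_detected_diagnoses"])
    out["never_smoker_share_of_lc_deaths_pct"] = percent_share(
        ns["cum_lc_deaths_never"], ns["cum_lc_deaths_total"])
    out["current_smoker_share_of_deaths_avoided_pct"] = percent_share(
        sc["deaths_avoided_current"], sc["deaths_avoided_total"])
    out["case_decline_no_screening_pct"] = percent_change(
        ns["cases_first_year"], ns["cases_last_year"])
    out["screens_decline_pct"] = percent_change(
        sc["screens_first_year"], sc["screens_last_year"])
    out["deaths_avoided_scaled_to_35pct_adherence"] = scale_deaths_avoided(
        sweep["0.45"], 0.45, 0.35)
    out["additional_deaths_avoided_full_adherence"] = sweep["1.00"] - sweep["0.45"]
    periods = sc["deaths_avoided_by_period"]
    out["period_totals_sum"] = sum(p["total"] for p in periods.values())
    out["period_current_sum"] = sum(p["current"] for p in periods.values())
    out["period_former_sum"] = sum(p["former"] for p in periods.values())
    return out
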