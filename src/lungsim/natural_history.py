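"""Lung cancer natural history: onset, histology, progression, survival.

A transparent stand-in for a fully calibrated natural-history model, keeping
the structure that matters for screening analysis:

* onset hazard = exponential-in-age baseline x exp(saturating dose-response in
  cigarettes/day), with the smoking excess decaying exponentially after
  cessation — never smokers face the baseline alone;
* five histologies, with small cell progressing faster and surviving worse;
* preclinical stages I→IV with exponential sojourns and stage-specific
  clinical-detection hazards (competing exponentials);
* post-diagnosis survival as a stage/histology cure fraction plus an
  exponential residual, driven by one per-person survival quantile.

The survival quantile mapping is comonotone across stages: for a fixed
quantile, an earlier stage at detection never produces an earlier lung-cancer
death. Stage shift through this coupling is the only pathway by which
screening confers benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import HISTOLOGIES, NaturalHistoryParams, STAGES
from .population import SmokingHistory


@dataclass(frozen=True)
class TumorCase:
    """One latent tumor path (scenario-invariant part) plus its detection outcome."""

    onset_age: float
    histology: str
    stage_entry_ages: tuple[float, float, float, float]
    clinical_detection_age: float          # inf if never clinically detected
    stage_at_clinical: Optional[int]
    detection_mode: Optional[str] = None   # "clinical" | "screen" | None
    detection_age: Optional[float] = None
    stage_at_detection: Optional[int] = None
    lc_death_age: Optional[float] = None   # None = cured / never diagnosed

    def stage_at(self, age: float) -> Optional[int]:
        """Preclinical stage occupied at ``age`` (None before onset)."""
        if age < self.onset_age:
            return None
        stage = 1
        for s, entry in enumerate(self.stage_entry_ages, start=1):
            if age >= entry:
                stage = s
        return stage


def _dose_multiplier_grid(history: SmokingHistory, params: NaturalHistoryParams,
                          ages: np.ndarray) -> np.ndarray:
    """exp(dose-response) evaluated on an age grid, with post-cessation decay."""
    if history.is_never:
        return np.ones_like(ages)
    dose = params.dose_coef * min(history.cigarettes_per_day, params.dose_saturation_cpd)
    f = np.zeros_like(ages)
    active = ages >= history.initiation_age
    f[active] = 1.0
    if history.cessation_age is not None:
        quit = ages >= history.cessation_age
        f[quit] = np.exp(-params.cessation_decay_rate * (ages[quit] - history.cessation_age))
    return np.exp(dose * f)


def sample_onset_age(history: SmokingHistory, params: NaturalHistoryParams,
                     rng: np.random.Generator, entry_age: float = 0.0) -> Optional[float]:
    """First lung-cancer onset age, or None if none occurs by ``max_onset_age``.

    The hazard is integrated on a 1-year grid (midpoint rule) from ``entry_age``
    — i.e. left-truncated, conditioning on being cancer-free at study entry —
    and inverted against a unit-exponential draw.
    """
    e = rng.exponential()
    if params.onset_base_rate <= 0.0:
        return None
    a0 = math.floor(entry_age)
    grid = np.arange(a0, math.ceil(params.max_onset_age))
    # first cell may be partial when entry_age is fractional
    widths = np.minimum(grid + 1.0, params.max_onset_age) - np.maximum(grid, entry_age)
    widths = np.clip(widths, 0.0, None)
    mid = np.maximum(grid, entry_age) + widths / 2.0
    haz = params.onset_base_rate * np.exp(params.onset_age_slope * mid)
    haz = haz * _dose_multiplier_grid(history, params, mid)
    cum = np.cumsum(haz * widths)
    idx = int(np.searchsorted(cum, e))
    if idx >= len(cum):
        return None
    prev = cum[idx - 1] if idx > 0 else 0.0
    rate = haz[idx]
    t0 = max(grid[idx], entry_age)
    return float(t0 + (e - prev) / rate)


def assign_histology(history: SmokingHistory, params: NaturalHistoryParams,
                     rng: np.random.Generator) -> str:
    """Categorical histology draw; never smokers use an adenocarcinoma-heavier mix."""
    probs = params.histology_probs_never if history.is_never else params.histology_probs
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        from .errors import ConfigError
        raise ConfigError("natural_history.histology_probs", "probabilities must sum to 1")
    p = np.array([probs[h] for h in HISTOLOGIES])
    return HISTOLOGIES[int(rng.choice(len(HISTOLOGIES), p=p / p.sum()))]


def _progression_factor(histology: str, params: NaturalHistoryParams) -> float:
    return params.small_cell_progression_factor if histology == "small_cell" else 1.0


def sample_preclinical_course(onset_age: float, histology: str,
                              params: NaturalHistoryParams, rng: np.random.Generator
                              ) -> tuple[tuple[float, float, float, float], float, Optional[int]]:
    """Stage entry ages and the clinical-detection age/stage for one tumor.

    In each stage, an exponential clinical-detection clock competes with the
    exponential sojourn to the next stage (stage IV has no onward transition).
    Returns ``(stage_entry_ages, clinical_detection_age, stage_at_clinical)``;
    the detection age is ``inf`` when every stage's detection hazard loses
    (only possible with zero hazards).
    """
    factor = _progression_factor(histology, params)
    sojourns = [rng.exponential(params.sojourn_mean_years[s] * factor) for s in (1, 2, 3)]
    sojourns.append(math.inf)  # stage IV is terminal
    entries = (onset_age,
               onset_age + sojourns[0],
               onset_age + sojourns[0] + sojourns[1],
               onset_age + sojourns[0] + sojourns[1] + sojourns[2])
    detect_age, detect_stage = math.inf, None
    for stage in STAGES:
        rate = params.clinical_detection_rate[stage]
        d = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if d < sojourns[stage - 1] and detect_stage is None:
            detect_age, detect_stage = entries[stage - 1] + d, stage
    return (entries, detect_age, detect_stage)


def _cure_fraction(stage: int, histology: str, params: NaturalHistoryParams) -> float:
    c = params.cure_fraction[stage]
    if histology == "small_cell":
        c *= params.small_cell_cure_factor
    return min(max(c, 0.0), 1.0)


def _death_rate(stage: int, histology: str, params: NaturalHistoryParams) -> float:
    r = params.residual_death_rate[stage]
    if histology == "small_cell":
        r *= params.small_cell_death_rate_factor
    return r


def sample_lc_death_age(stage_at_detection: int, histology: str, detection_age: float,
                        params: NaturalHistoryParams, survival_quantile: float,
                        anchor_age: Optional[float] = None) -> Optional[float]:
    """Lung-cancer death age for a diagnosed case, or None if cured.

    The survival quantile maps comonotonically: quantiles above ``1 - cure``
    are cured (cure regions are nested because cure fractions fall with
    stage), and below that the exponential residual is inverted so a better
    stage always yields a weakly longer residual. The residual clock runs from
    ``anchor_age`` — in the paired-scenario engine this is the
    scenario-invariant clinical-presentation age, which makes the stage-shift
    benefit free of lead-time bookkeeping artifacts.
    """
    if not (0.0 <= survival_quantile < 1.0):
        raise ValueError("survival_quantile must lie in [0, 1)")
    cure = _cure_fraction(stage_at_detection, histology, params)
    if survival_quantile >= 1.0 - cure:
        return None
    x = survival_quantile / (1.0 - cure)
    residual = -math.log1p(-x) / _death_rate(stage_at_detection, histology, params)
    origin = detection_age if anchor_age is None else anchor_age
    return float(origin + residual)


def survival_probability(stage: int, histology: str, params: NaturalHistoryParams,
                         years: float) -> float:
    """Closed-form P(alive from lung cancer > years after the anchor) — the
    cure + exponential mixture; used as an independent check on sampling."""
    cure = _cure_fraction(stage, histology, params)
    rate = _death_rate(stage, histology, params)
    return cure + (1.0 - cure) * math.exp(-rate * years)
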