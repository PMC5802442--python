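"""CMS eligibility, adherence assignment and annual low-dose CT screening.

Eligibility (checked at each exam date): age 55-77 inclusive, at least 30
pack-years, and current smoker or quit fewer than 15 years ago (exactly 15 is
ineligible). Adherence is a fixed per-person attribute obtained by
thresholding one uniform draw — the adherent set at a lower rate is nested
inside the set at any higher rate, which is what makes adherence sweeps on a
single population monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ScreeningPolicy
from .natural_history import TumorCase
from .population import (CURRENT, PersonRecord, SmokingHistory, pack_years_at,
                         quit_years_at, smoker_status_at)

NEGATIVE, FALSE_POSITIVE, DETECTED = "negative", "false_positive", "detected"


@dataclass(frozen=True)
class ScreenExam:
    calendar_year: int
    age: float
    result: str                      # negative | false_positive | detected
    stage: Optional[int] = None      # stage at detection, if detected


def is_eligible(history: SmokingHistory, age: float, policy: ScreeningPolicy) -> bool:
    """CMS screening eligibility at an exam age."""
    if not (policy.min_age <= age <= policy.max_age):
        return False
    if pack_years_at(history, age) < policy.min_pack_years:
        return False
    status = smoker_status_at(history, age)
    if status == CURRENT:
        return True
    qy = quit_years_at(history, age)
    return qy is not None and qy < policy.max_quit_years


def assign_adherent(person: PersonRecord, policy: ScreeningPolicy) -> bool:
    """Fixed per-person adherence via the nested threshold coupling."""
    return person.adherence_uniform < policy.adherence_rate


def screen_person_years(person: PersonRecord, tumor: Optional[TumorCase],
                        policy: ScreeningPolicy, years: range,
                        detection_uniforms: np.ndarray,
                        death_age: float = math.inf,
                        clinical_detection_age: Optional[float] = None,
                        ) -> tuple[list[ScreenExam], Optional[tuple[float, int]]]:
    """Annual exam loop over calendar ``years`` given precomputed per-year
    detection uniforms. Exams happen at the start of each year while the person
    is alive, undiagnosed and eligible; a preclinical tumor is found with
    stage-specific sensitivity; screening stops at any diagnosis.

    Returns the exam list and ``(detection_age, stage)`` if screen-detected.
    """
    if clinical_detection_age is None:
        clinical_detection_age = (tumor.clinical_detection_age
                                  if tumor is not None else math.inf)
    exams: list[ScreenExam] = []
    detection: Optional[tuple[float, int]] = None
    for i, year in enumerate(years):
        age = float(person.age_in(year))
        if age >= death_age:
            break
        if age >= clinical_detection_age:
            break  # clinically diagnosed before this exam date
        if not is_eligible(person.smoking, age, policy):
            continue
        u = float(detection_uniforms[i])
        preclinical = (tumor is not None and tumor.onset_age <= age
                       and age < clinical_detection_age)
        if preclinical:
            stage = tumor.stage_at(age)
            if u < policy.sensitivity[stage]:
                exams.append(ScreenExam(year, age, DETECTED, stage))
                detection = (age, stage)
                break
            exams.append(ScreenExam(year, age, NEGATIVE))
        else:
            result = FALSE_POSITIVE if u >= policy.specificity else NEGATIVE
            exams.append(ScreenExam(year, age, result))
    return exams, detection


def run_screens_for_person(person: PersonRecord, tumor: Optional[TumorCase],
                           policy: ScreeningPolicy, horizon: tuple[int, int],
                           rng: Optional[np.random.Generator] = None,
                           death_age: float = math.inf,
                           ) -> tuple[list[ScreenExam], Optional[tuple[float, int]]]:
    """Screening pathway for one adherent person over ``horizon`` years.

    Nonadherent persons (by ``assign_adherent``) should not reach this call;
    callers get an empty exam list by simply not calling it. The per-year
    detection uniforms come from the person's dedicated detection substream so
    the no-screening scenario is untouched by their consumption.
    """
    start = max(policy.start_year, horizon[0])
    years = range(start, horizon[1] + 1)
    if rng is None:
        rng = person.rng("detection")
    uniforms = rng.random(len(years))
    clin = tumor.clinical_detection_age if tumor is not None else math.inf
    return screen_person_years(person, tumor, policy, years, uniforms,
                               death_age=death_age, clinical_detection_age=clin)
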