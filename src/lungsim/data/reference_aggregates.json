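{
  "description": "National-scale reference aggregate counts for a 2016-2030 US lung cancer screening projection (CMS criteria, 45% adherence) used to exercise the derived-metric definitions. Counts are model outputs of a published national projection; every derived percentage/ratio in this package's checks is recomputed from these raw counts, never stored.",
  "horizon": {"start_year": 2016, "end_year": 2030},
  "no_screening": {
    "cum_lc_deaths_total": 1777144,
    "cum_lc_deaths_former": 952578,
    "cum_lc_deaths_current": 686780,
    "cum_lc_deaths_never": 137786,
    "cases_first_year": 180673,
    "cases_last_year": 141114,
    "cum_cases": 2462479
  },
  "screening_45pct_adherence": {
    "deaths_avoided_total": 62425,
    "deaths_avoided_current": 31482,
    "deaths_avoided_former": 30943,
    "deaths_avoided_by_period": {
      "2016-2020": {"current": 8861, "former": 7735, "total": 16596},
      "2021-2025": {"current": 12892, "former": 12800, "total": 25692},
      "2026-2030": {"current": 9728, "former": 10409, "total": 20137}
    },
    "screen_detected_diagnoses": 252429,
    "overdiagnoses": 9054,
    "life_years_gained": 148484,
    "screens_first_year": 5297959,
    "screens_last_year": 3076347,
    "cum_screens": 63857158
  },
  "adherence_sweep_deaths_avoided": {
    "0.25": 34681,
    "0.35": 48553,
    "0.45": 62425,
    "0.55": 76297,
    "0.65": 90170,
    "0.75": 104042,
    "1.00": 138722
  }
}
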