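"""CSV/JSON report writing and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from datetime import datetime, timezone

import pandas as pd

from . import __version__
from .config import FullConfig
from .engine import ReplicationResult, summarize_runs
from .metrics import (annual_mortality_reduction_series,
                      cumulative_mortality_reduction_series,
                      deaths_avoided_periods, metrics_report)


def config_hash(cfg: FullConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    replication_seeds: list[int]
    package_version: str
    timestamp: str
    outputs: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_reports(results: list[ReplicationResult], cfg: FullConfig,
                  out_dir: str) -> list[str]:
    """Write the reporting surfaces: per-replication engine log, across-run
    summary, annual screens by smoker type, annual/cumulative mortality
    reduction series, deaths-avoided period table, overdiagnosis panel, a JSON
    metrics summary and the run manifest. Deterministic content for a fixed
    config and seed (the manifest timestamp aside)."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _save(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        path = os.path.join(out_dir, name)
        frame.to_csv(path, index=index, float_format="%.6f")
        written.append(name)

    # tidy per-replication annual log
    log = pd.concat([r.annual.assign(replication_seed=r.replication_seed)
                     for r in results])
    _save(log, "engine_annual_log.csv")

    scalars = pd.DataFrame([dict(r.scalars, replication_seed=r.replication_seed)
                            for r in results])
    _save(scalars, "engine_scalars_log.csv", index=False)

    if len(results) >= 2:
        _save(summarize_runs(results), "summary_all_quantities.csv")

    mean_annual = sum(r.annual for r in results) / len(results)
    screens = mean_annual[["screens", "screens_current", "screens_former"]]
    _save(screens, "screens_by_smoker_type.csv")

    mr = pd.DataFrame({
        "annual_mr_pct": annual_mortality_reduction_series(
            mean_annual["lc_deaths_no_screen"].to_numpy(),
            mean_annual["lc_deaths_screen"].to_numpy()),
        "cumulative_mr_pct": cumulative_mortality_reduction_series(
            mean_annual["lc_deaths_no_screen"].to_numpy(),
            mean_annual["lc_deaths_screen"].to_numpy()),
    }, index=mean_annual.index)
    _save(mr, "mortality_reduction_series.csv")

    periods = sum(deaths_avoided_periods(r)["deaths_avoided"] for r in results) / len(results)
    _save(periods.to_frame("deaths_avoided"), "deaths_avoided_periods.csv")

    over = pd.DataFrame([{"replication_seed": r.replication_seed,
                          "overdiagnoses": r.scalars["overdiagnoses"],
                          "screen_detected": r.scalars["screen_detected"],
                          "deaths_avoided": r.scalars["deaths_avoided"]}
                         for r in results])
    _save(over, "overdiagnosis_panel.csv", index=False)

    headline = pd.DataFrame([metrics_report(r) for r in results])
    summary_json = {col: {"mean": float(headline[col].mean())} for col in headline.columns}
    with open(os.path.join(out_dir, "metrics_summary.json"), "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)
    written.append("metrics_summary.json")

    manifest = RunManifest(
        config_hash=config_hash(cfg),
        master_seed=cfg.population.master_seed,
        replication_seeds=[r.replication_seed for r in results],
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        outputs=sorted(written))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    written.append("manifest.json")
    return [os.path.join(out_dir, name) for name in written]
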