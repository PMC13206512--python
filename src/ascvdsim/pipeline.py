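"""End-to-end pipeline: generation -> simulation -> outcomes -> reports.

``run_pipeline`` draws the four ratio-stratum birth cohorts, simulates them
to completion, aggregates the three summary tables (by ratio stratum, by
LDL-C group over the pooled population, and the event-count table), writes
curve CSVs and a derived-statistics JSON, and records everything in a
manifest with checksums so a run can be verified and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, load_config, validate_config
from .engine import events_to_dataframe, simulate_cohort
from .events import CLINICAL_EVENTS, EventType
from .outcomes import (
    cumulative_incidence,
    mortality_adjusted_cum_risk,
    summarize_cohort,
)
from .population import assign_ldl_group, cohort_to_dataframe, sample_cohort
from .tables import PrintedTables, derived_statistics

logger = logging.getLogger("ascvdsim")

__all__ = ["RunManifest", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunManifest:
    """Snapshot of one completed run: config, seed, outputs and checksums."""

    package_version: str
    seed: int
    created: str
    config: dict
    outputs: Dict[str, str]  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _summary_table1(summaries: dict) -> pd.DataFrame:
    rows = []
    for sex in ("all", "female", "male"):
        for s in (1, 2, 3, 4):
            cs = summaries[s][sex]
            rows.append(
                {
                    "sex": sex,
                    "stratum": s,
                    "life_expectancy": round(cs.life_expectancy, 2),
                    "lifetime_qalys": round(cs.lifetime_qalys, 2),
                    "mean_ldl": round(cs.mean_ldl, 2),
                    "mean_hdl": round(cs.mean_hdl, 2),
                }
            )
    return pd.DataFrame(rows)


def _summary_table3(summaries: dict) -> pd.DataFrame:
    rows = []
    for sex in ("all", "female", "male"):
        for s in (1, 2, 3, 4):
            ev = summaries[s][sex].events
            row = {"sex": sex, "stratum": s}
            for name, col in (("hf", "HF"), ("ihd", "IHD"), ("mi", "MI")):
                row[f"{name}_total"] = round(ev.loc[col, "total"])
                row[f"{name}_fatal"] = round(ev.loc[col, "fatal"])
            row["other_fatal"] = round(ev.loc["OTHER_DEATH", "fatal"])
            row["is_total"] = round(ev.loc["IS", "total"])
            row["is_fatal"] = round(ev.loc["IS", "fatal"])
            rows.append(row)
    return pd.DataFrame(rows)


def _summary_table2(completed_all: list, config: RunConfig) -> pd.DataFrame:
    """LE/QALYs by LDL-C group over the pooled population (reclassified)."""
    from .outcomes import life_expectancy, lifetime_qalys

    rows = []
    groups = {p.person_id: assign_ldl_group(p.lipid, config.population.spec) for p in completed_all}
    for sex in ("all", "female", "male"):
        for g in (1, 2, 3, 4):
            sub = [
                p
                for p in completed_all
                if groups[p.person_id] == g and (sex == "all" or p.sex == sex)
            ]
            if not sub:
                continue
            rows.append(
                {
                    "sex": sex,
                    "ldl_group": g,
                    "n": len(sub),
                    "life_expectancy": round(life_expectancy(sub), 2),
                    "lifetime_qalys": round(lifetime_qalys(sub, config.utility), 2),
                }
            )
    return pd.DataFrame(rows)


def _curves(completed_by_stratum: dict, ages: np.ndarray) -> pd.DataFrame:
    rows = []
    for s, cohort in completed_by_stratum.items():
        for ev in CLINICAL_EVENTS:
            crude = cumulative_incidence(cohort, ev, ages)
            for a, v in zip(ages, crude):
                rows.append(
                    {"stratum": s, "event_type": ev.value, "age": a, "curve": "crude", "value": v}
                )
        net = mortality_adjusted_cum_risk(cohort, EventType.IS, ages)
        for a, v in zip(ages, net):
            rows.append(
                {"stratum": s, "event_type": "IS", "age": a, "curve": "net", "value": v}
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: Optional[RunConfig] = None,
    output_dir="run_output",
    config_path=None,
) -> RunManifest:
    """Run the full generation -> simulation -> summary pipeline.

    Raises ``ConfigError`` when validation fails; otherwise writes the cohort
    CSV, event-history CSV, three summary tables, curve CSV, a
    derived-statistics JSON and ``manifest.json`` into ``output_dir``.
    """
    if config is None:
        config = load_config(config_path)
    report = validate_config(config)
    failures = [f"{rule} ({detail})" for rule, ok, detail in report if not ok]
    if failures:
        raise ConfigError("invalid configuration: " + "; ".join(failures))

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    completed_by_stratum = {}
    summaries = {}
    cohort_frames = []
    for s in (1, 2, 3, 4):
        logger.info("stratum %d: sampling %d persons", s, config.population.n_per_stratum)
        cohort = sample_cohort(config.population, s)
        cohort_frames.append(cohort_to_dataframe(cohort))
        logger.info("stratum %d: simulating", s)
        completed = simulate_cohort(cohort, config.hazards, config.sim, config.population)
        completed_by_stratum[s] = completed
        summaries[s] = summarize_cohort(completed, config.utility, s, config.population)

    completed_all = [p for c in completed_by_stratum.values() for p in c]
    ages = np.arange(0.0, config.sim.age_cap + 1.0, 1.0)

    files = {
        "cohort.csv": pd.concat(cohort_frames, ignore_index=True),
        "events.csv": events_to_dataframe(completed_all),
        "summary_by_ratio_group.csv": _summary_table1(summaries),
        "summary_by_ldl_group.csv": _summary_table2(completed_all, config),
        "summary_event_counts.csv": _summary_table3(summaries),
        "curves.csv": _curves(completed_by_stratum, ages),
    }
    outputs: Dict[str, str] = {}
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=False)
        outputs[name] = _sha256(path)

    sim_tables = PrintedTables(
        table1=files["summary_by_ratio_group.csv"],
        table2=files["summary_by_ldl_group.csv"],
        table3=files["summary_event_counts.csv"],
    )
    stats_path = out / "derived_statistics.json"
    stats_path.write_text(json.dumps(derived_statistics(sim_tables), indent=2))
    outputs["derived_statistics.json"] = _sha256(stats_path)

    manifest = RunManifest(
        package_version=__version__,
        seed=config.sim.seed,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config=config.to_dict(),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("run complete: %d output files in %s", len(outputs) + 1, out)
    return manifest
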