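"""Configuration loading, bundling and validation.

A single YAML (or JSON) file holds the four configuration blocks —
``population``, ``hazards``, ``sim`` and ``utility`` — and a packaged default
file ships with the library.  The default parameter values are this package's
own calibration: stratum lipid means match the reference projection tables,
and the hazard baselines were tuned toward soft lifetime targets (about 5%
lifetime MI risk and 80-year life expectancy in the low-risk stratum, about
73% lifetime MI risk in the very-high-risk stratum, and a roughly twofold
male excess of MI in strata 1-3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .engine import SimConfig
from .hazards import HazardModel
from .outcomes import UtilityModel
from .population import (
    PopulationConfig,
    PrevalenceCurve,
    RiskGroupSpec,
    StratumLipidParams,
)

__all__ = ["RunConfig", "load_config", "default_config", "validate_config"]


@dataclass
class RunConfig:
    """The four configuration blocks of one simulation run."""

    population: PopulationConfig
    hazards: HazardModel
    sim: SimConfig
    utility: UtilityModel

    def to_dict(self) -> dict:
        pop = self.population
        return {
            "population": {
                "n_per_stratum": pop.n_per_stratum,
                "sex_split": pop.sex_split,
                "seed": pop.seed,
                "ratio_cutoffs": list(pop.spec.ratio_cutoffs),
                "ldl_cutoffs": list(pop.spec.ldl_cutoffs),
                "lipids": {
                    str(s): {sex: vars(p) for sex, p in by_sex.items()}
                    for s, by_sex in pop.lipids.items()
                },
                "prevalence": {
                    name: {
                        "start_age": c.start_age,
                        "end_age": c.end_age,
                        "max_prev": list(c.max_prev),
                        "sex_factor": dict(c.sex_factor),
                    }
                    for name, c in pop.prevalence.items()
                },
                "hba1c_mean": {str(k): v for k, v in pop.hba1c_mean.items()},
                "hba1c_sd": pop.hba1c_sd,
                "sbp_mean": {s: {str(k): v for k, v in d.items()} for s, d in pop.sbp_mean.items()},
                "sbp_sd": pop.sbp_sd,
                "bmi_mean": {s: {str(k): v for k, v in d.items()} for s, d in pop.bmi_mean.items()},
                "bmi_sd": pop.bmi_sd,
                "acceptance_floor": pop.acceptance_floor,
            },
            "hazards": self.hazards.to_dict(),
            "sim": {
                "time_step": self.sim.time_step,
                "age_cap": self.sim.age_cap,
                "seed": self.sim.seed,
            },
            "utility": {
                "intercept": dict(self.utility.intercept),
                "age_slope": self.utility.age_slope,
                "floor": self.utility.floor,
                "decrements": dict(self.utility.decrements),
                "discount_rate": self.utility.discount_rate,
            },
        }

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _population_from_dict(d: dict) -> PopulationConfig:
    spec = RiskGroupSpec(
        tuple(d.get("ratio_cutoffs", (0.45, 0.35, 0.25))),
        tuple(d.get("ldl_cutoffs", (3.1, 4.0, 5.0))),
    )
    lipids = {
        int(s): {sex: StratumLipidParams(**p) for sex, p in by_sex.items()}
        for s, by_sex in d.get("lipids", {}).items()
    }
    prevalence = {
        name: PrevalenceCurve(
            start_age=c["start_age"],
            end_age=c["end_age"],
            max_prev=tuple(c["max_prev"]),
            sex_factor=dict(c["sex_factor"]),
        )
        for name, c in d.get("prevalence", {}).items()
    }
    return PopulationConfig(
        n_per_stratum=d.get("n_per_stratum", 1000),
        sex_split=d.get("sex_split", 0.5),
        seed=d.get("seed", 0),
        spec=spec,
        lipids=lipids,
        prevalence=prevalence,
        hba1c_mean={int(k): v for k, v in d.get("hba1c_mean", {}).items()},
        hba1c_sd=d.get("hba1c_sd", 0.45),
        sbp_mean={s: {int(k): v for k, v in m.items()} for s, m in d.get("sbp_mean", {}).items()},
        sbp_sd=d.get("sbp_sd", 12.0),
        bmi_mean={s: {int(k): v for k, v in m.items()} for s, m in d.get("bmi_mean", {}).items()},
        bmi_sd=d.get("bmi_sd", 4.0),
        acceptance_floor=d.get("acceptance_floor", 1e-3),
    )


def config_from_dict(d: dict) -> RunConfig:
    return RunConfig(
        population=_population_from_dict(d.get("population", {})),
        hazards=HazardModel.from_dict(d.get("hazards", {})),
        sim=SimConfig(**d.get("sim", {})),
        utility=UtilityModel(**d.get("utility", {})),
    )


def load_config(path=None) -> RunConfig:
    """Load a run configuration from YAML/JSON; packaged defaults when ``path`` is None."""
    if path is None:
        text = (resources.files("ascvdsim.data") / "default_config.yaml").read_text()
        return config_from_dict(yaml.safe_load(text))
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return config_from_dict(data)


def default_config() -> RunConfig:
    """The packaged default calibration."""
    return load_config(None)


def validate_config(config: RunConfig) -> List[tuple[str, bool, str]]:
    """Full validation report over every configuration block."""
    report = []
    for block, obj in (
        ("population", config.population),
        ("hazards", config.hazards),
        ("sim", config.sim),
        ("utility", config.utility),
    ):
        for rule, ok, detail in obj.validate():
            report.append((f"{block}: {rule}", ok, detail))
    return report
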