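"""Hazard and case-fatality functions for the lifetime ASCVD model.

The myocardial-infarction hazard follows the cumulative-exposure picture of
atherogenesis: risk is proportional to an age- and sex-specific baseline
times a per-stratum lipid multiplier, and once the person's cumulative LDL-C
exposure crosses a threshold (default 5000 mg/dL-years) an exponential
excess term in (exposure - threshold) switches on, continuous at the
threshold.  Ischaemic-heart-disease risk shares the same shape at a lower
baseline.  Ischaemic-stroke risk scales as a power law in the LDL-C level:
each 1 mmol/L decrease multiplies the hazard by ``stroke_rr_per_mmol``
(default 0.84, i.e. a 16% reduction), with no risk before a configurable
onset age.  Heart-failure risk carries no lipid term at all.  Non-ASCVD
mortality is Gompertz-Makeham in age per sex.  Comorbidities (smoking,
diabetes, hypertension, atrial fibrillation, systolic blood pressure per
10 mmHg above a reference) act as multiplicative relative risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import yaml

from .events import EventType
from .population import PersonState
from .units import MG_DL_PER_MMOL_L

__all__ = [
    "HazardModel",
    "accumulate_exposure",
    "mi_hazard",
    "ihd_hazard",
    "stroke_hazard",
    "hf_hazard",
    "other_mortality_hazard",
    "case_fatality_prob",
    "is_fatal",
]


def accumulate_exposure(exposure: float, ldl_c: float, dt: float) -> float:
    """Advance cumulative LDL-C exposure (mg/dL-years) by ``dt`` years at ``ldl_c`` mmol/L.

    ``dt == 0`` is the identity; negative ``dt`` is rejected because exposure
    is non-decreasing over simulated time.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return exposure + ldl_c * MG_DL_PER_MMOL_L * dt


@dataclass
class HazardModel:
    """All rate functions and their parameters.

    Baselines are rates per person-year at age 0 growing exponentially with
    the given age slope; ``ratio_multiplier`` scales MI and IHD hazards per
    ratio stratum; ``gompertz`` holds (makeham, scale, shape) per sex for
    other-cause mortality; ``case_fatality`` holds per-event, per-sex,
    per-stratum probabilities that an event is fatal.
    """

    exposure_threshold: float = 5000.0  # mg/dL-years
    mi_baseline: Dict[str, float] = field(default_factory=lambda: {"female": 1e-5, "male": 2e-5})
    mi_age_slope: float = 0.08
    mi_excess_slope: float = 3e-4  # per mg/dL-year above threshold
    ratio_multiplier: Sequence[float] = (1.0, 2.0, 4.0, 12.0)
    ihd_baseline: Dict[str, float] = field(default_factory=lambda: {"female": 1e-5, "male": 1.5e-5})
    ihd_age_slope: float = 0.08
    stroke_baseline: Dict[str, float] = field(default_factory=lambda: {"female": 2e-3, "male": 3e-3})
    stroke_age_slope: float = 0.09
    stroke_onset_age: float = 60.0
    stroke_rr_per_mmol: float = 0.84
    stroke_ldl_ref: float = 3.0  # mmol/L reference for the power law
    hf_baseline: Dict[str, float] = field(default_factory=lambda: {"female": 1e-4, "male": 1e-4})
    hf_age_slope: float = 0.07
    gompertz: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {"female": (4e-4, 4e-6, 0.115), "male": (6e-4, 9e-6, 0.112)}
    )
    case_fatality: Dict[str, Dict[str, Sequence[float]]] = field(
        default_factory=lambda: {
            ev: {"female": [0.5] * 4, "male": [0.5] * 4} for ev in ("MI", "IHD", "IS", "HF")
        }
    )
    comorbidity_rr: Dict[str, Dict[str, float]] = field(default_factory=dict)
    sbp_ref: float = 120.0
    recurrent_multiplier: float = 1.5

    def validate(self) -> List[tuple[str, bool, str]]:
        rules: List[tuple[str, bool, str]] = []
        rules.append(("exposure_threshold > 0", self.exposure_threshold > 0, str(self.exposure_threshold)))
        rules.append(
            (
                "stroke_rr_per_mmol in (0,1)",
                0.0 < self.stroke_rr_per_mmol < 1.0,
                str(self.stroke_rr_per_mmol),
            )
        )
        base_ok = all(
            v >= 0
            for d in (self.mi_baseline, self.ihd_baseline, self.stroke_baseline, self.hf_baseline)
            for v in d.values()
        )
        rules.append(("baseline rates >= 0", base_ok, ""))
        gm_ok = all(len(p) == 3 and p[0] >= 0 and p[1] >= 0 for p in self.gompertz.values())
        rules.append(("Gompertz-Makeham parameters valid", gm_ok, ""))
        cf_ok = all(
            0.0 <= p <= 1.0
            for by_sex in self.case_fatality.values()
            for probs in by_sex.values()
            for p in probs
        )
        rules.append(("case-fatality probabilities in [0,1]", cf_ok, ""))
        mult_ok = len(self.ratio_multiplier) == 4 and all(m >= 0 for m in self.ratio_multiplier)
        rules.append(("4 non-negative ratio multipliers", mult_ok, str(self.ratio_multiplier)))
        return rules

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "exposure_threshold": self.exposure_threshold,
            "mi_baseline": dict(self.mi_baseline),
            "mi_age_slope": self.mi_age_slope,
            "mi_excess_slope": self.mi_excess_slope,
            "ratio_multiplier": list(self.ratio_multiplier),
            "ihd_baseline": dict(self.ihd_baseline),
            "ihd_age_slope": self.ihd_age_slope,
            "stroke_baseline": dict(self.stroke_baseline),
            "stroke_age_slope": self.stroke_age_slope,
            "stroke_onset_age": self.stroke_onset_age,
            "stroke_rr_per_mmol": self.stroke_rr_per_mmol,
            "stroke_ldl_ref": self.stroke_ldl_ref,
            "hf_baseline": dict(self.hf_baseline),
            "hf_age_slope": self.hf_age_slope,
            "gompertz": {k: list(v) for k, v in self.gompertz.items()},
            "case_fatality": {k: {s: list(v) for s, v in d.items()} for k, d in self.case_fatality.items()},
            "comorbidity_rr": {k: dict(v) for k, v in self.comorbidity_rr.items()},
            "sbp_ref": self.sbp_ref,
            "recurrent_multiplier": self.recurrent_multiplier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HazardModel":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "HazardModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def comorbidity_factor(person: PersonState, model: HazardModel, event: EventType) -> float:
    """Product of multiplicative relative risks active for ``person`` on ``event``."""
    rr = 1.0
    key = event.value
    flags = {
        "smoker": person.smoker,
        "diabetes": person.diabetes,
        "hypertension": person.hypertension,
        "atrial_fibrillation": person.atrial_fibrillation,
    }
    for name, on in flags.items():
        if on:
            rr *= model.comorbidity_rr.get(name, {}).get(key, 1.0)
    per10 = model.comorbidity_rr.get("sbp_per10", {}).get(key, 1.0)
    if per10 != 1.0:
        rr *= per10 ** ((person.sbp - model.sbp_ref) / 10.0)
    return rr


def _exposure_excess(exposure: float, model: HazardModel) -> float:
    over = exposure - model.exposure_threshold
    return math.exp(model.mi_excess_slope * over) if over > 0 else 1.0


def _recurrence(person: PersonState, model: HazardModel) -> float:
    return model.recurrent_multiplier if (person.prior_mi or person.prior_ihd) else 1.0


def mi_hazard(person: PersonState, model: HazardModel) -> float:
    """Myocardial-infarction rate per person-year for a living person."""
    base = model.mi_baseline[person.sex] * math.exp(model.mi_age_slope * person.age)
    h = (
        base
        * model.ratio_multiplier[person.stratum - 1]
        * _exposure_excess(person.cumulative_ldl_exposure, model)
        * comorbidity_factor(person, model, EventType.MI)
        * _recurrence(person, model)
    )
    return h


def ihd_hazard(person: PersonState, model: HazardModel) -> float:
    """Ischaemic-heart-disease rate; same stratum-multiplied shape as MI, lower baseline."""
    base = model.ihd_baseline[person.sex] * math.exp(model.ihd_age_slope * person.age)
    return (
        base
        * model.ratio_multiplier[person.stratum - 1]
        * _exposure_excess(person.cumulative_ldl_exposure, model)
        * comorbidity_factor(person, model, EventType.IHD)
        * _recurrence(person, model)
    )


def stroke_hazard(person: PersonState, model: HazardModel) -> float:
    """Ischaemic-stroke rate: LDL-C power law, zero before the onset age."""
    if person.age < model.stroke_onset_age:
        return 0.0
    base = model.stroke_baseline[person.sex] * math.exp(
        model.stroke_age_slope * (person.age - model.stroke_onset_age)
    )
    ldl_scale = model.stroke_rr_per_mmol ** (model.stroke_ldl_ref - person.lipid.ldl_c)
    return base * ldl_scale * comorbidity_factor(person, model, EventType.IS)


def hf_hazard(person: PersonState, model: HazardModel) -> float:
    """Heart-failure rate: no lipid term, comorbidity relative risks only."""
    base = model.hf_baseline[person.sex] * math.exp(model.hf_age_slope * person.age)
    return base * comorbidity_factor(person, model, EventType.HF)


def other_mortality_hazard(person: PersonState, model: HazardModel) -> float:
    """Gompertz-Makeham non-ASCVD mortality rate: makeham + scale * exp(shape * age)."""
    c, a, b = model.gompertz[person.sex]
    return c + a * math.exp(b * person.age)


def case_fatality_prob(event_type: EventType, person: PersonState, model: HazardModel) -> float:
    """Probability that an event of the given type is fatal for this person."""
    if event_type is EventType.OTHER_DEATH:
        return 1.0
    try:
        by_sex = model.case_fatality[event_type.value]
    except KeyError:
        raise ValueError(f"unknown event type {event_type!r}") from None
    return float(by_sex[person.sex][person.stratum - 1])


def is_fatal(
    event_type: EventType,
    person: PersonState,
    model: HazardModel,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli fatality draw for an event that has just occurred."""
    if not isinstance(event_type, EventType):
        raise ValueError(f"unknown event type {event_type!r}")
    return bool(rng.random() < case_fatality_prob(event_type, person, model))
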