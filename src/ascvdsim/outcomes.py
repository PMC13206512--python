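"""Aggregation of completed cohorts into lifetime summary quantities.

Outputs mirror the standard reporting surface of lifetime cardiovascular
microsimulations: mean life expectancy, lifetime QALYs under an age-declining
utility with multiplicative condition decrements, event counts per 100,000
births (total and fatal per event type, with heart failure restricted to
first occurrences without a history of ischaemic heart disease), crude
cumulative-incidence curves, and the mortality-adjusted ("net") cumulative
risk obtained by treating competing deaths as censoring in a Kaplan-Meier
estimator of the cause-specific hazard.  The crude and net curves together
expose survivorship bias: a high-risk stratum can accrue *fewer* lifetime
strokes than a lower-risk one purely because early fatal MI/IHD removes its
members before stroke-prone ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .events import CLINICAL_EVENTS, EventType
from .population import PersonState, PopulationConfig, PrevalenceCurve

__all__ = [
    "UtilityModel",
    "CohortSummary",
    "life_expectancy",
    "lifetime_qalys",
    "event_table",
    "cumulative_incidence",
    "mortality_adjusted_cum_risk",
    "summarize_cohort",
]


@dataclass(frozen=True)
class UtilityModel:
    """Health-state utility: linear age decline with multiplicative decrements.

    Baseline utility at age a is ``clip(intercept[sex] - age_slope * a,
    floor, 1)``; each prevalent condition multiplies it by a factor in (0, 1].
    QALYs are the discounted time-integral of the resulting utility.
    """

    intercept: Dict[str, float] = field(default_factory=lambda: {"female": 0.94, "male": 0.93})
    age_slope: float = 0.0022
    floor: float = 0.35
    decrements: Dict[str, float] = field(
        default_factory=lambda: {
            "post_mi": 0.88,
            "post_is": 0.85,
            "hf": 0.80,
            "ihd": 0.92,
            "diabetes": 0.95,
        }
    )
    discount_rate: float = 0.0

    def validate(self) -> List[tuple[str, bool, str]]:
        rules = []
        util_ok = all(0.0 <= v <= 1.0 for v in self.intercept.values()) and 0.0 <= self.floor <= 1.0
        rules.append(("utilities in [0,1]", util_ok, ""))
        dec_ok = all(0.0 < v <= 1.0 for v in self.decrements.values())
        rules.append(("decrement factors in (0,1]", dec_ok, ""))
        rules.append(("discount rate >= 0", self.discount_rate >= 0.0, str(self.discount_rate)))
        return rules

    def baseline(self, age: float, sex: str) -> float:
        return min(max(self.intercept[sex] - self.age_slope * age, self.floor), 1.0)


def life_expectancy(cohort: Sequence[PersonState]) -> float:
    """Arithmetic mean age at death across a completed cohort."""
    if not cohort:
        raise ValueError("life expectancy of an empty cohort is undefined")
    return float(np.mean([p.death_age for p in cohort]))


def _segment_integral(c: float, m: float, t0: float, t1: float, rho: float) -> float:
    """Integral of (c - m*t) * exp(-rho*t) over [t0, t1] in closed form."""
    if t1 <= t0:
        return 0.0
    if rho == 0.0:
        return c * (t1 - t0) - 0.5 * m * (t1**2 - t0**2)
    B = m / rho
    A = (B - c) / rho
    return (math.exp(-rho * t1) * (A + B * t1)) - (math.exp(-rho * t0) * (A + B * t0))


def _person_qalys(
    person: PersonState, utility: UtilityModel, diabetes_onset_age: Optional[float]
) -> float:
    death = person.death_age
    # ages at which the active-decrement set or the baseline kink changes
    onsets: List[tuple[float, str]] = []
    seen = set()
    for rec in person.history:
        key = {
            EventType.MI: "post_mi",
            EventType.IHD: "ihd",
            EventType.IS: "post_is",
            EventType.HF: "hf",
        }.get(rec.event_type)
        if key is not None and key not in seen:
            onsets.append((rec.age_at_event, key))
            seen.add(key)
    if diabetes_onset_age is not None and diabetes_onset_age < death:
        onsets.append((diabetes_onset_age, "diabetes"))

    kink = (utility.intercept[person.sex] - utility.floor) / utility.age_slope if utility.age_slope > 0 else math.inf
    breaks = sorted({0.0, death, *[a for a, _ in onsets if a < death], *( [kink] if 0 < kink < death else [] )})

    total = 0.0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        dec = 1.0
        for a, key in onsets:
            if a <= t0:
                dec *= utility.decrements.get(key, 1.0)
        if t0 >= kink:
            c, m = utility.floor, 0.0
        else:
            c, m = utility.intercept[person.sex], utility.age_slope
        total += dec * _segment_integral(c, m, t0, t1, utility.discount_rate)
    return total


def lifetime_qalys(
    cohort,
    utility: UtilityModel,
    diabetes_onset: Optional[Dict[int, float]] = None,
) -> float:
    """Mean lifetime QALYs of a completed cohort (or a single person).

    ``diabetes_onset`` optionally maps person_id to the age at which the
    diabetes decrement switches on; conditions tied to simulated events
    (post-MI, post-IS, HF, IHD) activate at the first event of each type.
    """
    for rule, ok, detail in utility.validate():
        if not ok:
            raise ValueError(f"invalid utility model: {rule} ({detail})")
    if isinstance(cohort, PersonState):
        cohort = [cohort]
    if not cohort:
        raise ValueError("QALYs of an empty cohort are undefined")
    onset = diabetes_onset or {}
    return float(np.mean([_person_qalys(p, utility, onset.get(p.person_id)) for p in cohort]))


def first_qualifying_event_age(person: PersonState, event_type: EventType) -> Optional[float]:
    """Age of the first counted event of a type, or None.

    Heart failure counts only when no ischaemic-heart-disease event precedes
    it in the history; other types count their first occurrence.
    """
    seen_ihd = False
    for rec in person.history:
        if rec.event_type is event_type:
            if event_type is EventType.HF and seen_ihd:
                return None
            return rec.age_at_event
        if rec.event_type is EventType.IHD:
            seen_ihd = True
    return None


def _fatal_qualifies(person: PersonState, event_type: EventType) -> bool:
    last = person.history[-1]
    if last.event_type is not event_type or not last.fatal:
        return False
    if event_type is EventType.HF:
        return not any(r.event_type is EventType.IHD for r in person.history[:-1])
    return True


def event_table(cohort: Sequence[PersonState], scale: float = 100_000.0) -> pd.DataFrame:
    """Lifetime total and fatal event counts per ``scale`` births.

    One count per person per event type (first qualifying occurrence); the
    OTHER_DEATH row has totals equal to its fatal count by construction.
    """
    n = len(cohort)
    rows = []
    for ev in (*CLINICAL_EVENTS, EventType.OTHER_DEATH):
        if ev is EventType.OTHER_DEATH:
            fatal = sum(1 for p in cohort if p.history and p.history[-1].event_type is ev)
            total = fatal
        else:
            total = sum(1 for p in cohort if first_qualifying_event_age(p, ev) is not None)
            fatal = sum(1 for p in cohort if _fatal_qualifies(p, ev))
        factor = scale / n if n else 0.0
        rows.append({"event_type": ev.value, "total": total * factor, "fatal": fatal * factor})
    return pd.DataFrame(rows).set_index("event_type")


def cumulative_incidence(
    cohort: Sequence[PersonState], event_type: EventType, ages: Sequence[float]
) -> np.ndarray:
    """Crude cumulative first-event fraction by age (non-decreasing step curve)."""
    ages = np.asarray(ages, dtype=float)
    n = len(cohort)
    if n == 0:
        return np.zeros_like(ages)
    ev_ages = np.sort(
        [a for p in cohort if (a := first_qualifying_event_age(p, event_type)) is not None]
    )
    return np.searchsorted(ev_ages, ages, side="right") / n


def mortality_adjusted_cum_risk(
    cohort: Sequence[PersonState], event_type: EventType, ages: Sequence[float]
) -> np.ndarray:
    """Net cumulative event risk with competing deaths treated as censoring.

    Product-integral (Kaplan-Meier complement) of the cause-specific hazard:
    the hypothetical cumulative risk that would obtain absent competing
    mortality.  Dominates the crude cumulative incidence pointwise.
    """
    ages = np.asarray(ages, dtype=float)
    durations, observed = [], []
    for p in cohort:
        a = first_qualifying_event_age(p, event_type)
        if a is not None:
            durations.append(a)
            observed.append(1)
        else:
            durations.append(p.death_age)
            observed.append(0)
    if not durations or not any(observed):
        return np.zeros_like(ages)
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed, timeline=ages)
    return 1.0 - km.survival_function_.iloc[:, 0].to_numpy()


@dataclass
class CohortSummary:
    """Stratum-level lifetime summary: survival, QALYs, lipids and event counts."""

    stratum: int
    label: str  # "all", "female" or "male"
    life_expectancy: float
    lifetime_qalys: float
    mean_ldl: float
    mean_hdl: float
    events: pd.DataFrame  # index event_type, columns total/fatal per 100,000 births


def diabetes_onset_ages(
    cohort: Sequence[PersonState], population: PopulationConfig
) -> Dict[int, float]:
    """Invert the diabetes prevalence ramp at each person's latent uniform."""
    curve: Optional[PrevalenceCurve] = population.prevalence.get("diabetes")
    out: Dict[int, float] = {}
    if curve is None:
        return out
    for p in cohort:
        u = p.comorbidity_latents.get("diabetes")
        if u is None:
            continue
        peak = min(curve.max_prev[p.stratum - 1] * curve.sex_factor[p.sex], 0.995)
        if peak <= 0 or u >= peak:
            continue
        out[p.person_id] = curve.start_age + (u / peak) * (curve.end_age - curve.start_age)
    return out


def summarize_cohort(
    cohort: Sequence[PersonState],
    utility: UtilityModel,
    stratum: int,
    population: Optional[PopulationConfig] = None,
    scale: float = 100_000.0,
) -> Dict[str, CohortSummary]:
    """Per-sex and pooled summaries; the pooled row uses the union of persons."""
    onset = diabetes_onset_ages(cohort, population) if population is not None else None
    out: Dict[str, CohortSummary] = {}
    for label in ("all", "female", "male"):
        sub = [p for p in cohort if label == "all" or p.sex == label]
        if not sub:
            continue
        out[label] = CohortSummary(
            stratum=stratum,
            label=label,
            life_expectancy=life_expectancy(sub),
            lifetime_qalys=lifetime_qalys(sub, utility, onset),
            mean_ldl=float(np.mean([p.lipid.ldl_c for p in sub])),
            mean_hdl=float(np.mean([p.lipid.hdl_c for p in sub])),
            events=event_table(sub, scale),
        )
    return out
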