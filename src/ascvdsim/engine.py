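"""Discrete-event lifetime simulation under competing hazards.

Each person advances through annual (configurable) steps from birth to death
or the age cap.  Within a step, hazards are held piecewise-constant at their
start-of-step values and one candidate time is sampled per active event type
from its exponential clock; the earliest candidate inside the step fires and
the others are discarded.  Non-fatal events are recorded at the event time
and the person completes the step (at most one clinical event per step);
fatal events terminate the trajectory at the event time.  Survivors at the
age cap receive a terminal other-cause death exactly at the cap.

Randomness is organised as counter-based per-person substreams keyed by
(seed, person_id): each person consumes one pre-drawn block of exponential
and uniform variates, so cohort results are invariant to execution order and
to whether the scalar or the vectorized driver is used.  ``simulate_cohort``
runs a vectorized implementation of exactly the same per-step arithmetic and
reproduces the scalar ``simulate_person`` trajectories event-for-event.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .events import CLINICAL_EVENTS, EventRecord, EventType
from .hazards import (
    HazardModel,
    case_fatality_prob,
    comorbidity_factor,
    hf_hazard,
    ihd_hazard,
    mi_hazard,
    other_mortality_hazard,
    stroke_hazard,
)
from .population import (
    COMORBIDITIES,
    PersonState,
    PopulationConfig,
    update_comorbidity_flags,
)
from .units import MG_DL_PER_MMOL_L

__all__ = ["SimConfig", "step_person", "simulate_person", "simulate_cohort", "events_to_dataframe"]

#: Fixed competing order of event clocks within a step.
_EVENT_ORDER = (*CLINICAL_EVENTS, EventType.OTHER_DEATH)


@dataclass(frozen=True)
class SimConfig:
    """Engine settings: cycle length, age cap and the root simulation seed."""

    time_step: float = 1.0
    age_cap: float = 110.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.time_step <= 1.0):
            raise ValueError(f"time_step must be in (0, 1], got {self.time_step}")
        if self.age_cap <= 0:
            raise ValueError(f"age_cap must be > 0, got {self.age_cap}")

    def validate(self) -> List[tuple[str, bool, str]]:
        return [
            ("time_step in (0, 1]", 0.0 < self.time_step <= 1.0, str(self.time_step)),
            ("age_cap > 0", self.age_cap > 0, str(self.age_cap)),
        ]

    @property
    def n_steps(self) -> int:
        return int(math.ceil(self.age_cap / self.time_step - 1e-9))


def _rates(person: PersonState, model: HazardModel) -> List[float]:
    return [
        mi_hazard(person, model),
        ihd_hazard(person, model),
        stroke_hazard(person, model),
        hf_hazard(person, model),
        other_mortality_hazard(person, model),
    ]


def _apply_event(person: PersonState, etype: EventType, age_at_event: float, fatal: bool) -> None:
    person.history.append(EventRecord(etype, age_at_event, fatal))
    if fatal:
        person.alive = False
    else:
        if etype is EventType.MI:
            person.prior_mi = True
        elif etype is EventType.IHD:
            person.prior_ihd = True
        elif etype is EventType.IS:
            person.prior_is = True
        elif etype is EventType.HF:
            person.prior_hf = True


def step_person(
    person: PersonState,
    model: HazardModel,
    dt: float,
    rng: Optional[np.random.Generator] = None,
    draws: Optional[tuple[np.ndarray, float]] = None,
) -> PersonState:
    """Advance a living person by one step of length ``dt`` (years), in place.

    Competing candidate times are one exponential draw per event type divided
    by its start-of-step rate; the earliest candidate inside the step fires.
    ``draws`` may supply the pre-drawn (5 exponentials, 1 uniform) block used
    by the block-stream drivers; otherwise they are taken from ``rng``.
    """
    if not person.alive:
        raise ValueError("cannot step a dead person")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if draws is None:
        if rng is None:
            raise ValueError("either rng or draws must be provided")
        exps = rng.standard_exponential(5)
        u = float(rng.random())
    else:
        exps, u = draws

    rates = _rates(person, model)
    best_j, best_tau = -1, math.inf
    for j in range(5):
        tau = exps[j] / rates[j] if rates[j] > 0 else math.inf
        if tau < best_tau:
            best_j, best_tau = j, tau

    ldl_mgdl = person.lipid.ldl_c * MG_DL_PER_MMOL_L
    if best_tau >= dt:  # uneventful step
        person.cumulative_ldl_exposure += ldl_mgdl * dt
        person.age += dt
        return person

    etype = _EVENT_ORDER[best_j]
    fatal = etype is EventType.OTHER_DEATH or u < case_fatality_prob(etype, person, model)
    age_at_event = person.age + best_tau
    if fatal:
        person.cumulative_ldl_exposure += ldl_mgdl * best_tau
        person.age = age_at_event
    else:
        # one clinical event per step: the remainder of the step is event-free
        person.cumulative_ldl_exposure += ldl_mgdl * dt
        person.age += dt
    _apply_event(person, etype, age_at_event, fatal)
    return person


def simulate_person(
    person: PersonState,
    model: HazardModel,
    config: SimConfig,
    population: Optional[PopulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> PersonState:
    """Run one person from their current age to death or the age cap, in place.

    The person's substream is ``default_rng([config.seed, person_id])`` unless
    an explicit generator is given; one block of (n_steps x 5) exponentials
    and (n_steps) uniforms is drawn up front.  Survivors at the age cap get a
    terminal other-cause death at the cap, so every completed history ends in
    exactly one fatal record.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, person.person_id])
    n = config.n_steps
    exps = rng.standard_exponential((n, 5))
    us = rng.random(n)

    for t in range(n):
        if not person.alive:
            break
        if population is not None:
            update_comorbidity_flags(person, population, person.age)
        dt = min(config.time_step, config.age_cap - person.age)
        if dt <= 0:
            break
        step_person(person, model, dt, draws=(exps[t], us[t]))

    if person.alive:
        person.age = config.age_cap
        _apply_event(person, EventType.OTHER_DEATH, config.age_cap, True)
    return person


def simulate_cohort(
    cohort: Sequence[PersonState],
    model: HazardModel,
    config: SimConfig,
    population: Optional[PopulationConfig] = None,
    vectorized: bool = True,
) -> List[PersonState]:
    """Simulate every person in the cohort; input states are not mutated.

    Per-person substreams derive from (config.seed, person_id), so the result
    is independent of person ordering and of the execution strategy.  The
    vectorized driver performs the same per-step arithmetic as
    ``simulate_person`` on arrays across persons and yields identical
    trajectories.
    """
    persons = [copy.deepcopy(p) for p in cohort]
    if not persons:
        return []
    if not vectorized:
        return [simulate_person(p, model, config, population) for p in persons]
    _simulate_vectorized(persons, model, config, population)
    return persons


def _simulate_vectorized(
    persons: List[PersonState],
    model: HazardModel,
    config: SimConfig,
    population: Optional[PopulationConfig],
) -> None:
    n = len(persons)
    n_steps = config.n_steps

    sex_idx = np.array([0 if p.sex == "female" else 1 for p in persons])  # 0=f, 1=m
    strat = np.array([p.stratum - 1 for p in persons])
    ldl_mgdl = np.array([p.lipid.ldl_c * MG_DL_PER_MMOL_L for p in persons])

    # per-person constant factors, computed with scalar arithmetic so the
    # vector path reproduces the scalar path bit-for-bit where possible
    mult = np.array([model.ratio_multiplier[p.stratum - 1] for p in persons])
    stroke_ldl = np.array(
        [model.stroke_rr_per_mmol ** (model.stroke_ldl_ref - p.lipid.ldl_c) for p in persons]
    )
    sbp_terms = {}
    for ev in CLINICAL_EVENTS:
        per10 = model.comorbidity_rr.get("sbp_per10", {}).get(ev.value, 1.0)
        if per10 != 1.0:
            sbp_terms[ev] = np.array(
                [per10 ** ((p.sbp - model.sbp_ref) / 10.0) for p in persons]
            )
        else:
            sbp_terms[ev] = np.ones(n)
    cf = np.empty((n, 4))
    for j, ev in enumerate(CLINICAL_EVENTS):
        by_sex = model.case_fatality[ev.value]
        tbl = np.array([by_sex["female"], by_sex["male"]])  # (2, 4)
        cf[:, j] = tbl[sex_idx, strat]

    flags = {
        name: np.array([getattr(p, attr) for p in persons])
        for name, attr in (
            ("smoker", "smoker"),
            ("diabetes", "diabetes"),
            ("hypertension", "hypertension"),
            ("atrial_fibrillation", "atrial_fibrillation"),
        )
    }
    latents = {
        name: np.array([p.comorbidity_latents.get(name, 1.0) for p in persons])
        for name in COMORBIDITIES
    }
    prior_rec = np.array([p.prior_mi or p.prior_ihd for p in persons])

    exps = np.empty((n, n_steps, 5))
    us = np.empty((n, n_steps))
    for i, p in enumerate(persons):
        rng = np.random.default_rng([config.seed, p.person_id])
        exps[i] = rng.standard_exponential((n_steps, 5))
        us[i] = rng.random(n_steps)

    alive = np.ones(n, dtype=bool)
    exposure = np.array([p.cumulative_ldl_exposure for p in persons])
    age = persons[0].age if persons else 0.0
    if any(p.age != age for p in persons):
        raise ValueError("vectorized driver requires a common starting age; use vectorized=False")

    gm = {s: model.gompertz[s] for s in ("female", "male")}

    for t in range(n_steps):
        if not alive.any():
            break
        dt = min(config.time_step, config.age_cap - age)
        if dt <= 0:
            break

        if population is not None:
            for name in COMORBIDITIES:
                curve = population.prevalence.get(name)
                if curve is None:
                    continue
                prev = np.array(
                    [[curve(age, s, k + 1) for k in range(4)] for s in ("female", "male")]
                )
                flags[name] |= latents[name] < prev[sex_idx, strat]

        idx = np.nonzero(alive)[0]
        sx, st = sex_idx[idx], strat[idx]

        # comorbidity relative-risk products (same multiplication order as
        # hazards.comorbidity_factor: smoker, diabetes, hypertension, AF, SBP)
        rr = {}
        for ev in CLINICAL_EVENTS:
            acc = np.ones(len(idx))
            for name in ("smoker", "diabetes", "hypertension", "atrial_fibrillation"):
                r = model.comorbidity_rr.get(name, {}).get(ev.value, 1.0)
                if r != 1.0:
                    acc = acc * np.where(flags[name][idx], r, 1.0)
            rr[ev] = acc * sbp_terms[ev][idx]

        over = exposure[idx] - model.exposure_threshold
        excess = np.where(over > 0, np.exp(model.mi_excess_slope * np.maximum(over, 0.0)), 1.0)
        rec = np.where(prior_rec[idx], model.recurrent_multiplier, 1.0)

        base_mi = np.array([model.mi_baseline[s] * math.exp(model.mi_age_slope * age) for s in ("female", "male")])
        base_ihd = np.array([model.ihd_baseline[s] * math.exp(model.ihd_age_slope * age) for s in ("female", "male")])
        base_hf = np.array([model.hf_baseline[s] * math.exp(model.hf_age_slope * age) for s in ("female", "male")])
        if age >= model.stroke_onset_age:
            base_is = np.array(
                [
                    model.stroke_baseline[s]
                    * math.exp(model.stroke_age_slope * (age - model.stroke_onset_age))
                    for s in ("female", "male")
                ]
            )
        else:
            base_is = np.zeros(2)
        base_other = np.array([gm[s][0] + gm[s][1] * math.exp(gm[s][2] * age) for s in ("female", "male")])

        rates = np.empty((len(idx), 5))
        rates[:, 0] = base_mi[sx] * mult[idx] * excess * rr[EventType.MI] * rec
        rates[:, 1] = base_ihd[sx] * mult[idx] * excess * rr[EventType.IHD] * rec
        rates[:, 2] = base_is[sx] * stroke_ldl[idx] * rr[EventType.IS]
        rates[:, 3] = base_hf[sx] * rr[EventType.HF]
        rates[:, 4] = base_other[sx]

        taus = np.divide(
            exps[idx, t, :], rates, out=np.full((len(idx), 5), np.inf), where=rates > 0
        )
        j_min = np.argmin(taus, axis=1)
        tau_min = taus[np.arange(len(idx)), j_min]
        fired = tau_min < dt

        # uneventful persons advance to step end
        quiet = idx[~fired]
        exposure[quiet] += ldl_mgdl[quiet] * dt

        for k in np.nonzero(fired)[0]:
            i = idx[k]
            p = persons[i]
            j = int(j_min[k])
            etype = _EVENT_ORDER[j]
            tau = float(tau_min[k])
            fatal = bool(etype is EventType.OTHER_DEATH or us[i, t] < cf[i, j])
            if fatal:
                exposure[i] += ldl_mgdl[i] * tau
                alive[i] = False
                p.age = age + tau
            else:
                exposure[i] += ldl_mgdl[i] * dt
                if etype in (EventType.MI, EventType.IHD):
                    prior_rec[i] = True
            _apply_event(p, etype, age + tau, fatal)

        age += dt

    # write back completed state; cap survivors die of other causes at the cap
    for i, p in enumerate(persons):
        p.cumulative_ldl_exposure = float(exposure[i])
        p.smoker = bool(flags["smoker"][i])
        p.diabetes = bool(flags["diabetes"][i])
        p.hypertension = bool(flags["hypertension"][i])
        p.atrial_fibrillation = bool(flags["atrial_fibrillation"][i])
        if alive[i]:
            p.age = config.age_cap
            _apply_event(p, EventType.OTHER_DEATH, config.age_cap, True)
        else:
            p.alive = False


def events_to_dataframe(cohort: Sequence[PersonState]) -> pd.DataFrame:
    """Long-format event history: person_id, event_type, age_at_event, fatal."""
    rows = [
        {
            "person_id": p.person_id,
            "event_type": rec.event_type.value,
            "age_at_event": rec.age_at_event,
            "fatal": rec.fatal,
        }
        for p in cohort
        for rec in p.history
    ]
    return pd.DataFrame(rows, columns=["person_id", "event_type", "age_at_event", "fatal"])
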