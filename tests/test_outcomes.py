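import math

import numpy as np
import pytest

import ascvdsim as a
from ascvdsim.engine import SimConfig, simulate_cohort
from ascvdsim.events import EventRecord, EventType
from ascvdsim.outcomes import UtilityModel, first_qualifying_event_age

from conftest import constant_hazard_model, make_person


def dead_person(pid, death_age, events=(), sex="male"):
    """A completed person with given (type, age, fatal) events plus terminal death."""
    p = make_person(pid=pid, sex=sex, age=death_age)
    for etype, age, fatal in events:
        p.history.append(EventRecord(etype, age, fatal))
    if not p.history or not p.history[-1].fatal:
        p.history.append(EventRecord(EventType.OTHER_DEATH, death_age, True))
    p.alive = False
    return p


def flat_utility(u=1.0, decrements=None):
    return UtilityModel(
        intercept={"female": u, "male": u},
        age_slope=0.0,
        floor=0.0,
        decrements=decrements or {},
        discount_rate=0.0,
    )


class TestLifeExpectancy:
    def test_mean_of_death_ages(self):
        cohort = [dead_person(0, 60.0), dead_person(1, 80.0)]
        assert a.life_expectancy(cohort) == 70.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            a.life_expectancy([])

    def test_pooling_identity_for_equal_subcohorts(self):
        females = [dead_person(i, 82.02, sex="female") for i in range(5)]
        males = [dead_person(10 + i, 78.45, sex="male") for i in range(5)]
        pooled = a.life_expectancy(females + males)
        assert pooled == pytest.approx((82.02 + 78.45) / 2)

    def test_all_deaths_at_cap(self):
        cohort = [dead_person(i, 110.0) for i in range(3)]
        assert a.life_expectancy(cohort) == 110.0


class TestLifetimeQALYs:
    def test_unit_utility_equals_years_lived(self):
        p = dead_person(0, 10.0)
        assert a.lifetime_qalys(p, flat_utility(1.0)) == pytest.approx(10.0)

    def test_constant_utility_proportionality(self):
        cohort = [dead_person(0, 60.0), dead_person(1, 80.0)]
        u = 0.8
        assert a.lifetime_qalys(cohort, flat_utility(u)) == pytest.approx(u * 70.0)

    def test_midlife_decrement_trapezoid_oracle(self):
        """Piecewise-constant utility with one decrement matches hand integration."""
        p = dead_person(0, 30.0, events=[(EventType.MI, 12.5, False)])
        um = flat_utility(0.9, decrements={"post_mi": 0.8})
        hand = 0.9 * 12.5 + 0.9 * 0.8 * (30.0 - 12.5)
        assert a.lifetime_qalys(p, um) == pytest.approx(hand, rel=1e-12)

    def test_age_declining_baseline_closed_form(self):
        um = UtilityModel(
            intercept={"female": 0.9, "male": 0.9},
            age_slope=0.002,
            floor=0.0,
            decrements={},
            discount_rate=0.0,
        )
        p = dead_person(0, 50.0)
        hand = 0.9 * 50.0 - 0.002 * 50.0**2 / 2.0
        assert a.lifetime_qalys(p, um) == pytest.approx(hand, rel=1e-12)

    def test_discounting_reduces_qalys(self):
        p = dead_person(0, 40.0)
        um0 = flat_utility(1.0)
        um3 = UtilityModel(
            intercept={"female": 1.0, "male": 1.0},
            age_slope=0.0,
            floor=0.0,
            decrements={},
            discount_rate=0.03,
        )
        q3 = a.lifetime_qalys(p, um3)
        assert q3 < a.lifetime_qalys(p, um0)
        assert q3 == pytest.approx((1 - math.exp(-0.03 * 40.0)) / 0.03, rel=1e-9)

    def test_qaly_bounded_by_life_expectancy(self, completed_small, default_cfg):
        for done in completed_small.values():
            q = a.lifetime_qalys(done, default_cfg.utility)
            assert q <= a.life_expectancy(done)

    def test_invalid_utility_rejected(self):
        p = dead_person(0, 10.0)
        with pytest.raises(ValueError):
            a.lifetime_qalys(p, flat_utility(decrements={"post_mi": 0.0}))


class TestEventTable:
    def test_single_person_scaling(self):
        p = dead_person(0, 80.0, events=[(EventType.MI, 50.0, False)])
        tbl = a.event_table([p])
        assert tbl.loc["MI", "total"] == 100_000
        assert tbl.loc["MI", "fatal"] == 0
        assert tbl.loc["OTHER_DEATH", "fatal"] == 100_000

    def test_hf_after_ihd_excluded(self):
        p = dead_person(
            0, 80.0, events=[(EventType.IHD, 55.0, False), (EventType.HF, 60.0, False)]
        )
        tbl = a.event_table([p])
        assert tbl.loc["HF", "total"] == 0
        assert tbl.loc["IHD", "total"] == 100_000
        assert first_qualifying_event_age(p, EventType.HF) is None

    def test_hf_without_ihd_counted(self):
        p = dead_person(0, 80.0, events=[(EventType.HF, 60.0, False)])
        assert a.event_table([p]).loc["HF", "total"] == 100_000

    def test_fatal_never_exceeds_total(self, completed_small):
        for done in completed_small.values():
            tbl = a.event_table(done)
            assert (tbl["fatal"] <= tbl["total"] + 1e-9).all()
            assert (tbl >= 0).all().all()


class TestCumulativeIncidence:
    def test_no_events_zero_curve(self):
        cohort = [dead_person(i, 80.0) for i in range(4)]
        ages = np.arange(0, 111.0)
        assert (a.cumulative_incidence(cohort, EventType.IS, ages) == 0).all()

    def test_single_event_step_curve(self):
        p = dead_person(0, 80.0, events=[(EventType.IS, 50.0, False)])
        curve = a.cumulative_incidence([p], EventType.IS, [0.0, 49.9, 50.0, 80.0])
        assert list(curve) == [0.0, 0.0, 1.0, 1.0]

    def test_terminal_value_matches_event_table(self, completed_small):
        ages = np.arange(0, 111.0)
        for done in completed_small.values():
            tbl = a.event_table(done)
            for ev in (EventType.MI, EventType.IS, EventType.HF):
                curve = a.cumulative_incidence(done, ev, ages)
                assert curve[-1] * 100_000 == pytest.approx(tbl.loc[ev.value, "total"])
            assert (np.diff(curve) >= 0).all()


class TestMortalityAdjustedRisk:
    def test_equals_crude_without_competing_deaths(self):
        # every death occurs at the age cap, after all stroke events
        cohort = [dead_person(i, 110.0, events=[(EventType.IS, 50.0 + i, False)]) for i in range(5)]
        cohort += [dead_person(10 + i, 110.0) for i in range(5)]
        ages = np.arange(0.0, 110.0)  # before the common censoring age
        crude = a.cumulative_incidence(cohort, EventType.IS, ages)
        net = a.mortality_adjusted_cum_risk(cohort, EventType.IS, ages)
        assert net == pytest.approx(crude)

    def test_two_hazard_closed_form(self):
        """Equal constant stroke and death hazards: crude halves, net is exponential."""
        lam = 0.05
        m = constant_hazard_model(stroke=lam, other=lam, cf=1.0)
        cohort = [
            make_person(pid=i, age=0.0, ldl=3.0, hdl=1.2, stratum=2, exposure=0.0)
            for i in range(10_000)
        ]
        done = simulate_cohort(cohort, m, SimConfig(seed=21))
        ages = np.array([10.0, 20.0, 40.0, 80.0])
        crude = a.cumulative_incidence(done, EventType.IS, ages)
        net = a.mortality_adjusted_cum_risk(done, EventType.IS, ages)
        crude_expected = 0.5 * (1.0 - np.exp(-2 * lam * ages))
        net_expected = 1.0 - np.exp(-lam * ages)
        assert np.abs(crude - crude_expected).max() < 0.02
        assert np.abs(net - net_expected).max() < 0.02

    def test_net_dominates_crude(self, completed_small):
        ages = np.arange(0.0, 111.0)
        for done in completed_small.values():
            crude = a.cumulative_incidence(done, EventType.IS, ages)
            net = a.mortality_adjusted_cum_risk(done, EventType.IS, ages)
            assert (net >= crude - 1e-9).all()


class TestSummaries:
    def test_summarize_structure(self, completed_small, default_cfg):
        summ = a.summarize_cohort(completed_small[1], default_cfg.utility, 1, default_cfg.population)
        assert set(summ) == {"all", "female", "male"}
        cs = summ["all"]
        assert cs.stratum == 1
        assert cs.lifetime_qalys <= cs.life_expectancy
        assert cs.events.loc["MI", "fatal"] <= cs.events.loc["MI", "total"]
        # pooled LE equals the mean of the sex rows for equal sub-cohorts
        assert cs.life_expectancy == pytest.approx(
            (summ["female"].life_expectancy + summ["male"].life_expectancy) / 2
        )
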