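import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import ascvdsim as a
from ascvdsim.events import EventType
from ascvdsim.hazards import accumulate_exposure, case_fatality_prob, is_fatal
from ascvdsim.units import MG_DL_PER_MMOL_L, mg_years_to_mmol_years

from conftest import make_person


class TestExposure:
    def test_threshold_arithmetic(self):
        # 135 mg/dL sustained for 5000/135 years accrues exactly the threshold
        ldl = 135.0 / MG_DL_PER_MMOL_L
        assert accumulate_exposure(0.0, ldl, 5000.0 / 135.0) == pytest.approx(5000.0)

    def test_zero_dt_is_identity(self):
        assert accumulate_exposure(100.0, 3.5, 0.0) == 100.0

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            accumulate_exposure(0.0, 3.5, -1.0)

    def test_lifetime_exposure_in_mmol_years(self):
        """2.58 mmol/L over 80.23 years ~ 207 mmol-years of cumulative exposure."""
        mg_years = accumulate_exposure(0.0, 2.58, 80.23)
        assert mg_years == pytest.approx(8004.6, rel=1e-3)
        assert mg_years_to_mmol_years(mg_years) == pytest.approx(207.31, rel=5e-3)


class TestMIHazard:
    def test_continuous_at_threshold(self, model):
        at = make_person(exposure=model.exposure_threshold)
        below = make_person(exposure=model.exposure_threshold - 1e-9)
        h_at, h_below = a.mi_hazard(at, model), a.mi_hazard(below, model)
        assert h_at == pytest.approx(h_below, rel=1e-12)

    def test_zero_slope_removes_exposure_dependence(self, model):
        import copy

        m = copy.deepcopy(model)
        m.mi_excess_slope = 0.0
        hs = [a.mi_hazard(make_person(exposure=e), m) for e in (0, 4000, 8000, 20000)]
        assert len(set(hs)) == 1

    def test_excess_hazard_ratio_closed_form(self, model):
        h1 = a.mi_hazard(make_person(exposure=6000.0), model)
        h2 = a.mi_hazard(make_person(exposure=5500.0), model)
        assert h1 / h2 == pytest.approx(math.exp(500.0 * model.mi_excess_slope), rel=1e-12)

    def test_monotone_in_exposure(self, model):
        grid = np.linspace(0.0, 12000.0, 400)
        hs = [a.mi_hazard(make_person(exposure=e), model) for e in grid]
        assert all(b >= a_ for a_, b in zip(hs, hs[1:]))

    def test_threshold_identifiable_by_grid_scan(self, model):
        """The departure point from the plateau recovers the configured threshold."""
        grid = np.arange(0.0, 10_001.0, 1.0)
        hs = np.array([a.mi_hazard(make_person(exposure=e), model) for e in grid])
        plateau = hs[0]
        first_above = grid[np.argmax(hs > plateau * 1.001)]
        assert abs(first_above - model.exposure_threshold) <= 1.0 + (
            math.log(1.001) / model.mi_excess_slope
        )
        strictly_above = grid[np.argmax(hs > plateau)]
        assert abs((strictly_above - 1.0) - model.exposure_threshold) <= 1.0


class TestStrokeHazard:
    def test_reference_ldl_gives_baseline(self, model):
        p = make_person(age=70.0, ldl=model.stroke_ldl_ref)
        expected = model.stroke_baseline["male"] * math.exp(
            model.stroke_age_slope * (70.0 - model.stroke_onset_age)
        )
        assert a.stroke_hazard(p, model) == pytest.approx(expected, rel=1e-12)

    def test_sixteen_percent_reduction_per_mmol(self, model):
        ref, down = model.stroke_ldl_ref, model.stroke_ldl_ref - 1.0
        h_ref = a.stroke_hazard(make_person(age=70.0, ldl=ref), model)
        h_down = a.stroke_hazard(make_person(age=70.0, ldl=down), model)
        assert h_down / h_ref == pytest.approx(0.84, rel=1e-12)
        h_up = a.stroke_hazard(make_person(age=70.0, ldl=ref + 1.0), model)
        assert h_up / h_ref == pytest.approx(1.0 / 0.84, rel=1e-12)
        h_2down = a.stroke_hazard(make_person(age=70.0, ldl=ref - 2.0), model)
        assert h_2down / h_ref == pytest.approx(0.84**2, rel=1e-12)

    @settings(
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        ldl=st.floats(min_value=2.5, max_value=8.0),
        delta=st.floats(min_value=-2.0, max_value=2.0),
    )
    def test_proportionality_property(self, model, ldl, delta):
        h0 = a.stroke_hazard(make_person(age=75.0, ldl=ldl), model)
        h1 = a.stroke_hazard(make_person(age=75.0, ldl=ldl + delta), model)
        assert h1 / h0 == pytest.approx(model.stroke_rr_per_mmol ** (-delta), rel=1e-9)

    def test_zero_before_onset_age(self, model):
        assert a.stroke_hazard(make_person(age=model.stroke_onset_age - 0.01), model) == 0.0


class TestOtherHazards:
    def test_hf_independent_of_ldl(self, model):
        h1 = a.hf_hazard(make_person(ldl=2.0), model)
        h2 = a.hf_hazard(make_person(ldl=6.0), model)
        assert h1 == h2

    def test_ihd_shares_stratum_shape_with_mi(self, model):
        p1, p4 = make_person(stratum=1), make_person(stratum=4)
        assert a.ihd_hazard(p4, model) / a.ihd_hazard(p1, model) == pytest.approx(
            a.mi_hazard(p4, model) / a.mi_hazard(p1, model), rel=1e-12
        )

    def test_gompertz_at_age_zero(self):
        from conftest import constant_hazard_model

        m = constant_hazard_model()
        m.gompertz = {"female": (0.0, 0.01, 0.1), "male": (0.0, 0.01, 0.1)}
        assert a.other_mortality_hazard(make_person(age=0.0), m) == pytest.approx(0.01)

    @pytest.mark.parametrize("params", [(1e-4, 0.1), (1e-5, 0.12), (5e-4, 0.08)])
    def test_gompertz_median_survival_closed_form(self, params):
        """Numerical inversion of the survivor function matches the analytic median."""
        from scipy.integrate import quad
        from scipy.optimize import brentq

        from conftest import constant_hazard_model

        s_scale, shape = params
        m = constant_hazard_model()
        m.gompertz = {"female": (0.0, s_scale, shape), "male": (0.0, s_scale, shape)}

        def cumhaz(t):
            return quad(
                lambda u: a.other_mortality_hazard(make_person(age=u), m), 0.0, t, limit=200
            )[0]

        numeric_median = brentq(lambda t: cumhaz(t) - math.log(2), 1.0, 400.0)
        analytic = math.log(1.0 + shape * math.log(2) / s_scale) / shape
        assert numeric_median == pytest.approx(analytic, rel=1e-6)

    def test_all_hazards_nonnegative(self, model):
        for stratum in (1, 2, 3, 4):
            for age in (0.0, 30.0, 65.0, 100.0):
                p = make_person(age=age, stratum=stratum, smoker=True, diabetes=True)
                for fn in (a.mi_hazard, a.ihd_hazard, a.stroke_hazard, a.hf_hazard, a.other_mortality_hazard):
                    assert fn(p, model) >= 0.0


class TestCaseFatality:
    def test_degenerate_probabilities(self, model):
        import copy

        rng = np.random.default_rng(0)
        for prob, expected in ((0.0, False), (1.0, True)):
            m = copy.deepcopy(model)
            m.case_fatality["MI"] = {"female": [prob] * 4, "male": [prob] * 4}
            draws = [is_fatal(EventType.MI, make_person(), m, rng) for _ in range(100)]
            assert all(d == expected for d in draws)

    def test_binomial_recovery_at_half(self, model):
        import copy

        m = copy.deepcopy(model)
        m.case_fatality["MI"] = {"female": [0.5] * 4, "male": [0.5] * 4}
        rng = np.random.default_rng(3)
        n = 10_000
        frac = sum(is_fatal(EventType.MI, make_person(), m, rng) for _ in range(n)) / n
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_unknown_event_type_rejected(self, model):
        with pytest.raises(ValueError):
            is_fatal("not_an_event", make_person(), model, np.random.default_rng(0))

    def test_other_death_always_fatal(self, model):
        assert case_fatality_prob(EventType.OTHER_DEATH, make_person(), model) == 1.0
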