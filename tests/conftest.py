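import numpy as np
import pytest

import ascvdsim as a
from ascvdsim.hazards import HazardModel
from ascvdsim.population import LipidProfile, PersonState


@pytest.fixture(scope="session")
def default_cfg():
    return a.default_config()


@pytest.fixture()
def model(default_cfg):
    return default_cfg.hazards


def make_person(
    pid=0,
    sex="male",
    age=50.0,
    ldl=3.0,
    hdl=1.2,
    tg=1.5,
    stratum=2,
    exposure=None,
    **flags,
):
    p = PersonState(
        person_id=pid,
        sex=sex,
        age=age,
        lipid=LipidProfile(ldl, hdl, tg),
        stratum=stratum,
    )
    if exposure is None:
        exposure = ldl * 38.67 * age
    p.cumulative_ldl_exposure = exposure
    for k, v in flags.items():
        setattr(p, k, v)
    return p


def constant_hazard_model(mi=0.0, ihd=0.0, stroke=0.0, hf=0.0, other=0.0, cf=1.0):
    """A model in which every hazard is constant in age and state."""
    return HazardModel(
        mi_baseline={"female": mi, "male": mi},
        mi_age_slope=0.0,
        mi_excess_slope=0.0,
        ratio_multiplier=(1.0, 1.0, 1.0, 1.0),
        ihd_baseline={"female": ihd, "male": ihd},
        ihd_age_slope=0.0,
        stroke_baseline={"female": stroke, "male": stroke},
        stroke_age_slope=0.0,
        stroke_onset_age=0.0,
        stroke_ldl_ref=3.0,
        hf_baseline={"female": hf, "male": hf},
        hf_age_slope=0.0,
        gompertz={"female": (other, 0.0, 0.1), "male": (other, 0.0, 0.1)},
        case_fatality={
            ev: {"female": [cf] * 4, "male": [cf] * 4} for ev in ("MI", "IHD", "IS", "HF")
        },
        comorbidity_rr={},
        recurrent_multiplier=1.0,
    )


@pytest.fixture(scope="session")
def completed_small(default_cfg):
    """Four simulated strata at n=400 each, for structural outcome checks."""
    import copy

    cfg = copy.deepcopy(default_cfg)
    cfg.population.n_per_stratum = 400
    out = {}
    for s in (1, 2, 3, 4):
        cohort = a.sample_cohort(cfg.population, s)
        out[s] = a.simulate_cohort(cohort, cfg.hazards, cfg.sim, cfg.population)
    return out
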