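"""Synthetic birth cohorts stratified by HDL-C/LDL-C ratio.

The generator emulates the statistical shape of adult lipid panels (CDC-like
correlated LDL-C/HDL-C/triglyceride distributions), age-parametrised
comorbidity prevalence (smoking, diabetes, hypertension, atrial fibrillation)
and sex-specific metabolic markers (HbA1c, SBP, BMI).  Each person carries a
single lifetime lipid set-point: lipid levels are treated as stable over the
life course, so the cumulative LDL-C exposure of a person is simply the
set-point times the years lived.

Stratification is by the HDL-C/LDL-C ratio, cut at 0.45 / 0.35 / 0.25 into
four groups (low, moderate, high and very high lipid risk), with a parallel
four-way split on LDL-C alone at 3.1 / 4.0 / 5.0 mmol/L.  Intervals are
lower-closed: a ratio of exactly 0.45 is low risk, an LDL-C of exactly
3.1 mmol/L falls in the second LDL group.

Sampling design
---------------
Within a stratum, the ratio is drawn from a log-normal restricted to the
stratum's half-open interval by rejection, and LDL-C from an independent
log-normal; HDL-C is their product.  The underlying log-normal location for
the ratio is pre-compensated analytically (truncated log-normal mean, solved
by root finding) so that the *post-rejection* stratum means of LDL-C and
HDL-C equal the configured targets exactly in expectation.  Triglycerides
share a latent Gaussian with the ratio with negative loading, giving the
negative TG/HDL-C correlation seen in population panels while keeping the
configured TG mean exact.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .units import MG_DL_PER_MMOL_L

__all__ = [
    "LipidProfile",
    "RiskGroupSpec",
    "PersonState",
    "PrevalenceCurve",
    "StratumLipidParams",
    "PopulationConfig",
    "assign_risk_group",
    "assign_ldl_group",
    "sample_cohort",
    "attach_comorbidities",
    "cohort_to_dataframe",
]

SEXES = ("female", "male")
COMORBIDITIES = ("smoker", "diabetes", "hypertension", "atrial_fibrillation")


class InvalidProfileError(ValueError):
    """Raised for non-finite or non-positive lipid inputs."""


class InfeasibleStratumError(RuntimeError):
    """Raised when rejection sampling for a stratum falls below the acceptance floor."""


@dataclass(frozen=True)
class LipidProfile:
    """Lifetime lipid set-point for one person (all concentrations mmol/L)."""

    ldl_c: float
    hdl_c: float
    triglycerides: float

    def __post_init__(self) -> None:
        for name in ("ldl_c", "hdl_c", "triglycerides"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidProfileError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def ratio(self) -> float:
        """HDL-C/LDL-C ratio, the primary risk stratifier."""
        return self.hdl_c / self.ldl_c


@dataclass(frozen=True)
class RiskGroupSpec:
    """Cut points for the ratio strata and the LDL-C groups.

    ``ratio_cutoffs`` are strictly decreasing; ``ldl_cutoffs`` (mmol/L)
    strictly increasing.  Both partitions are lower-closed.
    """

    ratio_cutoffs: Sequence[float] = (0.45, 0.35, 0.25)
    ldl_cutoffs: Sequence[float] = (3.1, 4.0, 5.0)

    def __post_init__(self) -> None:
        r, l = list(self.ratio_cutoffs), list(self.ldl_cutoffs)
        if len(r) != 3 or sorted(r, reverse=True) != r or len(set(r)) != 3:
            raise ValueError(f"ratio_cutoffs must be 3 strictly decreasing values, got {r}")
        if len(l) != 3 or sorted(l) != l or len(set(l)) != 3:
            raise ValueError(f"ldl_cutoffs must be 3 strictly increasing values, got {l}")

    def ratio_interval(self, stratum: int) -> tuple[float, float]:
        """Half-open ratio interval ``[lo, hi)`` for stratum 1..4 (hi=inf for 1)."""
        c = self.ratio_cutoffs
        bounds = [(c[0], math.inf), (c[1], c[0]), (c[2], c[1]), (0.0, c[2])]
        return bounds[stratum - 1]


def assign_risk_group(profile: LipidProfile, spec: RiskGroupSpec = RiskGroupSpec()) -> int:
    """Ratio stratum 1 (low risk, ratio >= 0.45) .. 4 (very high risk, < 0.25)."""
    r = profile.ratio
    if not (math.isfinite(r) and r > 0):
        raise InvalidProfileError(f"ratio must be finite and positive, got {r!r}")
    c = spec.ratio_cutoffs
    if r >= c[0]:
        return 1
    if r >= c[1]:
        return 2
    if r >= c[2]:
        return 3
    return 4


def assign_ldl_group(profile: LipidProfile, spec: RiskGroupSpec = RiskGroupSpec()) -> int:
    """LDL-C group 1 (< 3.1 mmol/L) .. 4 (> 5.0 mmol/L), lower-closed interiors."""
    x = profile.ldl_c
    c = spec.ldl_cutoffs
    if x < c[0]:
        return 1
    if x < c[1]:
        return 2
    if x < c[2]:
        return 3
    return 4


@dataclass
class PersonState:
    """One simulated individual, from birth through completed lifetime."""

    person_id: int
    sex: str
    age: float = 0.0
    lipid: Optional[LipidProfile] = None
    smoker: bool = False
    diabetes: bool = False
    hba1c: float = 5.3
    sbp: float = 120.0
    hypertension: bool = False
    atrial_fibrillation: bool = False
    bmi: float = 25.0
    cumulative_ldl_exposure: float = 0.0  # mg/dL-years
    alive: bool = True
    history: list = field(default_factory=list)
    stratum: int = 0
    # latent uniforms coupling comorbidity onset monotonically across ages
    comorbidity_latents: Dict[str, float] = field(default_factory=dict)
    prior_mi: bool = False
    prior_ihd: bool = False
    prior_is: bool = False
    prior_hf: bool = False

    @property
    def death_age(self) -> float:
        """Age at the fatal event; raises if the person is still alive."""
        if self.alive or not self.history:
            raise ValueError("person has no fatal record yet")
        last = self.history[-1]
        if not last.fatal:
            raise ValueError("last history record is not fatal")
        return last.age_at_event


@dataclass(frozen=True)
class PrevalenceCurve:
    """Age-ramp prevalence: 0 before ``start_age``, linear to ``max_prev`` at ``end_age``.

    ``max_prev`` is per ratio stratum (index 0 = stratum 1); ``sex_factor``
    scales it by sex.  Curves are non-decreasing in age so that a fixed latent
    uniform per person yields onset that can only switch on, never off.
    """

    start_age: float
    end_age: float
    max_prev: Sequence[float]
    sex_factor: Dict[str, float]

    def __call__(self, age: float, sex: str, stratum: int) -> float:
        frac = min(max((age - self.start_age) / (self.end_age - self.start_age), 0.0), 1.0)
        return min(frac * self.max_prev[stratum - 1] * self.sex_factor[sex], 0.995)


@dataclass(frozen=True)
class StratumLipidParams:
    """Log-normal lipid parameters for one (stratum, sex) cell.

    ``ratio_mean``/``ldl_mean``/``tg_mean`` are the target arithmetic means of
    the generated stratum (mmol/L for concentrations); the sigmas are
    log-scale standard deviations; ``tg_ratio_rho`` is the loading of the TG
    latent on the (negated) ratio latent.
    """

    ratio_mean: float
    ldl_mean: float
    tg_mean: float
    ratio_log_sd: float = 0.25
    ldl_log_sd: float = 0.20
    tg_log_sd: float = 0.45
    tg_ratio_rho: float = 0.4

    def __post_init__(self) -> None:
        if not (abs(self.tg_ratio_rho) <= 1.0):
            raise ValueError("tg_ratio_rho must lie in [-1, 1] (PSD latent correlation)")


@dataclass
class PopulationConfig:
    """Everything needed to draw seeded synthetic birth cohorts."""

    n_per_stratum: int = 1000
    sex_split: float = 0.5  # fraction female
    seed: int = 0
    spec: RiskGroupSpec = field(default_factory=RiskGroupSpec)
    lipids: Dict[int, Dict[str, StratumLipidParams]] = field(default_factory=dict)
    prevalence: Dict[str, PrevalenceCurve] = field(default_factory=dict)
    hba1c_mean: Dict[int, float] = field(default_factory=dict)
    hba1c_sd: float = 0.45
    sbp_mean: Dict[str, Dict[int, float]] = field(default_factory=dict)
    sbp_sd: float = 12.0
    bmi_mean: Dict[str, Dict[int, float]] = field(default_factory=dict)
    bmi_sd: float = 4.0
    acceptance_floor: float = 1e-3

    def validate(self) -> List[tuple[str, bool, str]]:
        """Per-rule validation report: (rule, passed, detail)."""
        rules: List[tuple[str, bool, str]] = []
        rules.append(("n_per_stratum >= 1", self.n_per_stratum >= 1, str(self.n_per_stratum)))
        rules.append(("sex_split in [0,1]", 0.0 <= self.sex_split <= 1.0, str(self.sex_split)))
        ok = True
        try:
            RiskGroupSpec(self.spec.ratio_cutoffs, self.spec.ldl_cutoffs)
        except ValueError:
            ok = False
        rules.append(("risk-group cutoffs ordered", ok, str(self.spec)))
        prev_ok = all(
            0.0 <= m <= 1.0 for c in self.prevalence.values() for m in c.max_prev
        )
        rules.append(("prevalences in [0,1]", prev_ok, ""))
        psd_ok = all(
            abs(p.tg_ratio_rho) <= 1.0 for by_sex in self.lipids.values() for p in by_sex.values()
        )
        rules.append(("lipid latent correlation PSD", psd_ok, ""))
        pos_ok = all(
            p.ratio_mean > 0 and p.ldl_mean > 0 and p.tg_mean > 0
            for by_sex in self.lipids.values()
            for p in by_sex.values()
        )
        rules.append(("lipid means positive", pos_ok, ""))
        return rules


def _truncated_lognormal_mu(target_mean: float, sigma: float, lo: float, hi: float) -> float:
    """Log-normal location whose [lo, hi)-truncated mean equals ``target_mean``.

    Closed-form truncated moment inverted by bracketed root finding; raises if
    the target is unattainable on the interval at the given sigma.
    """

    log_lo = math.log(lo) if lo > 0 else -math.inf
    log_hi = math.log(hi) if math.isfinite(hi) else math.inf

    def trunc_mean(mu: float) -> float:
        a = (log_lo - mu) / sigma
        b = (log_hi - mu) / sigma
        denom = norm.cdf(b) - norm.cdf(a)
        if denom <= 0:
            return lo if mu < log_lo else hi
        num = norm.cdf(b - sigma) - norm.cdf(a - sigma)
        return math.exp(mu + 0.5 * sigma**2) * num / denom

    center = math.log(target_mean)
    lo_mu, hi_mu = center - 8.0, center + 8.0
    f_lo, f_hi = trunc_mean(lo_mu) - target_mean, trunc_mean(hi_mu) - target_mean
    if f_lo * f_hi > 0:
        raise ValueError(
            f"truncated mean {target_mean} unattainable on [{lo}, {hi}) with sigma {sigma}"
        )
    return brentq(lambda mu: trunc_mean(mu) - target_mean, lo_mu, hi_mu, xtol=1e-12)


def _sample_lipids(
    n: int,
    params: StratumLipidParams,
    interval: tuple[float, float],
    rng: np.random.Generator,
    acceptance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` (ldl, hdl, tg) triples with the ratio confined to ``interval``.

    The ratio is rejection-sampled from a log-normal whose location is
    pre-compensated so the truncated mean matches ``params.ratio_mean``.
    """

    lo, hi = interval
    mu_r = _truncated_lognormal_mu(params.ratio_mean, params.ratio_log_sd, lo, hi)

    ratio = np.empty(n)
    z_ratio = np.empty(n)
    filled = 0
    drawn = 0
    while filled < n:
        batch = max(4 * (n - filled), 256)
        z = rng.standard_normal(batch)
        cand = np.exp(mu_r + params.ratio_log_sd * z)
        keep = (cand >= lo) & (cand < hi)
        drawn += batch
        k = min(int(keep.sum()), n - filled)
        idx = np.nonzero(keep)[0][:k]
        ratio[filled : filled + k] = cand[idx]
        z_ratio[filled : filled + k] = z[idx]
        filled += k
        if drawn > 1024 and filled / drawn < acceptance_floor:
            raise InfeasibleStratumError(
                f"ratio acceptance rate {filled/drawn:.2e} below floor {acceptance_floor:g} "
                f"for interval [{lo}, {hi})"
            )

    mu_l = math.log(params.ldl_mean) - 0.5 * params.ldl_log_sd**2
    ldl = np.exp(mu_l + params.ldl_log_sd * rng.standard_normal(n))
    hdl = ratio * ldl

    # TG latent loads negatively on the ratio latent -> negative TG/HDL corr.
    rho = params.tg_ratio_rho
    z_tg = -rho * z_ratio + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    mu_t = math.log(params.tg_mean) - 0.5 * params.tg_log_sd**2
    tg = np.exp(mu_t + params.tg_log_sd * z_tg)
    return ldl, hdl, tg


def attach_comorbidities(
    person: PersonState, config: PopulationConfig, rng: np.random.Generator
) -> PersonState:
    """Draw (or refresh) comorbidity flags and metabolic markers for ``person``.

    On first invocation a latent uniform per comorbidity and the HbA1c/SBP/BMI
    values are drawn; the flag for condition ``c`` at age ``a`` is
    ``latent < prevalence_c(a)``.  Because the prevalence curves are
    non-decreasing in age, re-invoking at an older age can only switch flags
    on, never off.
    """

    if not person.comorbidity_latents:
        for name in COMORBIDITIES:
            person.comorbidity_latents[name] = float(rng.random())
        s = person.stratum if person.stratum else 1
        person.hba1c = float(config.hba1c_mean.get(s, 5.3) + config.hba1c_sd * rng.standard_normal())
        person.sbp = float(
            config.sbp_mean.get(person.sex, {}).get(s, 120.0)
            + config.sbp_sd * rng.standard_normal()
        )
        person.bmi = float(
            config.bmi_mean.get(person.sex, {}).get(s, 25.0)
            + config.bmi_sd * rng.standard_normal()
        )
    update_comorbidity_flags(person, config, person.age)
    return person


def update_comorbidity_flags(person: PersonState, config: PopulationConfig, age: float) -> None:
    """Set comorbidity flags from the stored latents at the given age."""
    s = person.stratum if person.stratum else 1
    for name in COMORBIDITIES:
        curve = config.prevalence.get(name)
        u = person.comorbidity_latents.get(name)
        if curve is None or u is None:
            continue
        if u < curve(age, person.sex, s):
            setattr(person, name, True)


def sample_cohort(config: PopulationConfig, stratum: int) -> List[PersonState]:
    """Seeded birth cohort of ``config.n_per_stratum`` persons in one ratio stratum.

    The sex split is deterministic (first ``round(n * sex_split)`` persons are
    female), lipids are lifetime set-points confined to the stratum's ratio
    interval, and comorbidity latents are drawn at birth.  Identical
    (config, stratum) pairs yield field-for-field identical cohorts.
    """

    if not 1 <= stratum <= 4:
        raise ValueError(f"stratum must be in 1..4, got {stratum}")
    for rule, ok, detail in config.validate():
        if not ok:
            raise ValueError(f"invalid population config: {rule} ({detail})")

    n = config.n_per_stratum
    n_female = round(n * config.sex_split)
    interval = config.spec.ratio_interval(stratum)
    rng = np.random.default_rng([config.seed, stratum])

    persons: List[PersonState] = []
    for sex, count in (("female", n_female), ("male", n - n_female)):
        if count == 0:
            continue
        params = config.lipids[stratum][sex]
        ldl, hdl, tg = _sample_lipids(count, params, interval, rng, config.acceptance_floor)
        for i in range(count):
            pid = stratum * 1_000_000 + (0 if sex == "female" else 500_000) + i
            p = PersonState(
                person_id=pid,
                sex=sex,
                lipid=LipidProfile(float(ldl[i]), float(hdl[i]), float(tg[i])),
                stratum=stratum,
            )
            attach_comorbidities(p, config, rng)
            persons.append(p)
    return persons


def cohort_to_dataframe(cohort: Sequence[PersonState]) -> pd.DataFrame:
    """One row per person, matching the documented cohort CSV schema."""
    rows = [
        {
            "person_id": p.person_id,
            "sex": p.sex,
            "ldl_c": p.lipid.ldl_c,
            "hdl_c": p.lipid.hdl_c,
            "tg": p.lipid.triglycerides,
            "smoker": p.smoker,
            "diabetes": p.diabetes,
            "hba1c": p.hba1c,
            "sbp": p.sbp,
            "hypertension": p.hypertension,
            "af": p.atrial_fibrillation,
            "bmi": p.bmi,
            "stratum": p.stratum,
        }
        for p in cohort
    ]
    return pd.DataFrame(rows)
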