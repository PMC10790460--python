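"""Synthetic child-immunization surveys with planted inequity.

Generates populations shaped like a DHS child recode — categorical
household/child covariates, an asset battery loading on a latent
socioeconomic factor, survey weights, and per-antigen-dose receipt
indicators — from a logistic data-generating process with *known*
log-odds effects, so every downstream equity stage can be checked
against an analytic oracle (:func:`expected_stratum_coverage`).

Dose receipt is only generated for doses already due at the child's age
(in completed months); not-yet-due doses are recorded as 0. An optional
``monotone_doses`` flag makes dose k of an antigen require dose k-1,
mimicking the near-monotone drop-out pattern of real schedules.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._stats import fractional_rank, rank_quintile
from .schedule import Schedule, uganda_epi_schedule

SES_LEVELS = (1, 2, 3, 4, 5)

DEFAULT_REGION_LEVELS = {"central": 0.30, "eastern": 0.25, "northern": 0.20,
                         "western": 0.25}
DEFAULT_EDUCATION_LEVELS = {"none": 0.25, "primary": 0.55, "secondary+": 0.20}
DEFAULT_URBAN_PROB = 0.25
DEFAULT_CHILD_EFFECT_SD = 2.5


@dataclass
class DoseEffects:
    """Planted log-odds effects on one antigen-dose.

    ``coefficients`` maps covariate name -> {level: log-odds shift};
    levels not listed (the reference) contribute 0.
    """
    intercept: float = 0.0
    coefficients: Mapping[str, Mapping] = field(default_factory=dict)


def default_effects(schedule: Optional[Schedule] = None,
                    child_effect_sd: float = DEFAULT_CHILD_EFFECT_SD,
                    ) -> dict[str, DoseEffects]:
    """Default planted structure: per-dose coverage targets with modest
    education / wealth / residence / region gradients.

    Intercepts are calibrated so the population-average receipt
    probability among *due* children (marginal over the default
    covariate mix and the child-level heterogeneity) equals each dose's
    target coverage.
    """
    schedule = schedule or uganda_epi_schedule()
    target = {"bcg": 0.90, "opv0": 0.85, "opv1": 0.88, "opv2": 0.80, "opv3": 0.66,
              "dpt1": 0.88, "dpt2": 0.82, "dpt3": 0.74,
              "pcv1": 0.80, "pcv2": 0.73, "pcv3": 0.64, "mcv1": 0.80}
    grad = {
        "maternal_education": {"none": -0.50, "primary": -0.25},
        "ses_quintile": {1: -0.45, 2: -0.30, 3: -0.20, 4: -0.10},
        "residence": {"rural": -0.25},
        "region": {"northern": -0.20, "eastern": -0.10},
    }
    level_probs = {
        "maternal_education": DEFAULT_EDUCATION_LEVELS,
        "ses_quintile": {q: 0.2 for q in SES_LEVELS},
        "residence": {"urban": DEFAULT_URBAN_PROB, "rural": 1 - DEFAULT_URBAN_PROB},
        "region": DEFAULT_REGION_LEVELS,
    }
    strata = []
    for combo in itertools.product(*(level_probs[c].items() for c in grad)):
        prob = float(np.prod([p for _, p in combo]))
        shift = sum(_coef(grad[c], lvl) for c, (lvl, _) in zip(grad, combo))
        strata.append((prob, shift))

    def _population_coverage(intercept: float) -> float:
        return sum(p * _marginal_logistic(intercept + s, child_effect_sd)
                   for p, s in strata)

    out = {}
    for name in schedule.dose_names:
        t = target.get(name, 0.75)
        b = brentq(lambda x: _population_coverage(x) - t, -15.0, 15.0)
        out[name] = DoseEffects(float(b), grad)
    return out


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic survey."""
    n_children: int = 2000
    seed: int = 0
    region_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LEVELS))
    urban_prob: float = DEFAULT_URBAN_PROB
    education_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_LEVELS))
    insurance_prob: float = 0.05
    female_prob: float = 0.49
    #: probability of each age 0..59 months; None = uniform
    age_month_probs: Optional[Sequence[float]] = None
    #: loading of each binary asset on the latent SES factor
    asset_loadings: Sequence[float] = (1.2, 1.1, 1.0, 1.0, 0.9, 0.9, 0.8, 0.7, 0.6, 0.5)
    #: logit-scale prevalence intercept per asset; None = spread over [-1.5, 1.5]
    asset_intercepts: Optional[Sequence[float]] = None
    effects: Mapping[str, DoseEffects] = field(default_factory=default_effects)
    #: SD of a child-level log-odds intercept shared across all doses;
    #: induces the strong cross-dose correlation of real schedules
    #: (children tend to get everything or nothing), without which
    #: zero-dose and fully-immunized rates would be unrealistically
    #: near zero. Set to 0 for dose independence given covariates.
    child_effect_sd: float = DEFAULT_CHILD_EFFECT_SD
    weight_model: str = "ones"  # "ones" | "lognormal"
    weight_sigma: float = 0.35
    monotone_doses: bool = False
    missing_rate: float = 0.0
    schedule: Schedule = field(default_factory=uganda_epi_schedule)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        for name in ("urban_prob", "insurance_prob", "female_prob", "missing_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("region_levels", "education_levels"):
            levels = getattr(self, name)
            if not levels:
                raise ValueError(f"{name} must not be empty")
            probs = np.asarray(list(levels.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if self.age_month_probs is not None:
            p = np.asarray(self.age_month_probs, dtype=float)
            if p.shape != (60,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("age_month_probs must be 60 non-negative probabilities summing to 1")
        if len(self.asset_loadings) < 1:
            raise ValueError("asset_loadings must not be empty")
        if self.asset_intercepts is not None and \
                len(self.asset_intercepts) != len(self.asset_loadings):
            raise ValueError("asset_intercepts must match asset_loadings in length")
        if self.child_effect_sd < 0:
            raise ValueError("child_effect_sd must be >= 0")
        if self.weight_model not in ("ones", "lognormal"):
            raise ValueError(f"unknown weight_model {self.weight_model!r}")
        known = set(self.schedule.dose_names)
        for dose in self.effects:
            if dose not in known:
                raise ValueError(f"effects refer to unknown antigen-dose {dose!r}")

    def covariate_levels(self) -> dict[str, list]:
        return {
            "region": list(self.region_levels),
            "residence": ["urban", "rural"],
            "maternal_education": list(self.education_levels),
            "ses_quintile": list(SES_LEVELS),
            "sex": ["female", "male"],
            "insured": ["yes", "no"],
        }


def _coef(levels_map: Mapping, value) -> float:
    # tolerate int/str mismatches from YAML round-trips
    if value in levels_map:
        return float(levels_map[value])
    return float(levels_map.get(str(value), 0.0))


def _linear_predictor(eff: DoseEffects, covs: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    eta = np.full(n, eff.intercept, dtype=float)
    for cov, levels_map in eff.coefficients.items():
        if cov not in covs:
            raise ValueError(f"effects refer to unknown covariate {cov!r}")
        col = covs[cov]
        eta += np.array([_coef(levels_map, v) for v in col])
    return eta


def generate_population(config: SimConfig) -> pd.DataFrame:
    """Draw a population table; identical config + seed reproduces it exactly."""
    config.validate()
    n = config.n_children
    rng = np.random.default_rng(config.seed)

    ages = rng.choice(60, size=n, p=config.age_month_probs)
    sex = np.where(rng.random(n) < config.female_prob, "female", "male")
    region = rng.choice(list(config.region_levels), size=n,
                        p=list(config.region_levels.values()))
    residence = np.where(rng.random(n) < config.urban_prob, "urban", "rural")
    education = rng.choice(list(config.education_levels), size=n,
                           p=list(config.education_levels.values()))
    insured = np.where(rng.random(n) < config.insurance_prob, "yes", "no")

    latent = rng.standard_normal(n)
    loadings = np.asarray(config.asset_loadings, dtype=float)
    intercepts = (np.asarray(config.asset_intercepts, dtype=float)
                  if config.asset_intercepts is not None
                  else np.linspace(-1.5, 1.5, len(loadings)))
    asset_p = expit(intercepts[None, :] + latent[:, None] * loadings[None, :])
    assets = (rng.random((n, len(loadings))) < asset_p).astype(int)

    if config.weight_model == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    else:
        weights = np.ones(n)

    child_effect = rng.standard_normal(n) * config.child_effect_sd

    ses_quintile = rank_quintile(fractional_rank(latent, weights))

    pop = pd.DataFrame({
        "child_id": np.arange(n),
        "age_months": ages.astype(int),
        "sex": sex,
        "region": region,
        "residence": residence,
        "maternal_education": education,
        "insured": insured,
        "weight": weights,
        "ses_quintile": ses_quintile,
    })
    for j in range(len(loadings)):
        pop[f"asset_{j + 1}"] = assets[:, j]

    covs = {c: pop[c].to_numpy() for c in
            ("region", "residence", "maternal_education", "ses_quintile", "sex", "insured")}
    received_prev: dict[tuple[str, int], np.ndarray] = {}
    for entry in config.schedule.entries:
        eff = config.effects.get(entry.name, DoseEffects())
        p = expit(_linear_predictor(eff, covs, n) + child_effect)
        due = pop["age_months"].to_numpy() >= entry.due_age_months
        got = (rng.random(n) < p) & due
        if config.monotone_doses:
            prev = received_prev.get((entry.antigen, entry.dose_number - 1))
            if prev is not None:
                got &= prev
        received_prev[(entry.antigen, entry.dose_number)] = got
        col = got.astype(float)
        if config.missing_rate > 0:
            miss = (rng.random(n) < config.missing_rate) & due
            col = np.where(miss, np.nan, col)
        pop[entry.name] = col
    return pop


def _marginal_logistic(eta: float, sd: float, _gh=np.polynomial.hermite.hermgauss(80)) -> float:
    """E[logistic(eta + u)] for u ~ N(0, sd), by Gauss-Hermite quadrature."""
    if sd == 0:
        return float(expit(eta))
    x, w = _gh
    return float(np.sum(w * expit(eta + np.sqrt(2.0) * sd * x)) / np.sqrt(np.pi))


def expected_stratum_coverage(config: SimConfig, antigen_dose: str) -> pd.DataFrame:
    """Analytic receipt probability per covariate stratum, among children
    for whom the dose is due.

    Enumerates every combination of the covariate levels entering the
    dose's planted effects and applies the logistic transform,
    marginalized over the child-level heterogeneity by Gauss-Hermite
    quadrature; independent of the seed.
    """
    if antigen_dose not in config.schedule.dose_names:
        raise ValueError(f"unknown antigen-dose {antigen_dose!r}")
    eff = config.effects.get(antigen_dose, DoseEffects())
    all_levels = config.covariate_levels()
    covs = list(eff.coefficients)
    for cov in covs:
        if cov not in all_levels:
            raise ValueError(f"effects refer to unknown covariate {cov!r}")
    sd = config.child_effect_sd
    if not covs:
        return pd.DataFrame({"probability": [_marginal_logistic(eff.intercept, sd)]})
    rows = []
    for combo in itertools.product(*(all_levels[c] for c in covs)):
        eta = eff.intercept + sum(_coef(eff.coefficients[c], v)
                                  for c, v in zip(covs, combo))
        rows.append(dict(zip(covs, combo), probability=_marginal_logistic(eta, sd)))
    return pd.DataFrame(rows)
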