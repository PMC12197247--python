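"""Synthetic DVT cohort generator with confounded assignment and known effects.

Emulates the statistical structure of a two-arm retrospective inpatient
cohort: 17 baseline covariates with skew-tolerant marginals (truncated
normals for labs and anthropometrics, Bernoulli gender, discretized gamma
Wells score), a logistic treatment-assignment model whose nonzero slopes
sit on the covariates that were imbalanced in real data (APTT, PLT, WBC,
TT, gender), and outcome models with injectable true treatment effects:

- symptom improvement fraction ``f`` (IPR = 100·f) shifted additively by
  treatment, so the injected IPR effect is directly in percentage points;
- length of stay shifted additively (days);
- cost log-normal, increasing in LOS and day-1 severity, shifted
  multiplicatively by treatment.

Both potential outcomes are generated for every record and the observed one
selected by the assigned arm, so the consistency axiom holds exactly and a
Monte-Carlo oracle (:func:`ground_truth`) can compute the true average
causal effect on every derived metric.

Randomness is hierarchical: one global integer seed spawns one substream
per record, so enlarging the cohort never perturbs existing records.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .cohort import COLUMNS, COVARIATES
from .outcomes import OUTCOME_METRICS

DEFAULT_TREATED_FRACTION = 48.0 / 396.0


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one baseline covariate.

    family: 'truncnorm' (loc/scale/lower), 'bernoulli' (p = loc), or
    'gamma_disc' (gamma with mean loc and sd scale, discretized to 0.1).
    """

    name: str
    family: str
    loc: float
    scale: float = 1.0
    lower: float = -np.inf

    def draw(self, u: float | np.ndarray) -> float | np.ndarray:
        """Inverse-CDF draw from a uniform, vectorized."""
        if self.family == "truncnorm":
            a = ndtr((self.lower - self.loc) / self.scale)
            return self.loc + self.scale * ndtri(a + u * (1.0 - a))
        if self.family == "bernoulli":
            return (u < self.loc).astype(float) if isinstance(u, np.ndarray) else float(u < self.loc)
        if self.family == "gamma_disc":
            # mean = loc, sd = scale -> shape/rate parametrization
            k = (self.loc / self.scale) ** 2
            theta = self.scale**2 / self.loc
            from scipy.stats import gamma

            return np.round(gamma.ppf(u, a=k, scale=theta) / 0.1) * 0.1
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def z_loc(self) -> float:
        return self.loc if self.family != "bernoulli" else 0.0

    @property
    def z_scale(self) -> float:
        return self.scale if self.family != "bernoulli" else 1.0


def _default_covariate_specs() -> tuple[CovariateSpec, ...]:
    # Locations/scales chosen against the real cohort's reported medians and
    # IQRs (IQR/1.35 as the sd of a roughly normal marginal).
    return (
        CovariateSpec("age", "truncnorm", 64.0, 14.0, 18.0),
        CovariateSpec("gender", "bernoulli", 0.46),  # P(male)
        CovariateSpec("height_cm", "truncnorm", 160.0, 6.0, 120.0),
        CovariateSpec("weight_kg", "truncnorm", 61.0, 7.0, 30.0),
        CovariateSpec("wells", "gamma_disc", 4.0, 1.0),
        CovariateSpec("wbc", "truncnorm", 9.9, 2.2, 0.5),
        CovariateSpec("rbc", "truncnorm", 5.05, 0.40, 1.0),
        CovariateSpec("hgb", "truncnorm", 14.9, 1.0, 4.0),
        CovariateSpec("plt", "truncnorm", 157.0, 55.0, 10.0),
        CovariateSpec("hct", "truncnorm", 45.4, 1.2, 20.0),
        CovariateSpec("pt", "truncnorm", 13.6, 1.8, 6.0),
        CovariateSpec("inr", "truncnorm", 1.11, 0.15, 0.3),
        CovariateSpec("aptt", "truncnorm", 33.0, 6.5, 10.0),
        CovariateSpec("tt", "truncnorm", 25.3, 4.5, 8.0),
        CovariateSpec("fib", "truncnorm", 3.5, 0.75, 0.5),
        CovariateSpec("ddimer", "truncnorm", 11.5, 5.0, 0.1),
        CovariateSpec("fdp", "truncnorm", 20.0, 8.0, 0.5),
    )


#: Propensity log-odds slopes on z-scored covariates (gender on raw 0/1),
#: mirroring the significantly imbalanced baselines of the real cohort:
#: treated (CAV) patients have lower APTT, PLT and WBC, higher TT, and are
#: more often male.
DEFAULT_PROPENSITY_SLOPES: dict[str, float] = {
    "aptt": -0.60,
    "plt": -0.35,
    "wbc": -0.35,
    "tt": 0.50,
    "gender": 0.65,
}


@dataclass(frozen=True)
class OutcomeModel:
    """Baseline + additive-treatment-effect + noise models of raw outcomes."""

    # day-1 symptom score: severity increases with Wells score
    day1_base: float = 9.0
    day1_wells_coef: float = 0.8
    day1_sd: float = 2.0
    day1_min: float = 1.0
    # improvement fraction f; IPR = 100 f. z-coefs encode outcome confounding.
    improve_base: float = 0.50
    improve_coefs: dict[str, float] = field(
        default_factory=lambda: {"aptt": -0.05, "wbc": -0.02}
    )
    improve_sd: float = 0.12
    improve_clip: tuple[float, float] = (-0.30, 0.98)
    effect_ipr_pp: float = 6.4  # injected IPR effect, percentage points
    zero_improvement_rate: float = 0.02  # P(discharge == day1), both arms
    # length of stay, days
    los_base: float = 7.0
    los_coefs: dict[str, float] = field(default_factory=lambda: {"ddimer": 0.6})
    los_sd: float = 2.0
    los_min: float = 1.0
    effect_los_days: float = 0.15
    # cost, CNY (log-normal)
    log_cost_base: float = math.log(18000.0)
    cost_los_elasticity: float = 0.7
    cost_day1_coef: float = 0.02
    cost_coefs: dict[str, float] = field(default_factory=lambda: {"aptt": 0.12})
    log_cost_sd: float = 0.30
    effect_cost_multiplier: float = 1.02


def null_outcome_model() -> OutcomeModel:
    """Outcome model with every treatment effect switched off."""
    return OutcomeModel(effect_ipr_pp=0.0, effect_los_days=0.0, effect_cost_multiplier=1.0)


@dataclass(frozen=True)
class CohortParams:
    """Full parameterization of one synthetic cohort."""

    n_total: int = 396
    treated_fraction: float = DEFAULT_TREATED_FRACTION
    covariate_specs: tuple[CovariateSpec, ...] = field(default_factory=_default_covariate_specs)
    propensity_slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPENSITY_SLOPES)
    )
    propensity_intercept: float | None = None  # None -> calibrated to treated_fraction
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not 0.0 < self.treated_fraction < 1.0:
            raise ValueError("treated_fraction must be in (0, 1)")
        om = self.outcome_model
        for s, name in (
            (om.day1_sd, "day1_sd"),
            (om.improve_sd, "improve_sd"),
            (om.los_sd, "los_sd"),
            (om.log_cost_sd, "log_cost_sd"),
        ):
            if s < 0:
                raise ValueError(f"noise scale {name} must be >= 0")
        names = {s.name for s in self.covariate_specs}
        unknown = set(self.propensity_slopes) - names
        if unknown:
            raise ValueError(f"propensity slopes reference unknown covariates: {sorted(unknown)}")

    def spec(self, name: str) -> CovariateSpec:
        for s in self.covariate_specs:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class GroundTruth:
    """Monte-Carlo true average causal effects on the six derived metrics."""

    true_effect: dict[str, float]
    mc_se: dict[str, float]
    n_mc: int
    exclusion_rate: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_effect": self.true_effect,
                    "mc_se": self.mc_se,
                    "n_mc": self.n_mc,
                    "exclusion_rate": self.exclusion_rate,
                },
                indent=2,
                sort_keys=True,
            )
        )


# ---------------------------------------------------------------------------
# internals


def _z(params: CohortParams, name: str, value: np.ndarray | float):
    s = params.spec(name)
    if s.family == "bernoulli":
        return value
    return (value - s.z_loc) / s.z_scale


def _linear_predictor(params: CohortParams, cov: dict[str, np.ndarray], intercept: float) -> np.ndarray:
    eta = np.full_like(np.asarray(cov["age"], dtype=float), intercept)
    for name, slope in params.propensity_slopes.items():
        if slope != 0.0:
            eta = eta + slope * _z(params, name, cov[name])
    return eta


def _draw_covariates_vec(params: CohortParams, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    cov = {}
    for s in params.covariate_specs:
        u = rng.random(n)
        x = np.asarray(s.draw(u), dtype=float)
        bad = ~np.isfinite(x)
        while bad.any():  # pragma: no cover - inverse-CDF draws are finite
            warnings.warn(f"non-finite draw for {s.name}; regenerating with truncation")
            x[bad] = np.asarray(s.draw(rng.random(int(bad.sum()))), dtype=float)
            bad = ~np.isfinite(x)
        cov[s.name] = x
    return cov


def calibrated_intercept(params: CohortParams, n_probe: int = 40_000) -> float:
    """Intercept such that the marginal treated share matches treated_fraction.

    Solved by bisection on fixed internal covariate draws; deterministic and
    independent of the cohort seed.
    """
    if params.propensity_intercept is not None:
        return params.propensity_intercept
    rng = np.random.default_rng(np.random.SeedSequence(987654321))
    cov = _draw_covariates_vec(params, rng, n_probe)
    eta0 = _linear_predictor(params, cov, 0.0)
    lo, hi = -20.0, 20.0
    target = params.treated_fraction
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(eta0 + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class _Potentials:
    """Raw potential outcomes for one draw under control (0) and treatment (1)."""

    day1: np.ndarray
    discharge0: np.ndarray
    discharge1: np.ndarray
    los0: np.ndarray
    los1: np.ndarray
    cost0: np.ndarray
    cost1: np.ndarray


def _potential_outcomes(
    params: CohortParams, cov: dict[str, np.ndarray], rng: np.random.Generator, n: int
) -> _Potentials:
    eps_day1 = rng.standard_normal(n)
    eps_f = rng.standard_normal(n)
    eps_los = rng.standard_normal(n)
    eps_cost = rng.standard_normal(n)
    u_zero = rng.random(n)
    return _potential_outcomes_from_eps(params, cov, eps_day1, eps_f, eps_los, eps_cost, u_zero)


def _potential_outcomes_from_eps(
    params: CohortParams,
    cov: dict[str, np.ndarray],
    eps_day1: np.ndarray,
    eps_f: np.ndarray,
    eps_los: np.ndarray,
    eps_cost: np.ndarray,
    u_zero: np.ndarray,
) -> _Potentials:
    om = params.outcome_model

    day1 = np.maximum(
        om.day1_min,
        om.day1_base + om.day1_wells_coef * (cov["wells"] - params.spec("wells").loc) + om.day1_sd * eps_day1,
    )

    f_base = om.improve_base + om.improve_sd * eps_f
    for name, c in om.improve_coefs.items():
        f_base = f_base + c * _z(params, name, cov[name])
    lo, hi = om.improve_clip
    f0 = np.clip(f_base, lo, hi)
    f1 = np.clip(f_base + om.effect_ipr_pp / 100.0, lo, hi)
    zero = u_zero < om.zero_improvement_rate
    f0 = np.where(zero, 0.0, f0)
    f1 = np.where(zero, 0.0, f1)

    los_base = om.los_base + om.los_sd * eps_los
    for name, c in om.los_coefs.items():
        los_base = los_base + c * _z(params, name, cov[name])
    los0 = np.maximum(om.los_min, los_base)
    los1 = np.maximum(om.los_min, los_base + om.effect_los_days)

    def cost(los: np.ndarray, treated: bool) -> np.ndarray:
        lc = (
            om.log_cost_base
            + om.cost_los_elasticity * np.log(los / om.los_base)
            + om.cost_day1_coef * (day1 - om.day1_base)
            + om.log_cost_sd * eps_cost
        )
        for name, c in om.cost_coefs.items():
            lc = lc + c * _z(params, name, cov[name])
        if treated:
            lc = lc + math.log(om.effect_cost_multiplier)
        return np.exp(lc)

    return _Potentials(
        day1=day1,
        discharge0=day1 * (1.0 - f0),
        discharge1=day1 * (1.0 - f1),
        los0=los0,
        los1=los1,
        cost0=cost(los0, False),
        cost1=cost(los1, True),
    )


# ---------------------------------------------------------------------------
# public operations


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a synthetic cohort; bit-for-bit reproducible for a seed.

    Each record draws from its own substream of the global seed, so the
    first *k* records of an ``n``-record cohort equal the ``k``-record
    cohort at the same seed.  Both potential outcomes are computed and the
    observed outcome selected by the assigned arm (consistency axiom).
    """
    intercept = calibrated_intercept(params)
    n = params.n_total
    n_cov = len(params.covariate_specs)
    children = np.random.SeedSequence(params.seed).spawn(n)
    # each record consumes a fixed block of raw variates from its own
    # substream; the nonlinear transforms below are vectorized across records
    u_cov = np.empty((n, n_cov))
    u_arm = np.empty(n)
    eps = np.empty((n, 4))
    u_zero = np.empty(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        u_cov[i] = rng.random(n_cov)
        u_arm[i] = rng.random()
        eps[i] = rng.standard_normal(4)
        u_zero[i] = rng.random()
    cov = {}
    for j, s in enumerate(params.covariate_specs):
        x = np.asarray(s.draw(u_cov[:, j]), dtype=float)
        if not np.isfinite(x).all():  # pragma: no cover - inverse-CDF draws are finite
            warnings.warn(f"non-finite draw for {s.name}; regenerating with truncation")
            x = np.clip(np.nan_to_num(x, nan=s.z_loc, posinf=s.z_loc, neginf=s.lower), s.lower, None)
        cov[s.name] = x
    p = expit(_linear_predictor(params, cov, intercept))
    treated = u_arm < p
    pot = _potential_outcomes_from_eps(params, cov, eps[:, 0], eps[:, 1], eps[:, 2], eps[:, 3], u_zero)
    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "arm": np.where(treated, "CAV", "SAT"),
            **{
                k: (np.where(v == 1.0, "M", "F") if k == "gender" else v)
                for k, v in cov.items()
            },
            "score_day1": pot.day1,
            "score_discharge": np.where(treated, pot.discharge1, pot.discharge0),
            "los_days": np.where(treated, pot.los1, pot.los0),
            "cost_cny": np.where(treated, pot.cost1, pot.cost0),
        },
        columns=list(COLUMNS),
    )
    arms = df["arm"].unique()
    if len(arms) < 2:
        active = {k: v for k, v in params.propensity_slopes.items() if v != 0.0}
        raise ValueError(
            f"degenerate propensity: all records assigned to arm {arms[0]!r}; "
            f"intercept={intercept:.3f}, slopes={active}"
        )
    return df


def _metrics_from_raw(day1, discharge, los, cost):
    diff = day1 - discharge
    ipr = diff / day1 * 100.0
    dir_ = ipr / los
    with np.errstate(divide="ignore", invalid="ignore"):
        cer = cost / diff
        dic = cost / dir_
    cle = cer / los
    return {"ipr": ipr, "dir": dir_, "cer": cer, "dic": dic, "cle": cle, "los": los}


def ground_truth(params: CohortParams, n_mc: int = 100_000) -> GroundTruth:
    """True average causal effect per metric by Monte-Carlo potential-outcome
    contrast on the covariate population (assignment plays no role).

    Draws with an undefined metric (zero score difference) are excluded and
    the exclusion rate reported.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000")
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 424243)))
    cov = _draw_covariates_vec(params, rng, n_mc)
    pot = _potential_outcomes(params, cov, rng, n_mc)
    m1 = _metrics_from_raw(pot.day1, pot.discharge1, pot.los1, pot.cost1)
    m0 = _metrics_from_raw(pot.day1, pot.discharge0, pot.los0, pot.cost0)
    defined = np.isfinite(m1["cer"]) & np.isfinite(m0["cer"]) & (pot.day1 != pot.discharge1) & (pot.day1 != pot.discharge0)
    excl_rate = 1.0 - defined.mean()
    eff, se = {}, {}
    for k in OUTCOME_METRICS:
        d = m1[k][defined] - m0[k][defined]
        eff[k] = float(d.mean())
        se[k] = float(d.std(ddof=1) / np.sqrt(d.size))
    return GroundTruth(true_effect=eff, mc_se=se, n_mc=int(defined.sum()), exclusion_rate=float(excl_rate))
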