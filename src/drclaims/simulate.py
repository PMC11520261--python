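"""Synthetic claims generator with known ground truth.

Emulates the structure of a two-arm new-user cohort drawn from insurance
claims: demographics and baseline labs with missingness, sparse
zero-inflated phecode comorbidity counts, treatment assignment that depends
on covariates (with an age-varying component), arm-specific
Weibull-baseline proportional-hazards event times over a ~5.4-year horizon,
and independent censoring.  Two output modes are provided:

* :func:`generate_cohort` -- an analysis-ready cohort table (covariates,
  arm, follow-up time in years, event indicator), bypassing claim curation;
* :func:`generate_claim_stream` -- raw dated claim tables (patients,
  pharmacy fills, diagnoses, labs, coverage spans) together with a record
  of the arm / index date / exclusion reason that the curation rules should
  produce for every patient, enabling exact round-trip tests of the cohort
  module.

Because the event-time model is Weibull proportional hazards,
:func:`true_survival` gives the marginal arm-specific event-free
probability either in closed form (no covariate effects) or by Monte Carlo
averaging of the closed-form conditional survival, so every downstream
estimator can be checked against an oracle.

All dates are integer days from the study start (day 0); windows use
1 year = 365 days and 6 months = 183 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from drclaims.exceptions import ConfigError

__all__ = [
    "LAB_NAMES",
    "SIM_DESIGN_COLUMNS",
    "SimConfig",
    "GroundTruth",
    "ClaimStream",
    "generate_cohort",
    "generate_claim_stream",
    "true_survival",
    "ground_truth",
]

#: Baseline laboratory measurements carried by the generator.
LAB_NAMES = ("hba1c", "cholesterol", "hdl", "ldl")

#: Columns of the simulation (truth) design vector, in order.  Continuous
#: covariates enter standardized by the *configured* mean/SD so the truth
#: models are exactly linear in these columns.
SIM_DESIGN_COLUMNS = (
    "intercept",
    "z_age",
    "z_age_sq",
    "male",
    "z_hba1c",
    "z_cholesterol",
    "z_hdl",
    "z_ldl",
    "z_age_x_z_hba1c",
)

_N_DESIGN = len(SIM_DESIGN_COLUMNS)

DAYS_PER_YEAR = 365
HALF_YEAR_DAYS = 183


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.shape[0] != _N_DESIGN:
        raise ConfigError(
            f"{name} must be a length-{_N_DESIGN} vector over the simulation "
            f"design columns {SIM_DESIGN_COLUMNS}, got shape {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise ConfigError(f"{name} contains non-finite entries")
    return v


@dataclass
class SimConfig:
    """Parameters of the synthetic study population.

    Defaults emulate the insulin arm of a large type-2-diabetes claims
    cohort: age 66.24 (SD 9.86) years, 48% male, HbA1c 8.52% (SD 1.1),
    cholesterol 170.87 (22.35), HDL 45.51 (6.35), LDL 90.04 (17.51) mg/dL,
    ~75% of patients on insulin, and 5-year heart-failure rates of roughly
    0.29 (insulin) vs 0.18 (comparator) under confounded assignment.
    """

    n_patients: int = 10_000
    age_mean: float = 66.24
    age_sd: float = 9.86
    frac_male: float = 0.4806
    n_phecode_features: int = 50
    phecode_prevalence_range: tuple[float, float] = (0.01, 0.40)
    lab_means: dict = field(
        default_factory=lambda: {
            "hba1c": 8.52,
            "cholesterol": 170.87,
            "hdl": 45.51,
            "ldl": 90.04,
        }
    )
    lab_sds: dict = field(
        default_factory=lambda: {
            "hba1c": 1.10,
            "cholesterol": 22.35,
            "hdl": 6.35,
            "ldl": 17.51,
        }
    )
    lab_missing_rates: dict = field(
        default_factory=lambda: {
            "hba1c": 0.0,
            "cholesterol": 0.10,
            "hdl": 0.10,
            "ldl": 0.10,
        }
    )
    #: Treatment (logit) model coefficients over SIM_DESIGN_COLUMNS.
    ps_coefficients: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.10, 0.50, 0.0, 0.10, 0.40, 0.0, 0.0, 0.0, 0.20]
        )
    )
    hazard_shape: float = 1.2
    #: Weibull scale (years) per arm, indexed (comparator, treated).
    hazard_scale_by_arm: tuple[float, float] = (23.0, 14.0)
    #: Log-hazard coefficients over SIM_DESIGN_COLUMNS, per arm
    #: (comparator, treated).
    log_hazard_coefficients_by_arm: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (
            np.array([0.0, 0.40, 0.0, 0.10, 0.30, 0.0, 0.0, 0.0, 0.15]),
            np.array([0.0, 0.40, 0.0, 0.10, 0.30, 0.0, 0.0, 0.0, 0.15]),
        )
    )
    censor_rate: float = 0.25  # events per year; 0 disables random censoring
    #: Optional coefficient on z_age in the log censoring rate, for
    #: covariate-dependent censoring stress tests (0 = independent).
    censor_age_coef: float = 0.0
    admin_end: float = 5.4  # years of administrative follow-up
    horizon_t: float = 5.0  # years; estimand horizon
    seed: int = 0

    # --- claim-stream scripting fractions (raw-claims mode only) ---
    frac_single_fill: float = 0.04
    frac_early_refill: float = 0.04
    frac_two_class: float = 0.08
    frac_pre_hf: float = 0.05
    frac_no_hba1c: float = 0.03
    frac_short_coverage: float = 0.03
    frac_t1dm: float = 0.02
    comparator_class: str = "GLP1"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if int(self.n_patients) < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        for name, value in [
            ("frac_male", self.frac_male),
            ("frac_single_fill", self.frac_single_fill),
            ("frac_early_refill", self.frac_early_refill),
            ("frac_two_class", self.frac_two_class),
            ("frac_pre_hf", self.frac_pre_hf),
            ("frac_no_hba1c", self.frac_no_hba1c),
            ("frac_short_coverage", self.frac_short_coverage),
            ("frac_t1dm", self.frac_t1dm),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.phecode_prevalence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("phecode_prevalence_range must satisfy 0 <= lo <= hi <= 1")
        for lab in LAB_NAMES:
            if lab not in self.lab_means or lab not in self.lab_sds:
                raise ConfigError(f"lab_means/lab_sds must define lab '{lab}'")
            rate = self.lab_missing_rates.get(lab, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"lab_missing_rates['{lab}'] must be in [0, 1]")
        self.ps_coefficients = _as_vector(self.ps_coefficients, "ps_coefficients")
        b0, b1 = self.log_hazard_coefficients_by_arm
        self.log_hazard_coefficients_by_arm = (
            _as_vector(b0, "log_hazard_coefficients_by_arm[0]"),
            _as_vector(b1, "log_hazard_coefficients_by_arm[1]"),
        )
        if self.hazard_shape <= 0:
            raise ConfigError("hazard_shape must be > 0")
        if any(s <= 0 for s in self.hazard_scale_by_arm):
            raise ConfigError("hazard_scale_by_arm entries must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if self.admin_end < self.horizon_t:
            raise ConfigError("admin_end must be >= horizon_t")
        if self.horizon_t < 0:
            raise ConfigError("horizon_t must be >= 0")


@dataclass
class GroundTruth:
    """Oracle effect values for a :class:`SimConfig`.

    ``S1_t`` / ``S0_t`` are the true marginal event-free probabilities at
    the horizon for everyone-treated / everyone-comparator;
    ``ate_t = S1_t - S0_t`` on the survival scale.  The analysis pipeline
    reports the heart-failure *rate* difference
    ``rate_1 - rate_0 = (1 - S1_t) - (1 - S0_t) = -ate_t`` (positive =
    treated arm has the higher event rate), exposed here as
    ``hf_rate_diff``.  ``cate_fn`` maps a simulation design row to the true
    conditional survival difference ``S1(t|x) - S0(t|x)``.
    """

    t: float
    S1_t: float
    S0_t: float
    mc_se: float
    cate_fn: Callable[[np.ndarray], np.ndarray]

    @property
    def ate_t(self) -> float:
        return self.S1_t - self.S0_t

    @property
    def hf_rate_diff(self) -> float:
        return -self.ate_t


@dataclass
class ClaimStream:
    """Raw claim tables plus the generator's curation expectations."""

    patients: pd.DataFrame
    rx_claims: pd.DataFrame
    dx_claims: pd.DataFrame
    labs: pd.DataFrame
    coverage: pd.DataFrame
    code_map: pd.DataFrame
    expected: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# covariate and design helpers
# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, config: SimConfig, n: int) -> dict:
    cov = {
        "age": rng.normal(config.age_mean, config.age_sd, n),
        "male": (rng.random(n) < config.frac_male).astype(float),
    }
    for lab in LAB_NAMES:
        cov[lab] = rng.normal(config.lab_means[lab], config.lab_sds[lab], n)
    return cov


def sim_design(cov: dict, config: SimConfig) -> np.ndarray:
    """Build the truth design matrix (columns ``SIM_DESIGN_COLUMNS``)."""
    z_age = (np.asarray(cov["age"]) - config.age_mean) / config.age_sd
    z = {lab: (np.asarray(cov[lab]) - config.lab_means[lab]) / config.lab_sds[lab]
         for lab in LAB_NAMES}
    n = z_age.shape[0]
    return np.column_stack(
        [
            np.ones(n),
            z_age,
            z_age**2 - 1.0,  # centered so the column has mean ~0
            np.asarray(cov["male"], dtype=float),
            z["hba1c"],
            z["cholesterol"],
            z["hdl"],
            z["ldl"],
            z_age * z["hba1c"],
        ]
    )


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _conditional_survival(
    design: np.ndarray, config: SimConfig, arm: int, t: float
) -> np.ndarray:
    """Weibull-PH conditional event-free probability S_arm(t | x)."""
    beta = config.log_hazard_coefficients_by_arm[arm]
    scale = config.hazard_scale_by_arm[arm]
    lp = design @ beta
    return np.exp(-((t / scale) ** config.hazard_shape) * np.exp(lp))


def _draw_event_times(
    rng: np.random.Generator, design: np.ndarray, config: SimConfig, arm: np.ndarray
) -> np.ndarray:
    """Inverse-CDF draw from the arm-specific Weibull PH model (years)."""
    n = design.shape[0]
    u = rng.random(n)
    k = config.hazard_shape
    times = np.empty(n)
    for a in (0, 1):
        mask = arm == a
        if not np.any(mask):
            continue
        lp = design[mask] @ config.log_hazard_coefficients_by_arm[a]
        scale = config.hazard_scale_by_arm[a]
        times[mask] = scale * (-np.log(u[mask]) / np.exp(lp)) ** (1.0 / k)
    return times


def _draw_censoring(
    rng: np.random.Generator, design: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Censoring times in years, min(exponential, administrative end)."""
    n = design.shape[0]
    if config.censor_rate <= 0:
        return np.full(n, config.admin_end)
    rate = config.censor_rate * np.exp(config.censor_age_coef * design[:, 1])
    c = rng.exponential(1.0 / rate, n)
    return np.minimum(c, config.admin_end)


def _draw_phecode_counts(
    rng: np.random.Generator, config: SimConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-inflated Poisson counts: active ~ Bernoulli(prevalence_j),
    count | active = 1 + Poisson(1.5); prevalence_j ~ U(configured range)."""
    lo, hi = config.phecode_prevalence_range
    prevalence = rng.uniform(lo, hi, config.n_phecode_features)
    active = rng.random((n, config.n_phecode_features)) < prevalence
    counts = np.where(active, 1 + rng.poisson(1.5, (n, config.n_phecode_features)), 0)
    return counts, prevalence


def _apply_lab_missingness(
    rng: np.random.Generator, cov: dict, config: SimConfig, n: int
) -> dict:
    """MCAR missingness; returns per-lab observed arrays with NaN."""
    observed = {}
    for lab in LAB_NAMES:
        rate = config.lab_missing_rates.get(lab, 0.0)
        vals = cov[lab].copy()
        if rate > 0:
            vals[rng.random(n) < rate] = np.nan
        observed[lab] = vals
    return observed


def _phecode_names(config: SimConfig) -> list[str]:
    return [f"phe_{j:03d}" for j in range(config.n_phecode_features)]


# ---------------------------------------------------------------------------
# direct-cohort mode
# ---------------------------------------------------------------------------


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw an analysis-ready cohort table, bypassing claim curation.

    Returns one row per patient with columns: ``patient_id``, demographics
    (``age``, ``male``, ``medicaid``, ``rural``, ``socio_index``,
    ``disease_duration`` in months), baseline labs (NaN where missing),
    auxiliary medication counts, phecode count columns, ``arm`` (1 =
    treated/insulin), ``time`` (years of follow-up) and ``event``.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_patients)

    cov = _draw_covariates(rng, config, n)
    design = sim_design(cov, config)
    arm = (rng.random(n) < _expit(design @ config.ps_coefficients)).astype(int)

    event_time = _draw_event_times(rng, design, config, arm)
    censor_time = _draw_censoring(rng, design, config)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    counts, _ = _draw_phecode_counts(rng, config, n)
    labs_observed = _apply_lab_missingness(rng, cov, config, n)

    out = pd.DataFrame({"patient_id": np.arange(1, n + 1)})
    out["age"] = cov["age"]
    out["male"] = cov["male"].astype(int)
    out["medicaid"] = (rng.random(n) < 0.013).astype(int)
    out["rural"] = (rng.random(n) < 0.27).astype(int)
    out["socio_index"] = rng.normal(52.0, 3.0, n)
    out["disease_duration"] = np.abs(rng.normal(3.0, 10.0, n))
    for lab in LAB_NAMES:
        out[lab] = labs_observed[lab]
    for med, mean in [("metformin", 0.6), ("statins", 0.73),
                      ("sulfonylureas", 0.32), ("thiazolidinediones", 0.07)]:
        out[med] = rng.poisson(mean, n)
    for j, name in enumerate(_phecode_names(config)):
        out[name] = counts[:, j]
    out["arm"] = arm
    out["time"] = time
    out["event"] = event
    return out


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def true_survival(
    config: SimConfig,
    arm: int,
    t: float,
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """True marginal event-free probability at ``t`` under ``arm``.

    Uses the Weibull closed form when the arm's covariate effects are all
    zero, otherwise Monte Carlo averages the closed-form conditional
    survival over ``n_draws`` covariate draws.  Returns ``(value, mc_se)``.
    """
    if t < 0:
        raise ConfigError("t must be >= 0")
    if arm not in (0, 1):
        raise ConfigError("arm must be 0 or 1")
    if t == 0:
        return 1.0, 0.0
    beta = config.log_hazard_coefficients_by_arm[arm]
    scale = config.hazard_scale_by_arm[arm]
    base = (t / scale) ** config.hazard_shape
    if np.all(beta[1:] == 0.0):
        return float(np.exp(-base * math.exp(beta[0]))), 0.0
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = _draw_covariates(rng, config, n_draws)
    s = _conditional_survival(sim_design(cov, config), config, arm, t)
    return float(s.mean()), float(s.std(ddof=1) / math.sqrt(n_draws))


def ground_truth(
    config: SimConfig,
    t: float | None = None,
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> GroundTruth:
    """Oracle :class:`GroundTruth` at horizon ``t`` (default config horizon)."""
    horizon = config.horizon_t if t is None else t
    s1, se1 = true_survival(config, 1, horizon, n_draws=n_draws, seed=seed)
    s0, se0 = true_survival(
        config, 0, horizon, n_draws=n_draws,
        seed=(seed + 1) if seed is not None else config.seed + 1,
    )

    def cate_fn(design_rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(design_rows, dtype=float))
        return (
            _conditional_survival(rows, config, 1, horizon)
            - _conditional_survival(rows, config, 0, horizon)
        )

    return GroundTruth(
        t=horizon, S1_t=s1, S0_t=s0,
        mc_se=math.hypot(se1, se0), cate_fn=cate_fn,
    )


# ---------------------------------------------------------------------------
# raw-claims mode
# ---------------------------------------------------------------------------

_T2DM_PHECODE = "250.2"
_T1DM_PHECODE = "250.1"
_HF_PHECODES = ("428.1", "428.2", "428.3", "428.4")

_AUX_MED_MEANS = {
    "metformin": 0.6,
    "statins": 0.73,
    "sulfonylureas": 0.32,
    "thiazolidinediones": 0.07,
}


def default_code_map(config: SimConfig) -> pd.DataFrame:
    """Two synthetic diagnosis codes per phecode, plus diabetes/HF phecodes."""
    phecodes = list(_phecode_names(config)) + [
        _T2DM_PHECODE, _T1DM_PHECODE, *_HF_PHECODES,
    ]
    rows = [
        {"code": f"ICD_{phe}_{k}", "phecode": phe}
        for phe in phecodes
        for k in (0, 1)
    ]
    return pd.DataFrame(rows)


def _dx_rows(rows, rng, pid, phecode, dates):
    for d in np.atleast_1d(dates):
        variant = int(rng.integers(0, 2))
        rows.append((pid, int(d), f"ICD_{phecode}_{variant}"))


def generate_claim_stream(config: SimConfig) -> ClaimStream:
    """Emit dated claim tables exercising the curation rules.

    Most patients follow a "clean" script (sustained fills of one class,
    HbA1c on record, >= 1 year of qualifying coverage, no prior heart
    failure); configured fractions are scripted to violate exactly one rule
    (single fill, early refill outside the 6-12-month window, missing
    HbA1c, short coverage, likely type-1 diabetes, pre-index HF) or to have
    two sustained classes (earliest wins; occasional same-day ties broken
    by class priority).  The ``expected`` table records, per patient, the
    arm, index date and first-failing exclusion reason that the curation
    rules should produce, plus the latent arm/event-time truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_patients)

    cov = _draw_covariates(rng, config, n)
    design = sim_design(cov, config)
    arm = (rng.random(n) < _expit(design @ config.ps_coefficients)).astype(int)
    event_time = _draw_event_times(rng, design, config, arm)
    censor_time = _draw_censoring(rng, design, config)
    counts, _ = _draw_phecode_counts(rng, config, n)
    labs_observed = _apply_lab_missingness(rng, cov, config, n)

    categories = np.array(
        ["single_fill", "early_refill", "two_class", "pre_hf",
         "no_hba1c", "short_coverage", "t1dm", "clean"]
    )
    probs = np.array(
        [config.frac_single_fill, config.frac_early_refill, config.frac_two_class,
         config.frac_pre_hf, config.frac_no_hba1c, config.frac_short_coverage,
         config.frac_t1dm, 0.0]
    )
    if probs.sum() > 1.0:
        raise ConfigError("scripted claim-stream fractions sum to more than 1")
    probs[-1] = 1.0 - probs.sum()
    script = rng.choice(categories, size=n, p=probs)

    insulin = "insulin"
    comparator = config.comparator_class
    class_priority = (insulin, comparator)

    patients_rows, rx_rows, dx_rows_list, lab_rows, cov_rows, exp_rows = (
        [], [], [], [], [], []
    )
    phe_names = _phecode_names(config)

    for i in range(n):
        pid = i + 1
        cat = script[i]
        own_class = insulin if arm[i] == 1 else comparator
        d0 = int(rng.integers(365, 541))  # full 1-year lookback available

        # --- pharmacy fills of the study classes ---
        expected_class: str | None = own_class
        expected_index: int | None = d0
        if cat == "single_fill":
            rx_rows.append((pid, d0, own_class))
            expected_class, expected_index = None, None
        elif cat == "early_refill":
            gap = int(rng.integers(30, 151))
            rx_rows.append((pid, d0, own_class))
            rx_rows.append((pid, d0 + gap, own_class))
            expected_class, expected_index = None, None
        elif cat == "two_class":
            other = comparator if own_class == insulin else insulin
            tie = rng.random() < 0.2
            d_other = d0 if tie else d0 + int(rng.integers(10, 121))
            for cls, start in ((own_class, d0), (other, d_other)):
                gap = int(rng.integers(183, 366))
                rx_rows.append((pid, start, cls))
                rx_rows.append((pid, start + gap, cls))
            if tie:
                expected_class = next(
                    c for c in class_priority if c in (own_class, other)
                )
            expected_index = d0
        else:
            gap = int(rng.integers(183, 366))
            rx_rows.append((pid, d0, own_class))
            rx_rows.append((pid, d0 + gap, own_class))

        # --- auxiliary medication fills in the lookback year ---
        for med, mean in _AUX_MED_MEANS.items():
            for _ in range(int(rng.poisson(mean))):
                rx_rows.append((pid, d0 - int(rng.integers(1, 366)), med))

        # --- diabetes history ---
        duration_days = int(abs(rng.normal(3.0, 10.0)) * 30.44)
        t2dm_date = max(0, d0 - duration_days)
        if cat == "t1dm":
            _dx_rows(dx_rows_list, rng, pid, _T1DM_PHECODE,
                     rng.integers(0, d0, 3))
            _dx_rows(dx_rows_list, rng, pid, _T2DM_PHECODE, [t2dm_date])
        else:
            _dx_rows(dx_rows_list, rng, pid, _T2DM_PHECODE,
                     [t2dm_date, t2dm_date + int(rng.integers(1, 200))])

        # --- baseline phecode claims in [index-365, index) ---
        for j, name in enumerate(phe_names):
            c = int(counts[i, j])
            if c > 0:
                _dx_rows(dx_rows_list, rng, pid, name,
                         d0 - 1 - rng.integers(0, 365, c))

        # --- pre-index HF ---
        if cat == "pre_hf":
            hf_phe = _HF_PHECODES[int(rng.integers(0, 4))]
            _dx_rows(dx_rows_list, rng, pid, hf_phe,
                     [d0 - int(rng.integers(10, 300))])

        # --- outcome: post-index HF claim if the event is observed ---
        followup_days = max(1, int(round(censor_time[i] * DAYS_PER_YEAR)))
        event_days = max(1, int(round(event_time[i] * DAYS_PER_YEAR)))
        observed_event = event_days <= followup_days
        if observed_event:
            hf_phe = _HF_PHECODES[int(rng.integers(0, 4))]
            _dx_rows(dx_rows_list, rng, pid, hf_phe, [d0 + event_days])
        last_followup = d0 + followup_days

        # --- labs ---
        if cat != "no_hba1c" and not np.isnan(labs_observed["hba1c"][i]):
            n_a1c = int(rng.integers(1, 4))
            days = np.sort(rng.integers(1, 366, n_a1c))[::-1]  # most recent last
            for k, back in enumerate(days):
                val = (cov["hba1c"][i] if k == n_a1c - 1
                       else cov["hba1c"][i] + rng.normal(0, 0.3))
                lab_rows.append((pid, d0 - int(back), "hba1c", float(val)))
        for lab in ("cholesterol", "hdl", "ldl"):
            if not np.isnan(labs_observed[lab][i]):
                lab_rows.append(
                    (pid, d0 - int(rng.integers(1, 366)), lab,
                     float(cov[lab][i]))
                )

        # --- coverage spans ---
        plan = "MAPD" if rng.random() < 0.6 else "FI"
        if cat == "short_coverage":
            cov_rows.append((pid, d0 - 100, d0 + 100, plan))
        else:
            cov_rows.append((pid, 0, last_followup, plan))

        birth_year = int(round(2016 + d0 / DAYS_PER_YEAR - cov["age"][i]))
        patients_rows.append(
            (pid, birth_year, "M" if cov["male"][i] == 1 else "F",
             int(rng.random() < 0.013), int(rng.random() < 0.27),
             float(rng.normal(52.0, 3.0)))
        )

        # --- expected curation outcome (first-failing-reason order) ---
        if expected_class is None:
            reason = "no_arm"
        elif cat == "no_hba1c" or np.isnan(labs_observed["hba1c"][i]):
            reason = "no_hba1c"
        elif cat == "short_coverage":
            reason = "coverage"
        elif cat == "t1dm":
            reason = "t1dm"
        elif cat == "pre_hf":
            reason = "prior_hf"
        else:
            reason = None
        exp_rows.append(
            {
                "patient_id": pid,
                "script": cat,
                "expected_arm_class": expected_class,
                "expected_index_date": expected_index,
                "expected_reason": reason,
                "expected_eligible": reason is None,
                "true_arm": int(arm[i]),
                "true_event_time_years": float(event_time[i]),
                "true_followup_years": float(censor_time[i]),
                "expected_event": bool(observed_event) if reason is None else None,
                "expected_followup_days": (
                    (min(event_days, followup_days) if reason is None else None)
                ),
            }
        )

    patients = pd.DataFrame(
        patients_rows,
        columns=["patient_id", "birth_year", "sex", "medicaid", "rural",
                 "socio_index"],
    )
    rx_claims = pd.DataFrame(
        rx_rows, columns=["patient_id", "fill_date", "drug_class"]
    )
    dx_claims = pd.DataFrame(dx_rows_list, columns=["patient_id", "date", "code"])
    labs = pd.DataFrame(
        lab_rows, columns=["patient_id", "date", "lab_name", "value"]
    )
    coverage = pd.DataFrame(
        cov_rows, columns=["patient_id", "start_date", "end_date", "plan_type"]
    )
    expected = pd.DataFrame(exp_rows)
    return ClaimStream(
        patients=patients,
        rx_claims=rx_claims,
        dx_claims=dx_claims,
        labs=labs,
        coverage=coverage,
        code_map=default_code_map(config),
        expected=expected,
        config=replace(config),
    )
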