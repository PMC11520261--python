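"""One-command orchestration of the full comparison analysis.

``run_comparison`` drives: input (synthetic claim stream or user-supplied
claim tables) -> cohort construction -> feature/design-matrix building ->
adaptive-LASSO nuisance fits -> IPW balance + weighted Kaplan-Meier +
doubly robust ATE -> score-based CATE; every stage's artifact is written
to the output directory as a delimited table or JSON summary, with a
manifest recording the config hash, seeds and stage row counts so a rerun
with the identical config reproduces the bundle byte for byte.

``run_simulation_study`` is the replication harness: seeded replicate
loops over named scenarios (correct / misspecified nuisance models)
summarizing bias, empirical vs estimated SE, and CI coverage against the
generator's closed-form/Monte-Carlo truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from drclaims import __version__
from drclaims.cate import compute_score, score_specific_ate, subgroup_ate
from drclaims.cohort import HF_PHECODES, build_cohort
from drclaims.estimation import (
    aipw_ate,
    balance_diagnostics,
    ipw_weights,
    weighted_km,
)
from drclaims.exceptions import ConfigError
from drclaims.features import (
    build_design_matrix,
    comorbidity_pca,
    filter_rare_features,
    impute_labs_mean,
)
from drclaims.nuisance import (
    fit_adaptive_lasso_cox,
    fit_adaptive_lasso_logistic,
    fit_cox_mle,
    fit_logistic_mle,
    intercept_only_cox,
    predict_survival,
)
from drclaims.simulate import (
    LAB_NAMES,
    ClaimStream,
    SimConfig,
    generate_claim_stream,
    generate_cohort,
    ground_truth,
    sim_design,
)

logger = logging.getLogger("drclaims")

__all__ = [
    "RunConfig",
    "run_comparison",
    "run_simulation_study",
    "load_claim_tables",
    "dr_scenario_config",
    "null_scenario_config",
    "hte_scenario_config",
    "constant_effect_config",
]

_SPECIAL_PHECODES = {"250.1", "250.2", *HF_PHECODES}

AUX_MEDS = ("metformin", "statins", "sulfonylureas", "thiazolidinediones")
DEMOGRAPHICS = ("male", "medicaid", "rural", "socio_index", "disease_duration")


@dataclass
class RunConfig:
    """Declarative configuration of one two-arm comparison run."""

    mode: str = "synthetic"  # "synthetic" | "claims-tables"
    input_dir: str | None = None  # claims-tables mode: directory of CSVs
    output_dir: str = "drclaims_output"
    treated_class: str = "insulin"
    comparator_class: str = "GLP1"
    horizon_t: float = 5.0
    trim_bounds: tuple[float, float] = (0.01, 0.99)
    cv_folds: int = 10
    seed: int = 0
    rare_threshold: float = 0.05
    n_pcs: int = 3
    include_phecode_counts: bool = False  # raw counts alongside the PCs
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "claims-tables"):
            raise ConfigError("mode must be 'synthetic' or 'claims-tables'")
        if self.mode == "claims-tables" and not self.input_dir:
            raise ConfigError("claims-tables mode requires input_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trim_bounds" in raw:
            raw["trim_bounds"] = tuple(raw["trim_bounds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trim_bounds"] = list(self.trim_bounds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_claim_tables(input_dir) -> ClaimStream:
    """Read the five flat claim tables (+ code_map) from CSV files."""
    d = Path(input_dir)
    def read(name):
        path = d / f"{name}.csv"
        if not path.exists():
            raise ConfigError(f"missing input table {path}")
        return pd.read_csv(path)

    cfg = SimConfig(n_patients=1)  # placeholder; unused in table mode
    return ClaimStream(
        patients=read("patients"),
        rx_claims=read("rx_claims"),
        dx_claims=read("dx_claims"),
        labs=read("labs"),
        coverage=read("coverage"),
        code_map=read("code_map"),
        expected=pd.DataFrame(),
        config=cfg,
    )


def _sim_config(config: RunConfig) -> SimConfig:
    overrides = dict(config.sim)
    overrides.setdefault("seed", config.seed)
    overrides.setdefault("comparator_class", config.comparator_class)
    overrides.setdefault("horizon_t", config.horizon_t)
    return SimConfig(**overrides)


def _phecode_columns(cohort: pd.DataFrame, code_map: pd.DataFrame) -> list[str]:
    phecodes = set(code_map["phecode"].astype(str)) - _SPECIAL_PHECODES
    return sorted(p for p in phecodes if p in cohort.columns)


def build_features(
    cohort: pd.DataFrame,
    code_map: pd.DataFrame,
    *,
    rare_threshold: float = 0.05,
    n_pcs: int = 3,
    include_phecode_counts: bool = False,
):
    """Cohort covariates -> (design matrix, covariate frame, reports).

    Applies the rare-feature filter to phecode counts, mean imputation to
    labs, comorbidity PCA, and the age-basis interaction expansion.
    Returns ``(dm, covariates, info)`` where ``covariates`` holds the
    un-expanded analysis covariates (for balance diagnostics) and ``info``
    carries the dropped features and imputation report.
    """
    phe_cols = _phecode_columns(cohort, code_map)
    counts, dropped = (
        filter_rare_features(cohort[phe_cols], rare_threshold)
        if phe_cols
        else (pd.DataFrame(index=cohort.index), [])
    )
    labs_complete, impute_report = impute_labs_mean(cohort[list(LAB_NAMES)])

    pieces = [cohort[list(DEMOGRAPHICS)], labs_complete, cohort[list(AUX_MEDS)]]
    if counts.shape[1] >= n_pcs:
        pcs, loadings = comorbidity_pca(counts, n_pcs)
        pieces.append(pcs)
    else:
        loadings = pd.DataFrame()
    if include_phecode_counts and counts.shape[1]:
        pieces.append(counts)
    covariates = pd.concat(pieces, axis=1)

    dm = build_design_matrix(covariates, cohort["age"].to_numpy())
    info = {
        "dropped_features": dropped,
        "imputation": impute_report,
        "pca_loadings": loadings,
    }
    return dm, covariates, info


def fit_nuisances(
    dm, cohort: pd.DataFrame, *, cv_folds: int = 10, seed: int = 0
):
    """Adaptive-LASSO PS fit plus the two arm-specific Cox fits.

    The age-basis columns are never penalized (age is a forced
    confounder); cross-validation folds are keyed to patient ids.
    """
    X = dm.X
    arm = cohort["arm"].to_numpy()
    pid = cohort["patient_id"].to_numpy()
    basis_cols = dm.basis_columns
    psfit = fit_adaptive_lasso_logistic(
        X, arm, penalty_free=basis_cols, n_folds=cv_folds, seed=seed,
        patient_id=pid,
    )
    coxfits = {}
    for a in (1, 0):
        mask = arm == a
        coxfits[a] = fit_adaptive_lasso_cox(
            X[mask],
            cohort.loc[mask, "time"].to_numpy(),
            cohort.loc[mask, "event"].to_numpy(),
            arm_label=a,
            n_folds=cv_folds,
            seed=seed + 1 + a,
            patient_id=pid[mask],
        )
    return psfit, coxfits[1], coxfits[0]


def run_comparison(config: RunConfig) -> dict:
    """Execute the full analysis; write artifacts; return the result bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }

    # ---- stage: input ----
    if config.mode == "synthetic":
        stream = generate_claim_stream(_sim_config(config))
    else:
        stream = load_claim_tables(config.input_dir)
    present = set(stream.rx_claims["drug_class"].unique())
    for label in (config.treated_class, config.comparator_class):
        if label not in present:
            raise ConfigError(
                f"drug class '{label}' has no fills in the pharmacy claims"
            )
    manifest["stages"]["input"] = {"n_patients": int(len(stream.patients))}

    # ---- stage: cohort ----
    logger.info("building cohort")
    cohort, attrition = build_cohort(
        stream,
        treated_class=config.treated_class,
        comparator_class=config.comparator_class,
    )
    attrition.to_csv(out / "attrition.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest["stages"]["cohort"] = {
        "n_retained": int(len(cohort)),
        "n_treated": int(cohort["arm"].sum()),
    }

    # ---- stage: features ----
    logger.info("building design matrix")
    dm, covariates, info = build_features(
        cohort,
        stream.code_map,
        rare_threshold=config.rare_threshold,
        n_pcs=config.n_pcs,
        include_phecode_counts=config.include_phecode_counts,
    )
    info["imputation"].to_csv(out / "imputation_report.csv", index=False)
    manifest["stages"]["features"] = {
        "n_design_columns": int(dm.X.shape[1]),
        "n_dropped_rare": len(info["dropped_features"]),
    }

    # ---- stage: nuisance fits ----
    logger.info("fitting nuisance models")
    psfit, cox1, cox0 = fit_nuisances(
        dm, cohort, cv_folds=config.cv_folds, seed=config.seed
    )
    with open(out / "fits.json", "w") as fh:
        json.dump(
            {"ps": psfit.to_dict(), "cox_treated": cox1.to_dict(),
             "cox_comparator": cox0.to_dict()},
            fh, indent=1, sort_keys=True,
        )
    manifest["stages"]["nuisance"] = {
        "ps_support": len(psfit.support),
        "cox_treated_support": len(cox1.support),
        "cox_comparator_support": len(cox0.support),
    }

    # ---- stage: estimation ----
    logger.info("estimating the treatment effect")
    arm = cohort["arm"].to_numpy()
    time = cohort["time"].to_numpy()
    event = cohort["event"].to_numpy()
    pi = psfit.propensities
    w, keep = ipw_weights(pi, arm, config.trim_bounds)

    balance = balance_diagnostics(
        pd.concat([cohort[["age"]], covariates], axis=1), arm, w
    )
    balance.to_csv(out / "balance.csv", index=False)

    km_before = weighted_km(time, event, None, arm)
    km_before["weighted"] = False
    km_after = weighted_km(time[keep], event[keep], w[keep], arm[keep])
    km_after["weighted"] = True
    pd.concat([km_before, km_after], ignore_index=True).to_csv(
        out / "km_curves.csv", index=False
    )

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        s1 = predict_survival(cox1, dm.X, config.horizon_t)
        s0 = predict_survival(cox0, dm.X, config.horizon_t)
    ate = aipw_ate(
        time, event, arm, pi, s1, s0, config.horizon_t,
        trim_bounds=config.trim_bounds,
    )
    with open(out / "ate.json", "w") as fh:
        json.dump(ate.to_dict(), fh, indent=1, sort_keys=True)
    manifest["stages"]["estimation"] = {
        "n_used": ate.n_used, "n_trimmed": ate.n_trimmed,
    }

    # ---- stage: CATE ----
    logger.info("estimating score-specific effects")
    score = compute_score(cox1, cox0, dm.X, config.horizon_t)
    curve = None
    if np.std(score[ate.keep_mask], ddof=1) >= 1e-8:
        curve = score_specific_ate(score[ate.keep_mask], ate)
        curve.to_frame().to_csv(out / "cate_curve.csv", index=False)
        curve.histogram_frame().to_csv(out / "cate_histogram.csv", index=False)
        manifest["stages"]["cate"] = {
            "n_grid": int(len(curve.grid)), "bandwidth": float(curve.bandwidth),
        }
    else:
        # both outcome fits coincide: the score carries no heterogeneity
        pd.DataFrame(
            {"score": [float(np.mean(score))], "cate": [ate.ate],
             "ci_lower": [ate.ci[0]], "ci_upper": [ate.ci[1]], "se": [ate.se]}
        ).to_csv(out / "cate_curve.csv", index=False)
        pd.DataFrame(columns=["bin_left", "bin_right", "count"]).to_csv(
            out / "cate_histogram.csv", index=False
        )
        manifest["stages"]["cate"] = {"degenerate_score": True}

    # subgroup split at S = 0 per the design; fall back to the median when
    # every score lies on one side (e.g. one drug modeled worse for all)
    threshold = 0.0
    if (score > 0).all() or (score <= 0).all():
        threshold = float(np.median(score))
        manifest["stages"]["cate"]["subgroup_threshold"] = threshold
    subgroups = None
    if np.std(score) >= 1e-8:
        subgroups = subgroup_ate(
            score, time, event, arm, pi, s1, s0, config.horizon_t,
            threshold=threshold, trim_bounds=config.trim_bounds,
        )
        with open(out / "subgroups.json", "w") as fh:
            json.dump(
                {k: v.to_dict() for k, v in subgroups.items()},
                fh, indent=1, sort_keys=True,
            )
    else:
        with open(out / "subgroups.json", "w") as fh:
            json.dump({"degenerate_score": True}, fh)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "cohort": cohort,
        "attrition": attrition,
        "design": dm,
        "covariates": covariates,
        "psfit": psfit,
        "cox_treated": cox1,
        "cox_comparator": cox0,
        "balance": balance,
        "ate": ate,
        "score": score,
        "cate_curve": curve,
        "subgroups": subgroups,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# simulation study harness
# ---------------------------------------------------------------------------


def dr_scenario_config(**overrides) -> SimConfig:
    """Generator settings for the double-robustness / calibration studies.

    Labs are fully observed and the sparse phecode block is switched off so
    the truth models are exactly the generator's design columns; treatment
    assignment and hazards share strong age / HbA1c effects, so ignoring
    them (the "broken" models) confounds the naive comparison.
    """
    base = dict(
        n_patients=5000,
        n_phecode_features=0,
        lab_missing_rates={lab: 0.0 for lab in LAB_NAMES},
        censor_rate=0.25,
    )
    base.update(overrides)
    return SimConfig(**base)


def null_scenario_config(**overrides) -> SimConfig:
    """Null-effect scenario: identical hazards in both arms (true ATE = 0),
    with the same confounded treatment assignment as the default."""
    base = dict(hazard_scale_by_arm=(14.0, 14.0))
    base.update(overrides)
    return dr_scenario_config(**base)


def hte_scenario_config(**overrides) -> SimConfig:
    """Heterogeneous-effect scenario for score-based subgroup analyses.

    Both arms share the baseline hazard, but the treated arm carries an
    extra log-hazard ``0.8 + 0.4 z_age`` that crosses zero deep in the
    younger tail: the treated drug is markedly worse for most patients and
    near-equivalent for the score-favorable subset, so the conditional
    effect is monotone in the score and changes sign.
    """
    b1 = np.zeros(9)
    b1[0], b1[1] = 0.8, 0.4
    base = dict(
        hazard_shape=1.0,
        hazard_scale_by_arm=(10.0, 10.0),
        log_hazard_coefficients_by_arm=(np.zeros(9), b1),
        ps_coefficients=np.array([0.5, 0.3, 0, 0.1, 0.2, 0, 0, 0, 0.1]),
    )
    base.update(overrides)
    return dr_scenario_config(**base)


def constant_effect_config(**overrides) -> SimConfig:
    """Constant-effect scenario: no covariate effects on either hazard, so
    the conditional effect is the same for every patient (fitted scores
    vary only by estimation noise)."""
    base = dict(
        log_hazard_coefficients_by_arm=(np.zeros(9), np.zeros(9)),
    )
    base.update(overrides)
    return dr_scenario_config(**base)


def sim_design_from_cohort(cohort: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Rebuild the generator's (truth) design columns from a cohort table."""
    cov = {"age": cohort["age"].to_numpy(), "male": cohort["male"].to_numpy()}
    for lab in LAB_NAMES:
        cov[lab] = cohort[lab].to_numpy()
    return sim_design(cov, config)


def _fit_scenario_nuisances(
    cohort: pd.DataFrame, config: SimConfig, ps_spec: str, or_spec: str
):
    """Correct = lambda-0 fit on the generator's design; broken = intercept-only."""
    z = sim_design_from_cohort(cohort, config)[:, 1:]  # drop intercept column
    arm = cohort["arm"].to_numpy()
    time = cohort["time"].to_numpy()
    event = cohort["event"].to_numpy()

    if ps_spec == "correct":
        pi = fit_logistic_mle(z, arm).propensities
    elif ps_spec == "broken":
        pi = np.full(len(arm), arm.mean())
    else:
        raise ConfigError(f"unknown ps_spec '{ps_spec}'")

    import warnings as _w

    preds = {}
    for a in (1, 0):
        mask = arm == a
        if or_spec == "correct":
            fit = fit_cox_mle(z[mask], time[mask], event[mask], arm_label=a)
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # horizon can exceed last event time
                preds[a] = predict_survival(fit, z, config.horizon_t)
        elif or_spec == "broken":
            fit = intercept_only_cox(time[mask], event[mask], arm_label=a)
            lam = fit.cumulative_hazard(config.horizon_t)
            preds[a] = np.full(len(arm), np.exp(-lam))
        else:
            raise ConfigError(f"unknown or_spec '{or_spec}'")
    return pi, preds[1], preds[0]


DEFAULT_SCENARIOS = {
    "both_correct": {"ps": "correct", "or": "correct"},
    "ps_correct_or_broken": {"ps": "correct", "or": "broken"},
    "ps_broken_or_correct": {"ps": "broken", "or": "correct"},
    "both_broken": {"ps": "broken", "or": "broken"},
}


def run_simulation_study(
    scenarios: dict | None = None,
    n_replicates: int = 200,
    *,
    n_patients: int = 5000,
    seed: int = 0,
    base_config: SimConfig | None = None,
    trim_bounds: tuple[float, float] = (0.01, 0.99),
    truth_draws: int = 500_000,
    return_replicates: bool = False,
):
    """Replicate loop over nuisance-specification scenarios.

    For each scenario and replicate: draw a cohort, fit the scenario's
    nuisance models, compute the AIPW t-year rate difference, and compare
    with the generator truth.  Returns a per-scenario summary frame (bias,
    empirical SE, mean estimated SE, 95% CI coverage), optionally plus the
    per-replicate estimates.
    """
    scenarios = DEFAULT_SCENARIOS if scenarios is None else scenarios
    base = base_config if base_config is not None else dr_scenario_config()
    base = dataclasses.replace(base, n_patients=n_patients)
    truth = ground_truth(base, n_draws=truth_draws, seed=seed + 10_000)
    true_ate = truth.hf_rate_diff

    rows = []
    reps = []
    for name, spec in scenarios.items():
        if "truth" in spec and spec["truth"] is None:
            raise ConfigError(f"scenario '{name}' is missing its ground truth")
        estimates = np.empty(n_replicates)
        ses = np.empty(n_replicates)
        covered = np.zeros(n_replicates, dtype=bool)
        for r in range(n_replicates):
            cfg = dataclasses.replace(base, seed=seed + 1000 * (r + 1))
            cohort = generate_cohort(cfg)
            pi, s1, s0 = _fit_scenario_nuisances(
                cohort, cfg, spec["ps"], spec["or"]
            )
            res = aipw_ate(
                cohort["time"], cohort["event"], cohort["arm"],
                pi, s1, s0, cfg.horizon_t, trim_bounds=trim_bounds,
            )
            estimates[r] = res.ate
            ses[r] = res.se
            covered[r] = res.ci[0] <= true_ate <= res.ci[1]
            if return_replicates:
                reps.append(
                    {"scenario": name, "replicate": r, "ate": res.ate,
                     "se": res.se, "covered": bool(covered[r])}
                )
        rows.append(
            {
                "scenario": name,
                "ps": spec["ps"],
                "or": spec["or"],
                "n_replicates": n_replicates,
                "true_ate": true_ate,
                "mean_estimate": float(estimates.mean()),
                "bias": float(estimates.mean() - true_ate),
                "empirical_se": float(estimates.std(ddof=1)),
                "mean_estimated_se": float(ses.mean()),
                "coverage": float(covered.mean()),
            }
        )
    summary = pd.DataFrame(rows)
    if return_replicates:
        return summary, pd.DataFrame(reps)
    return summary
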