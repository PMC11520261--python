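"""IPW diagnostics and the doubly robust t-year event-rate difference.

The estimand is the difference in t-year event (heart-failure) rates
between the treated and comparator arms.  The estimator is augmented
inverse-probability weighting (AIPW) with inverse-probability-of-censoring
correction:

    psi_i^a = S_a(t|X_i)
              + I(arm_i = a) / pi_a(X_i)
                * Delta_i(t) / G_a(min(T_i, t)-)
                * (I(T_i > t) - S_a(t|X_i))

where ``Delta_i(t) = I(T_i > t) + I(T_i <= t) * event_i`` indicates that the
t-year status is known, ``G_a`` is the arm-specific Kaplan-Meier estimator
of the censoring distribution (evaluated with left limits), and
``S_a(t|X)`` comes from the arm-specific Cox fits.  Then
``S_a(t) = mean(psi^a)``, ``rate_a = 1 - S_a(t)`` and
``ATE = rate_1 - rate_0`` (positive = treated arm has the higher event
rate).  The estimator is consistent if *either* the propensity model or
the outcome model is correctly specified; standard errors come from the
empirical variance of the per-patient influence contributions, with a
seeded patient-level bootstrap as cross-check.

Patients with extreme estimated propensities are trimmed before
estimation (default bounds 0.01-0.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from drclaims.exceptions import DataError
from drclaims.nuisance import CoxFit, PSFit, predict_propensity, predict_survival

__all__ = [
    "ipw_weights",
    "balance_diagnostics",
    "weighted_km",
    "ATEResult",
    "aipw_ate",
    "aipw_ate_from_fits",
]


def ipw_weights(
    propensity: np.ndarray,
    arm: np.ndarray,
    trim_bounds: tuple[float, float] = (0.01, 0.99),
    stabilized: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-probability-of-treatment weights with propensity trimming.

    Returns ``(weights, keep_mask)``: patients with propensity outside
    ``trim_bounds`` are masked out (their weight entry is 0); kept treated
    patients get ``1/pi`` and kept comparator patients ``1/(1-pi)``.  The
    stabilized variant multiplies by the (untrimmed) arm prevalence.
    """
    pi = np.asarray(propensity, dtype=float)
    a = np.asarray(arm, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise DataError("propensities must lie strictly inside (0, 1)")
    lo, hi = trim_bounds
    keep = (pi >= lo) & (pi <= hi)
    if not (np.any(a[keep] == 1) and np.any(a[keep] == 0)):
        raise DataError("propensity trimming removed an entire arm")
    w = np.where(a == 1, 1.0 / pi, 1.0 / (1.0 - pi))
    if stabilized:
        prev = a.mean()
        w = np.where(a == 1, prev * w, (1.0 - prev) * w)
    w = np.where(keep, w, 0.0)
    return w, keep


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    if sw <= 0:
        return np.nan, np.nan
    m = float(np.sum(w * x) / sw)
    v = float(np.sum(w * (x - m) ** 2) / sw)
    return m, v


def balance_diagnostics(
    covariates: pd.DataFrame,
    arm: np.ndarray,
    weights: np.ndarray | None = None,
    smd_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-covariate means/SDs by arm and standardized mean differences,
    before (unit weights) and after weighting.

    SMD = |mean_1 - mean_0| / sqrt((var_1 + var_0) / 2); a zero pooled SD
    yields SMD 0 with the ``zero_sd`` flag set.  ``flag_after`` marks
    covariates whose post-weighting SMD exceeds ``smd_threshold``.
    """
    a = np.asarray(arm, dtype=float)
    if weights is None:
        weights = np.ones(len(a))
    w = np.asarray(weights, dtype=float)
    rows = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(dtype=float)
        rec = {"covariate": col}
        for tag, wt in (("before", np.ones(len(a))), ("after", w)):
            m1, v1 = _weighted_moments(x[a == 1], wt[a == 1])
            m0, v0 = _weighted_moments(x[a == 0], wt[a == 0])
            pooled = np.sqrt((v1 + v0) / 2.0)
            smd = 0.0 if pooled == 0 else abs(m1 - m0) / pooled
            rec.update({
                f"mean1_{tag}": m1, f"sd1_{tag}": np.sqrt(v1),
                f"mean0_{tag}": m0, f"sd0_{tag}": np.sqrt(v0),
                f"smd_{tag}": float(smd),
            })
            if tag == "after":
                rec["zero_sd"] = bool(pooled == 0)
        rec["flag_after"] = bool(rec["smd_after"] > smd_threshold)
        rows.append(rec)
    return pd.DataFrame(rows)


def _km_curve(
    time: np.ndarray, event: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Kaplan-Meier survival; returns (event_times, S(t)) steps."""
    order = np.argsort(time, kind="mergesort")
    t_s, w_s = time[order], weights[order]
    e_mask = event[order] == 1
    if not np.any(e_mask):
        return np.array([]), np.array([])
    ev_times, inv = np.unique(t_s[e_mask], return_inverse=True)
    d = np.bincount(inv, weights=w_s[e_mask])
    total_w = w_s.sum()
    # at-risk weight just before each distinct event time
    cum_w = np.concatenate([[0.0], np.cumsum(w_s)])
    at_risk = total_w - cum_w[np.searchsorted(t_s, ev_times, side="left")]
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - d / at_risk, 1.0)
    return ev_times, np.cumprod(factors)


def weighted_km(
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    arm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted Kaplan-Meier event-probability curves (1 - S(t)).

    Returns a tidy frame with columns ``arm`` (omitted when ``arm`` is
    None), ``time`` and ``hf_probability`` — one row per distinct event
    time, matching the orientation of cumulative-incidence displays.  A
    group with no events yields an empty (flat zero) curve.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.any(time <= 0):
        raise DataError("all survival times must be > 0")
    if weights is None:
        weights = np.ones(len(time))
    weights = np.asarray(weights, dtype=float)

    def one(mask: np.ndarray) -> pd.DataFrame:
        t, s = _km_curve(time[mask], event[mask], weights[mask])
        return pd.DataFrame({"time": t, "hf_probability": 1.0 - s})

    if arm is None:
        return one(np.ones(len(time), dtype=bool))
    arm = np.asarray(arm)
    frames = []
    for a in np.unique(arm):
        f = one(arm == a)
        f.insert(0, "arm", a)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _censoring_survival_left(
    time: np.ndarray, event: np.ndarray, eval_at: np.ndarray
) -> np.ndarray:
    """Left-limit Kaplan-Meier of the censoring distribution, G(u-).

    Censoring events are the complement of outcome events; at tied times,
    outcome events are taken to precede censorings, so the at-risk set at a
    censoring time includes same-time events.
    """
    c_times, g = _km_curve(time, 1 - event, np.ones(len(time)))
    if c_times.size == 0:
        return np.ones(len(eval_at))
    idx = np.searchsorted(c_times, eval_at, side="left")  # jumps strictly < u
    padded = np.concatenate([[1.0], g])
    return padded[idx]


@dataclass
class ATEResult:
    """Doubly robust t-year event rates and their difference."""

    t: float
    rate_treated: float
    rate_control: float
    se_treated: float
    se_control: float
    ate: float
    se: float
    ci: tuple[float, float]
    n_used: int
    n_trimmed: int
    #: per-patient pseudo-values on the trimmed cohort (survival scale)
    psi_treated: np.ndarray = field(repr=False, default=None)
    psi_control: np.ndarray = field(repr=False, default=None)
    keep_mask: np.ndarray = field(repr=False, default=None)
    bootstrap_se: float | None = None

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "rate_treated": self.rate_treated,
            "rate_control": self.rate_control,
            "se_treated": self.se_treated,
            "se_control": self.se_control,
            "ate": self.ate,
            "se": self.se,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "n_used": self.n_used,
            "n_trimmed": self.n_trimmed,
            "bootstrap_se": self.bootstrap_se,
        }


def _pseudo_values(
    time: np.ndarray,
    event: np.ndarray,
    arm: np.ndarray,
    propensity: np.ndarray,
    s_pred: np.ndarray,
    t: float,
    which_arm: int,
) -> np.ndarray:
    """AIPW pseudo-values psi^a for one arm on the (already trimmed) data."""
    in_arm = (arm == which_arm).astype(float)
    pi_a = propensity if which_arm == 1 else 1.0 - propensity
    above = (time > t).astype(float)
    delta = above + (1.0 - above) * event  # t-year status known
    mask_a = arm == which_arm
    g = np.ones(len(time))
    g_a = _censoring_survival_left(
        time[mask_a], event[mask_a], np.minimum(time, t)[mask_a]
    )
    g[mask_a] = g_a
    # horizon support: G_a just before t must be positive
    g_at_t = _censoring_survival_left(
        time[mask_a], event[mask_a], np.array([t])
    )[0]
    if mask_a.sum() and g_at_t <= 0:
        raise DataError(
            "horizon beyond follow-up support: censoring survival reaches 0 "
            f"before t={t} in arm {which_arm}"
        )
    ipcw = np.zeros(len(time))
    nonzero = (delta > 0) & mask_a
    ipcw[nonzero] = delta[nonzero] / g[nonzero]
    return s_pred + (in_arm / pi_a) * ipcw * (above - s_pred)


def aipw_ate(
    time,
    event,
    arm,
    propensity,
    s1_pred,
    s0_pred,
    t: float,
    *,
    trim_bounds: tuple[float, float] = (0.01, 0.99),
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ATEResult:
    """Doubly robust t-year event-rate difference from nuisance predictions.

    ``s1_pred`` / ``s0_pred`` are conditional survival predictions
    ``S_a(t | X_i)`` for *all* patients under each arm; ``propensity`` is
    ``P(arm = 1 | X_i)``.  Patients with propensity outside
    ``trim_bounds`` are trimmed before estimation.  ``n_bootstrap > 0``
    adds a seeded patient-level bootstrap SE for the ATE (nuisance
    predictions held fixed) as a cross-check on the influence-function SE.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    arm = np.asarray(arm).astype(int)
    pi = np.asarray(propensity, dtype=float)
    s1 = np.asarray(s1_pred, dtype=float)
    s0 = np.asarray(s0_pred, dtype=float)
    if t < 0:
        raise DataError("t must be >= 0")
    if not (len(time) == len(event) == len(arm) == len(pi) == len(s1) == len(s0)):
        raise DataError("input arrays are not aligned")

    _, keep = ipw_weights(pi, arm, trim_bounds)
    n_trimmed = int((~keep).sum())
    tt, ee, aa = time[keep], event[keep], arm[keep]
    pp, ss1, ss0 = pi[keep], s1[keep], s0[keep]
    n = len(tt)

    if t == 0:
        psi1 = np.ones(n)
        psi0 = np.ones(n)
    else:
        psi1 = _pseudo_values(tt, ee, aa, pp, ss1, t, 1)
        psi0 = _pseudo_values(tt, ee, aa, pp, ss0, t, 0)

    s1_hat, s0_hat = psi1.mean(), psi0.mean()
    contrast = psi0 - psi1  # rate_1 - rate_0 on the event scale
    ate = float(contrast.mean())
    se = float(contrast.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    se1 = float(psi1.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    se0 = float(psi0.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    boot_se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            stats[b] = contrast[idx].mean()
        boot_se = float(stats.std(ddof=1))

    return ATEResult(
        t=float(t),
        rate_treated=float(1.0 - s1_hat),
        rate_control=float(1.0 - s0_hat),
        se_treated=se1,
        se_control=se0,
        ate=ate,
        se=se,
        ci=(ate - 1.96 * se, ate + 1.96 * se),
        n_used=n,
        n_trimmed=n_trimmed,
        psi_treated=psi1,
        psi_control=psi0,
        keep_mask=keep,
        bootstrap_se=boot_se,
    )


def aipw_ate_from_fits(
    X: pd.DataFrame,
    time,
    event,
    arm,
    psfit: PSFit,
    coxfit_1: CoxFit,
    coxfit_0: CoxFit,
    t: float,
    *,
    trim_bounds: tuple[float, float] = (0.01, 0.99),
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ATEResult:
    """Convenience wrapper: compute nuisance predictions from fitted models
    sharing the same design columns, then run :func:`aipw_ate`."""
    if set(coxfit_1.columns) != set(coxfit_0.columns):
        raise DataError("the two Cox fits use different design columns")
    pi = predict_propensity(psfit, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s1 = predict_survival(coxfit_1, X, t)
        s0 = predict_survival(coxfit_0, X, t)
    return aipw_ate(
        time, event, arm, pi, s1, s0, t,
        trim_bounds=trim_bounds, n_bootstrap=n_bootstrap, seed=seed,
    )
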