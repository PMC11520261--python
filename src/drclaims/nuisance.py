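"""Adaptive-LASSO nuisance models: logistic propensity and Cox outcome fits.

Both models use the same two-stage adaptive LASSO:

1. an initial ridge fit gives preliminary coefficients ``beta~``;
2. a weighted-L1 fit with per-column penalty weight
   ``w_j = 1 / (|beta~_j| + eps)**gamma`` (``gamma = 1``, ``eps = 1e-6``)
   shrinks uninformative columns exactly to zero while informative columns
   are penalized lightly.

The L1 tuning parameter is chosen by seeded K-fold cross-validation
(default K = 10, minimum mean CV deviance, folds keyed to patient ids so
row order is irrelevant).  Designated columns (e.g. the age-basis columns,
which are forced confounders) can be exempted from penalization, as is the
intercept.

Cox fits use the Breslow tie approximation throughout, and carry the
Breslow cumulative baseline hazard so conditional survival
``S(t|x) = exp(-Lambda0(t) * exp(x beta))`` can be predicted at any
horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from drclaims._coxlik import (
    breslow_baseline,
    cox_partial_gradient,
    cox_partial_loglik,
    evaluate_step,
)
from drclaims._penalized import logistic_deviance, logistic_path
from drclaims.exceptions import ConfigError, DataError

__all__ = [
    "PSFit",
    "CoxFit",
    "fit_adaptive_lasso_logistic",
    "fit_adaptive_lasso_cox",
    "fit_logistic_mle",
    "fit_cox_mle",
    "predict_propensity",
    "predict_survival",
    "cox_partial_loglik",
    "cox_partial_gradient",
    "breslow_baseline",
]


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------


@dataclass
class PSFit:
    """Fitted propensity model: P(arm = 1 | X)."""

    intercept: float
    coef: pd.Series  # indexed by design column names; exact zeros kept
    propensities: np.ndarray  # on the training rows
    alpha: float
    alphas: np.ndarray
    cv_deviance: np.ndarray
    converged: bool = True

    @property
    def columns(self) -> list[str]:
        return list(self.coef.index)

    @property
    def support(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])

    def to_dict(self) -> dict:
        return {
            "model": "logistic_propensity",
            "intercept": self.intercept,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "alpha": float(self.alpha),
            "alphas": [float(a) for a in self.alphas],
            "cv_deviance": [float(d) for d in self.cv_deviance],
        }


@dataclass
class CoxFit:
    """Fitted arm-specific Cox model with Breslow baseline hazard."""

    arm_label: object
    coef: pd.Series
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    alpha: float = 0.0
    alphas: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_deviance: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def columns(self) -> list[str]:
        return list(self.coef.index)

    @property
    def support(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])

    def cumulative_hazard(self, t) -> np.ndarray:
        """Breslow cumulative baseline hazard Lambda0(t), 0 at t=0."""
        return evaluate_step(self.baseline_times, self.baseline_cumhaz, t)

    def to_dict(self) -> dict:
        return {
            "model": "cox_outcome",
            "arm_label": self.arm_label,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "baseline_hazard": [
                [float(t), float(h)]
                for t, h in zip(self.baseline_times, self.baseline_cumhaz)
            ],
            "alpha": float(self.alpha),
        }


def _design_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _fold_labels(ids: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment keyed to (sorted) ids: row-order invariant."""
    ids = np.asarray(ids)
    order = np.argsort(ids, kind="mergesort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    folds[order] = perm % n_folds
    return folds


def _select_alpha(
    alphas: np.ndarray, cv_dev: np.ndarray, fold_dev: np.ndarray, rule: str
) -> int:
    """Index of the selected penalty on a descending-alpha path.

    ``"min"``: argmin of the mean CV deviance.  ``"1se"``: the largest
    alpha whose mean deviance is within one standard error (over folds) of
    the minimum.
    """
    best = int(np.argmin(cv_dev))
    if rule == "min":
        return best
    if rule != "1se":
        raise ConfigError(f"unknown lambda_rule '{rule}'")
    k = fold_dev.shape[0]
    se = float(fold_dev[:, best].std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    within = np.nonzero(cv_dev <= cv_dev[best] + se)[0]
    return int(within[0])  # alphas descend: first qualifying = sparsest


def _penalty_weights(
    beta_init: np.ndarray, columns: list[str], penalty_free, gamma: float, eps: float
) -> np.ndarray:
    w = 1.0 / (np.abs(beta_init) + eps) ** gamma
    free = set(penalty_free or ())
    unknown = free - set(columns)
    if unknown:
        raise ConfigError(f"penalty_free names not in design: {sorted(unknown)}")
    for j, c in enumerate(columns):
        if c in free:
            w[j] = 0.0
    return w


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------


def fit_adaptive_lasso_logistic(
    X,
    arm,
    *,
    penalty_free=(),
    n_folds: int = 10,
    seed: int = 0,
    gamma: float = 1.0,
    eps: float = 1e-6,
    alphas=None,
    n_alphas: int = 15,
    alpha_min_ratio: float = 1e-3,
    patient_id=None,
    max_iter: int = 500,
    tol: float = 1e-7,
    lambda_rule: str = "1se",
) -> PSFit:
    """Two-stage adaptive-LASSO logistic propensity fit.

    ``penalty_free`` names columns never penalized (the intercept is always
    unpenalized).  ``alphas`` overrides the automatic log-spaced penalty
    grid.  ``lambda_rule`` selects the penalty from the CV deviance curve:
    ``"1se"`` (default) takes the sparsest model within one fold-level
    standard error of the minimum — the min-deviance rule (``"min"``)
    systematically admits spurious noise columns because deviance dips of
    the order of the CV noise occur along the path.
    """
    Xa, columns = _design_array(X)
    y = np.asarray(arm, dtype=float)
    n = len(y)
    if n <= 10:
        raise DataError("need more than 10 observations to fit the PS model")
    if len(np.unique(y)) < 2:
        raise DataError("both arms must be present to fit a propensity model")

    ridge = LogisticRegression(C=1.0, max_iter=2000)  # L2 by default
    ridge.fit(Xa, y)
    w = _penalty_weights(ridge.coef_[0], columns, penalty_free, gamma, eps)

    if alphas is None:
        p_null = y.mean()
        grad0 = Xa.T @ (p_null - y) / n
        with np.errstate(divide="ignore"):
            ratios = np.abs(grad0) / w
        finite = ratios[np.isfinite(ratios) & (w > 0)]
        alpha_max = float(finite.max()) if finite.size else 1.0
        if alpha_max <= 0:
            alpha_max = 1.0
        alphas = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alphas)
    alphas = np.asarray(alphas, dtype=float)

    ids = np.asarray(patient_id) if patient_id is not None else np.arange(n)
    folds = _fold_labels(ids, n_folds, seed)
    fold_dev = np.zeros((n_folds, len(alphas)))
    fold_sizes = np.zeros(n_folds)
    for k in range(n_folds):
        test = folds == k
        fold_sizes[k] = test.sum()
        b0s, betas, _ = logistic_path(
            Xa[~test], y[~test], w, alphas, max_iter=max_iter, tol=tol
        )
        for a_idx in range(len(alphas)):
            fold_dev[k, a_idx] = logistic_deviance(
                b0s[a_idx], betas[a_idx], Xa[test], y[test]
            )
    cv_dev = fold_sizes @ fold_dev / n

    best = _select_alpha(alphas, cv_dev, fold_dev, lambda_rule)
    b0s, betas, flags = logistic_path(
        Xa, y, w, alphas[: best + 1], max_iter=max_iter, tol=tol
    )
    intercept, beta = float(b0s[best]), betas[best]
    eta = intercept + Xa @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    return PSFit(
        intercept=intercept,
        coef=pd.Series(beta, index=columns),
        propensities=pi,
        alpha=float(alphas[best]),
        alphas=alphas,
        cv_deviance=cv_dev,
        converged=bool(flags[best]),
    )


def fit_logistic_mle(X, arm) -> PSFit:
    """Unpenalized logistic fit (the lambda = 0 special case)."""
    Xa, columns = _design_array(X)
    y = np.asarray(arm, dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("both arms must be present to fit a propensity model")
    model = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized
    model.fit(Xa, y)
    pi = model.predict_proba(Xa)[:, 1]
    return PSFit(
        intercept=float(model.intercept_[0]),
        coef=pd.Series(model.coef_[0], index=columns),
        propensities=np.clip(pi, 1e-12, 1 - 1e-12),
        alpha=0.0,
        alphas=np.array([0.0]),
        cv_deviance=np.array([np.nan]),
    )


def predict_propensity(fit: PSFit, Xnew) -> np.ndarray:
    """expit(intercept + Xnew @ beta) on the fit's design columns."""
    if isinstance(Xnew, pd.DataFrame):
        missing = [c for c in fit.columns if c not in Xnew.columns]
        if missing:
            raise DataError(f"design columns missing from Xnew: {missing[:5]}")
        Xa = Xnew[fit.columns].to_numpy(dtype=float)
    else:
        Xa = np.asarray(Xnew, dtype=float)
        if Xa.shape[1] != len(fit.columns):
            raise DataError(
                f"Xnew has {Xa.shape[1]} columns, fit expects {len(fit.columns)}"
            )
    eta = fit.intercept + Xa @ fit.coef.to_numpy()
    return np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)


# ---------------------------------------------------------------------------
# outcome (Cox) models
# ---------------------------------------------------------------------------


def _check_survival_inputs(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.any(time <= 0):
        raise DataError("all survival times must be > 0")
    if event.sum() < 1:
        raise DataError("need at least one event to fit a Cox model")
    if len(np.unique(time)) == 1:
        warnings.warn(
            "all survival times are tied; Breslow tie handling applies",
            stacklevel=3,
        )
    return time, event


def fit_adaptive_lasso_cox(
    X,
    time,
    event,
    *,
    arm_label=None,
    penalty_free=(),
    n_folds: int = 10,
    seed: int = 0,
    gamma: float = 1.0,
    eps: float = 1e-6,
    ridge_alpha: float = 0.01,
    alphas=None,
    n_alphas: int = 15,
    alpha_min_ratio: float = 0.01,
    patient_id=None,
    lambda_rule: str = "1se",
) -> CoxFit:
    """Two-stage adaptive-LASSO Cox fit with Breslow baseline hazard.

    Stage 1 is a ridge Cox fit (L2 strength ``ridge_alpha`` per
    observation); stage 2 a weighted-L1 coordinate-descent path (Coxnet)
    with per-column penalty factors, tuned by K-fold cross-validated
    partial-likelihood deviance (Verweij & Van Houwelingen: full-data minus
    training partial likelihood).  ``lambda_rule`` as in
    :func:`fit_adaptive_lasso_logistic` (default ``"1se"``).
    """
    Xa, columns = _design_array(X)
    time, event = _check_survival_inputs(time, event)
    n = len(time)
    y_surv = Surv.from_arrays(event.astype(bool), time)

    ridge = CoxPHSurvivalAnalysis(alpha=ridge_alpha * n, ties="breslow")
    ridge.fit(Xa, y_surv)
    w = _penalty_weights(ridge.coef_, columns, penalty_free, gamma, eps)

    def _path(Xtr, ytr, grid):
        model = CoxnetSurvivalAnalysis(
            alphas=grid,
            penalty_factor=w,
            l1_ratio=1.0,
            normalize=False,
            fit_baseline_model=False,
            tol=1e-7,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        return model

    if alphas is None:
        probe = CoxnetSurvivalAnalysis(
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            penalty_factor=w,
            l1_ratio=1.0,
            normalize=False,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(Xa, y_surv)
        alphas = probe.alphas_
    alphas = np.asarray(alphas, dtype=float)

    ids = np.asarray(patient_id) if patient_id is not None else np.arange(n)
    folds = _fold_labels(ids, n_folds, seed)
    fold_dev = np.zeros((n_folds, len(alphas)))
    fold_sizes = np.zeros(n_folds)
    for k in range(n_folds):
        test = folds == k
        train = ~test
        fold_sizes[k] = test.sum()
        if event[train].sum() == 0:
            raise DataError(f"cross-validation fold {k} has no training events")
        fit_k = _path(Xa[train], Surv.from_arrays(event[train].astype(bool),
                                                  time[train]), alphas)
        coefs = _coef_path(fit_k, alphas)
        for a_idx in range(len(alphas)):
            beta = coefs[a_idx]
            ll_full = cox_partial_loglik(beta, Xa, time, event)
            ll_train = cox_partial_loglik(beta, Xa[train], time[train], event[train])
            fold_dev[k, a_idx] = -2.0 * (ll_full - ll_train) / max(test.sum(), 1)
    cv_dev = fold_sizes @ fold_dev / n

    best = _select_alpha(alphas, cv_dev, fold_dev, lambda_rule)
    final = _path(Xa, y_surv, alphas)
    beta = _coef_path(final, alphas)[best]
    bt, bh = breslow_baseline(beta, Xa, time, event)
    return CoxFit(
        arm_label=arm_label,
        coef=pd.Series(beta, index=columns),
        baseline_times=bt,
        baseline_cumhaz=bh,
        alpha=float(alphas[best]),
        alphas=alphas,
        cv_deviance=cv_dev,
    )


def _coef_path(model: CoxnetSurvivalAnalysis, alphas: np.ndarray) -> np.ndarray:
    """Coefficients per requested alpha, shape (n_alphas, p).

    Coxnet may truncate the path; missing tail alphas reuse the last
    available coefficients.
    """
    fitted = np.asarray(model.alphas_)
    coefs = model.coef_.T  # (n_fitted, p)
    out = np.empty((len(alphas), coefs.shape[1]))
    for i, a in enumerate(alphas):
        j = int(np.argmin(np.abs(fitted - a)))
        out[i] = coefs[j]
    return out


def fit_cox_mle(X, time, event, *, arm_label=None, l2_alpha: float = 0.0) -> CoxFit:
    """Unpenalized (or ridge) Cox fit, Breslow ties and baseline hazard."""
    Xa, columns = _design_array(X)
    time, event = _check_survival_inputs(time, event)
    model = CoxPHSurvivalAnalysis(alpha=l2_alpha, ties="breslow", tol=1e-12)
    model.fit(Xa, Surv.from_arrays(event.astype(bool), time))
    beta = model.coef_
    bt, bh = breslow_baseline(beta, Xa, time, event)
    return CoxFit(
        arm_label=arm_label,
        coef=pd.Series(beta, index=columns),
        baseline_times=bt,
        baseline_cumhaz=bh,
    )


def intercept_only_cox(time, event, *, arm_label=None, columns=()) -> CoxFit:
    """The no-covariate fit: baseline hazard = Nelson-Aalen estimator."""
    time, event = _check_survival_inputs(time, event)
    n = len(time)
    bt, bh = breslow_baseline(np.zeros(1), np.zeros((n, 1)), time, event)
    coef = pd.Series(np.zeros(len(columns)), index=list(columns), dtype=float)
    return CoxFit(
        arm_label=arm_label, coef=coef, baseline_times=bt, baseline_cumhaz=bh
    )


def predict_survival(fit: CoxFit, Xnew, t, *, return_flag: bool = False):
    """Conditional survival ``S(t|x) = exp(-Lambda0(t) exp(x beta))``.

    ``t`` may exceed the last observed event time, in which case the last
    baseline-hazard step is carried forward and a flag is raised (returned
    when ``return_flag``, warned otherwise).
    """
    if t < 0:
        raise DataError("t must be >= 0")
    if isinstance(Xnew, pd.DataFrame):
        missing = [c for c in fit.columns if c not in Xnew.columns]
        if missing:
            raise DataError(f"design columns missing from Xnew: {missing[:5]}")
        Xa = Xnew[fit.columns].to_numpy(dtype=float)
    else:
        Xa = np.asarray(Xnew, dtype=float)
        if len(fit.columns) and Xa.shape[1] != len(fit.columns):
            raise DataError(
                f"Xnew has {Xa.shape[1]} columns, fit expects {len(fit.columns)}"
            )
    beyond = bool(len(fit.baseline_times)) and t > fit.baseline_times[-1]
    lam = float(fit.cumulative_hazard(t))
    if len(fit.columns):
        lp = Xa @ fit.coef.to_numpy()
    else:
        lp = np.zeros(Xa.shape[0])
    s = np.exp(-lam * np.exp(lp))
    if beyond and not return_flag:
        warnings.warn(
            f"t={t} is beyond the last observed event time "
            f"{fit.baseline_times[-1]:.4g}; carrying the last hazard step forward",
            stacklevel=2,
        )
    return (s, beyond) if return_flag else s
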