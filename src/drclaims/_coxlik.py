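"""Cox partial likelihood with Breslow tie handling, plus the Breslow
cumulative baseline hazard.

These are the primitives behind cross-validated deviance scoring, survival
prediction and the small-sample oracle tests; fitting itself is delegated
to Newton (scikit-survival) and coordinate-descent (Coxnet) routines.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cox_partial_loglik",
    "cox_partial_gradient",
    "breslow_baseline",
    "evaluate_step",
]


def _risk_suffix_sums(time: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each row i (in input order) return the sum of ``values`` over the
    risk set {j : t_j >= t_i}.  ``values`` may be 1-d or 2-d (rows)."""
    order = np.argsort(time, kind="mergesort")
    t_sorted = time[order]
    v_sorted = values[order]
    suffix = np.cumsum(v_sorted[::-1], axis=0)[::-1]
    # map each time to the first index with that time (ties share a risk set)
    first = np.searchsorted(t_sorted, time, side="left")
    return suffix[first], order


def cox_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood at ``beta`` (not normalized by n)."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    lp = X @ beta
    lp = lp - lp.mean()  # invariant shift, for numerical stability
    elp = np.exp(lp)
    rs, _ = _risk_suffix_sums(time, elp)
    return float(np.sum(lp[event] - np.log(rs[event])))


def cox_partial_gradient(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Gradient of the Breslow partial log-likelihood at ``beta``."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    lp = X @ beta
    lp = lp - lp.mean()
    elp = np.exp(lp)
    s0, _ = _risk_suffix_sums(time, elp)
    s1, _ = _risk_suffix_sums(time, elp[:, None] * X)
    xbar = s1 / s0[:, None]
    return np.sum(X[event] - xbar[event], axis=0)


def breslow_baseline(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard step function.

    Returns ``(times, cumhaz)`` where ``times`` are the distinct event
    times (ascending) and ``cumhaz`` the cumulative baseline hazard at each
    (``Lambda0(0) = 0`` implicitly).  With ``beta = 0`` this is the
    Nelson-Aalen estimator.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    elp = np.exp(X @ np.asarray(beta, dtype=float))
    s0, _ = _risk_suffix_sums(time, elp)
    ev_times = time[event]
    ev_s0 = s0[event]
    order = np.argsort(ev_times, kind="mergesort")
    ev_times, ev_s0 = ev_times[order], ev_s0[order]
    uniq, start = np.unique(ev_times, return_index=True)
    d = np.diff(np.append(start, len(ev_times)))  # tied-event counts
    increments = d / ev_s0[start]
    return uniq, np.cumsum(increments)


def evaluate_step(times: np.ndarray, values: np.ndarray, t) -> np.ndarray:
    """Evaluate a right-continuous step function (0 before the first jump)."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(times, t, side="right")
    padded = np.concatenate([[0.0], values])
    return padded[idx]
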