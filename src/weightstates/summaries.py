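"""Summaries derived from an intensity matrix: transition probabilities,
mean sojourn times, total length of stay, prevalence projection, and the
projection-validation rule.

For a time-homogeneous chain with intensity matrix Q,

* ``P(t) = expm(tQ)`` gives the t-year transition probabilities;
* the mean sojourn time in state r is ``-1/q_rr`` (exponential holding time);
* the expected total time spent in state s over ``[0, T]`` starting from r is
  the integral ``int_0^T P_rs(u) du``, computed exactly via the augmented
  block matrix ``expm(T * [[Q, I], [0, 0]])`` whose upper-right block is the
  integral (adaptive quadrature is kept as an independent test oracle);
* the cohort prevalence at t is the baseline state distribution propagated
  through P(t).

Confidence intervals for sojourn times use the delta method on the
log-intensity scale; intervals for probabilities and lengths of stay use a
parametric bootstrap from the asymptotic parameter distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .markov import N_STATES, FittedModel, build_q, transition_probability, validate_q


def mean_sojourn(Q: np.ndarray) -> np.ndarray:
    """Mean sojourn time per state, years: -1/diagonal intensity.

    A state with no exit intensity (q_rr == 0) is absorbing; its sojourn is
    returned as ``inf``.
    """
    Q = validate_q(Q)
    d = np.diag(Q)
    with np.errstate(divide="ignore"):
        out = np.where(d < 0, -1.0 / np.where(d < 0, d, -1.0), np.inf)
    return out


def mean_sojourn_ci(fitted: FittedModel) -> np.ndarray:
    """Sojourn times with delta-method 95% CIs from a fitted model.

    Returns an array of shape (3, 3): columns are (estimate, lo, hi).
    The exit rate of state r is a sum of exponentials of log-intensities, so
    the variance of ``log(exit_r)`` follows from the log_q covariance block.
    """
    model = fitted.model
    Q = build_q(model)
    k = model.log_q.size
    cov = fitted.cov[:k, :k]
    trans = model.transitions
    q = np.exp(model.log_q)
    out = np.full((N_STATES, 3), np.inf)
    for r in range(N_STATES):
        idx = [i for i, (a, _) in enumerate(trans) if a == r]
        exit_rate = -Q[r, r]
        if not idx or exit_rate <= 0:
            continue
        grad = np.zeros(k)
        for i in idx:
            grad[i] = q[i] / exit_rate  # d log(exit) / d log_q_i
        se_log = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        s = 1.0 / exit_rate
        out[r] = (s, s * np.exp(-1.96 * se_log), s * np.exp(1.96 * se_log))
    return out


def integrated_transition_probability(Q: np.ndarray, T: float) -> np.ndarray:
    """``int_0^T expm(Qu) du`` via the augmented block-matrix exponential."""
    Q = validate_q(Q)
    if T < 0:
        raise ValueError("horizon must be non-negative")
    A = np.zeros((2 * N_STATES, 2 * N_STATES))
    A[:N_STATES, :N_STATES] = Q
    A[:N_STATES, N_STATES:] = np.eye(N_STATES)
    return expm(T * A)[:N_STATES, N_STATES:]


def total_length_of_stay(Q: np.ndarray, start_state: int, T: float) -> np.ndarray:
    """Expected years spent in each state over [0, T] from ``start_state`` (1-based).

    Entries sum to T exactly (up to floating point): time is conserved.
    """
    if not 1 <= start_state <= N_STATES:
        raise ValueError("start_state must be in 1..3")
    return integrated_transition_probability(Q, T)[start_state - 1]


def project_prevalence(init_dist: np.ndarray, Q: np.ndarray, t: float) -> np.ndarray:
    """Cohort state distribution after t years: ``init_dist @ P(t)``."""
    init = np.asarray(init_dist, dtype=float)
    if init.shape != (N_STATES,):
        raise ValueError("initial distribution must have 3 entries")
    if np.any(init < 0):
        raise ValueError("initial distribution entries must be non-negative")
    if abs(init.sum() - 1.0) > 1e-6:
        raise ValueError("initial distribution must sum to 1")
    return init @ transition_probability(Q, t)


def leave_probability(Q: np.ndarray, state: int, t: float) -> float:
    """Probability of being in a different state after t years: 1 - P_ss(t)."""
    if not 1 <= state <= N_STATES:
        raise ValueError("state must be in 1..3")
    P = transition_probability(Q, t)
    return float(1.0 - P[state - 1, state - 1])


def validate_projection(predicted: float, observed: float, ci: tuple[float, float]) -> dict:
    """Check a projected prevalence against an observed value with 95% CI.

    Valid if the prediction falls inside the observed CI, or if it differs
    from the observed value by less than 1% of the predicted value.
    """
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"inverted confidence interval ({lo}, {hi})")
    in_ci = lo <= predicted <= hi
    close = abs(predicted - observed) < 0.01 * abs(predicted)
    return {
        "valid": bool(in_ci or close),
        "in_ci": bool(in_ci),
        "within_1pct": bool(close),
        "predicted": float(predicted),
        "observed": float(observed),
        "ci": (float(lo), float(hi)),
    }


@dataclass
class TransitionSummary:
    """Transition probabilities, sojourns, lengths of stay and prevalence at
    one horizon, with 95% CIs where a fitted model supplies a covariance."""

    horizon: float
    P: np.ndarray                      # (3, 3)
    P_ci: np.ndarray | None            # (3, 3, 2) lo/hi
    sojourn: np.ndarray                # (3,) or (3, 3) with CI columns
    length_of_stay: np.ndarray         # (3,) from start_state
    length_of_stay_ci: np.ndarray | None
    start_state: int
    projected_prev: np.ndarray | None


def transition_summary(
    Q: np.ndarray | None = None,
    t: float = 1.0,
    start_state: int = 1,
    init_dist: np.ndarray | None = None,
    fitted: FittedModel | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> TransitionSummary:
    """One-stop summary at horizon ``t``.

    Pass either a raw intensity matrix (point estimates only) or a
    :class:`~weightstates.markov.FittedModel` (adds bootstrap CIs for the
    probabilities and lengths of stay, delta-method CIs for sojourns).
    """
    if (Q is None) == (fitted is None):
        raise ValueError("supply exactly one of Q or fitted")
    if fitted is not None:
        Q = build_q(fitted.model)
    P = transition_probability(Q, t)
    los = total_length_of_stay(Q, start_state, t)
    prev = project_prevalence(init_dist, Q, t) if init_dist is not None else None

    P_ci = los_ci = None
    sojourn: np.ndarray
    if fitted is not None:
        sojourn = mean_sojourn_ci(fitted)
        rng = np.random.default_rng(0) if rng is None else rng
        draws_P = np.empty((n_boot, N_STATES, N_STATES))
        draws_L = np.empty((n_boot, N_STATES))
        k = fitted.model.log_q.size
        cov = fitted.cov[:k, :k]
        for b in range(n_boot):
            log_q = rng.multivariate_normal(fitted.model.log_q, cov)
            Qb = build_q(
                type(fitted.model)(log_q, None, (), fitted.model.mask)
            )
            draws_P[b] = transition_probability(Qb, t)
            draws_L[b] = total_length_of_stay(Qb, start_state, t)
        P_ci = np.stack(
            [np.quantile(draws_P, 0.025, axis=0), np.quantile(draws_P, 0.975, axis=0)],
            axis=-1,
        )
        los_ci = np.stack(
            [np.quantile(draws_L, 0.025, axis=0), np.quantile(draws_L, 0.975, axis=0)],
            axis=-1,
        )
    else:
        sojourn = mean_sojourn(Q)

    return TransitionSummary(
        horizon=t,
        P=P,
        P_ci=P_ci,
        sojourn=sojourn,
        length_of_stay=los,
        length_of_stay_ci=los_ci,
        start_state=start_state,
        projected_prev=prev,
    )
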