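"""Continuous-time, time-homogeneous multistate Markov engine for panel data.

The model: a child occupies one of three weight states (1 = normal,
2 = overweight, 3 = obese) and moves between *adjacent* states with
constant transition intensities ``q_rs`` (per year).  The state is observed
only at examination times (interval censoring), so the likelihood of a
child's record is a product of matrix-exponential transition probabilities
``P(dt) = expm(dt * Q)`` over consecutive observation pairs.  Covariates act
proportionally on each allowed intensity, ``q_rs(z) = q_rs * exp(beta_rs . z)``,
evaluated piecewise-constant at the start of each interval; ``exp(beta)`` is
the hazard ratio for that transition.

Intensities are parameterized on the log scale so positivity is automatic,
and structurally forbidden transitions (normal <-> obese directly) are
excluded from the parameter vector entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import expm
from statsmodels.tools.numdiff import approx_hess

logger = logging.getLogger(__name__)

N_STATES = 3

#: Allowed instantaneous transitions: only between adjacent weight states.
ADJACENT_MASK = np.array(
    [
        [False, True, False],
        [True, False, True],
        [False, True, False],
    ]
)


def mask_transitions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Row-major list of (from, to) index pairs allowed by ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (N_STATES, N_STATES) or mask.diagonal().any():
        raise ValueError("mask must be 3x3 with a False diagonal")
    return [(r, s) for r in range(N_STATES) for s in range(N_STATES) if mask[r, s]]


@dataclass
class IntensityModel:
    """Baseline log-intensities plus per-transition covariate coefficients.

    Parameters
    ----------
    log_q
        Log baseline intensity for each allowed transition, in the row-major
        order given by :func:`mask_transitions`.
    beta
        Array of shape ``(n_transitions, n_covariates)`` of log-hazard-ratio
        coefficients; ``None`` for the null (no-covariate) model.
    covariates
        Names of the covariate columns, matching ``beta``'s second axis.
    """

    log_q: np.ndarray
    beta: np.ndarray | None = None
    covariates: tuple[str, ...] = ()
    mask: np.ndarray = field(default_factory=lambda: ADJACENT_MASK.copy())

    def __post_init__(self) -> None:
        self.log_q = np.atleast_1d(np.asarray(self.log_q, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        trans = mask_transitions(self.mask)
        if self.log_q.shape != (len(trans),):
            raise ValueError(
                f"log_q must have {len(trans)} entries for this mask, "
                f"got shape {self.log_q.shape}"
            )
        if self.beta is not None:
            self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
            if self.beta.shape[0] != len(trans):
                raise ValueError("beta must have one row per allowed transition")
            if len(self.covariates) != self.beta.shape[1]:
                raise ValueError("covariate names must match beta columns")

    @property
    def transitions(self) -> list[tuple[int, int]]:
        return mask_transitions(self.mask)

    @property
    def n_params(self) -> int:
        n = self.log_q.size
        if self.beta is not None:
            n += self.beta.size
        return n

    def pack(self) -> np.ndarray:
        """Flatten (log_q, beta) into a single parameter vector."""
        if self.beta is None:
            return self.log_q.copy()
        return np.concatenate([self.log_q, self.beta.ravel()])

    def unpack(self, theta: np.ndarray) -> "IntensityModel":
        """Rebuild a model of this shape from a flat parameter vector."""
        theta = np.asarray(theta, dtype=float)
        k = self.log_q.size
        beta = None
        if self.beta is not None:
            beta = theta[k:].reshape(self.beta.shape)
        return IntensityModel(theta[:k], beta, self.covariates, self.mask)


def build_q(model: IntensityModel, covariates: Sequence[float] | None = None) -> np.ndarray:
    """Intensity matrix for a given covariate vector (empty for the null model).

    ``q_rs = exp(log_q_rs + beta_rs . z)`` on allowed cells; the diagonal is
    the negative row sum so that rows sum to zero.
    """
    eta = model.log_q.copy()
    if model.beta is not None:
        z = np.zeros(model.beta.shape[1]) if covariates is None else np.asarray(covariates, float)
        if z.shape != (model.beta.shape[1],):
            raise ValueError("covariate vector does not match beta dimension")
        eta = eta + model.beta @ z
    elif covariates is not None and len(np.atleast_1d(covariates)):
        raise ValueError("null model takes no covariates")
    rates = np.exp(eta)
    if not np.all(np.isfinite(rates)):
        raise FloatingPointError("non-finite intensity from parameters")
    Q = np.zeros((N_STATES, N_STATES))
    for (r, s), q in zip(model.transitions, rates):
        Q[r, s] = q
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def validate_q(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError("Q must be 3x3")
    off = Q[~np.eye(N_STATES, dtype=bool)]
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8):
        raise ValueError("rows of an intensity matrix must sum to zero")
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(t Q): rows are probability distributions over end states."""
    if t < 0:
        raise ValueError("time horizon must be non-negative")
    Q = validate_q(Q)
    P = expm(t * Q)
    # expm is accurate to machine precision here; clip stray negatives of
    # magnitude ~1e-17 so downstream logs are safe.
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Panel likelihood
# ---------------------------------------------------------------------------

def _as_frame(ds) -> pd.DataFrame:
    return ds.df if hasattr(ds, "df") else ds


def interval_table(ds, covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Consecutive observation pairs, one row per interval.

    Columns: ``from_state``, ``to_state``, ``dt`` plus the covariate values
    at the interval start (piecewise-constant convention).
    """
    df = _as_frame(ds)
    if "state" not in df.columns:
        raise ValueError("states must be assigned before building intervals")
    df = df.sort_values(["child_id", "t"], kind="stable")
    g = df.groupby("child_id", sort=False)
    out = pd.DataFrame(
        {
            "child_id": df["child_id"],
            "from_state": df["state"],
            "to_state": g["state"].shift(-1),
            "dt": g["t"].shift(-1) - df["t"],
        }
    )
    for c in covariates:
        if c not in df.columns:
            raise KeyError(f"covariate column {c!r} not in dataset")
        out[c] = df[c].to_numpy()
    out = out.dropna(subset=["to_state"])
    if (out["dt"] <= 0).any():
        raise ValueError("non-increasing observation times within a child")
    out["to_state"] = out["to_state"].astype(int)
    out["from_state"] = out["from_state"].astype(int)
    return out.reset_index(drop=True)


def _grouped_counts(intervals: pd.DataFrame, covariates: Sequence[str]):
    """Aggregate intervals into (dt, z) groups with 3x3 pair-count matrices.

    The likelihood only depends on intervals through these sufficient
    statistics, which makes repeated evaluation during optimization cheap:
    one matrix exponential per distinct (dt, covariate-value) combination.
    """
    intervals = intervals.assign(dt=intervals["dt"].round(9))  # collapse float noise
    keys = ["dt", *covariates]
    grouped = intervals.groupby(keys, sort=False)
    groups = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        counts = np.zeros((N_STATES, N_STATES))
        np.add.at(counts, (sub["from_state"] - 1, sub["to_state"] - 1), 1.0)
        z = np.array(key[1:], dtype=float)
        groups.append((float(key[0]), z, counts))
    return groups


def panel_loglik(ds, model: IntensityModel) -> float:
    """Log-likelihood of interval-censored panel data under ``model``.

    Sum over consecutive observation pairs of ``log P_{from,to}(dt; z)``.
    Pairs with zero probability (possible only for degenerate intensity
    matrices) contribute ``-inf`` and are logged.
    """
    intervals = interval_table(ds, model.covariates)
    return _loglik_from_groups(_grouped_counts(intervals, model.covariates), model)


def _loglik_from_groups(groups, model: IntensityModel) -> float:
    total = 0.0
    for dt, z, counts in groups:
        Q = build_q(model, z if model.beta is not None else None)
        P = transition_probability(Q, dt)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        if np.any(counts[P == 0] > 0):
            logger.warning("observed transition has zero probability under model")
            return -np.inf
        total += float(np.nansum(counts * np.where(counts > 0, logP, 0.0)))
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """MLE result: point estimates, covariance, log-likelihood, AIC."""

    model: IntensityModel
    theta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    boundary: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.theta.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def q_matrix(self) -> np.ndarray:
        """Baseline intensity matrix at covariates = 0."""
        return build_q(self.model)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def intensity_table(self) -> pd.DataFrame:
        """Point estimates and 95% CIs for the baseline intensities."""
        trans = self.model.transitions
        k = self.model.log_q.size
        se = self.se()[:k]
        q = np.exp(self.model.log_q)
        return pd.DataFrame(
            {
                "transition": [f"{r + 1}->{s + 1}" for r, s in trans],
                "q": q,
                "lo": q * np.exp(-1.96 * se),
                "hi": q * np.exp(1.96 * se),
            }
        )

    def to_dict(self) -> dict:
        return {
            "log_q": self.model.log_q.tolist(),
            "beta": None if self.model.beta is None else self.model.beta.tolist(),
            "covariates": list(self.model.covariates),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
        }


def crude_initial_rates(ds, mask: np.ndarray = ADJACENT_MASK) -> np.ndarray:
    """Deterministic starting values: observed r->s pairs per year at risk in r.

    Observed non-adjacent pairs (e.g. 1 then 3 a year later) are attributed
    to the first allowed step of the path, which is enough for a starting
    point.  Transitions with no events start at a small floor rate.
    """
    intervals = interval_table(ds)
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (intervals["from_state"] - 1, intervals["to_state"] - 1), 1.0)
    time_at_risk = np.zeros(N_STATES)
    np.add.at(time_at_risk, intervals["from_state"] - 1, intervals["dt"])
    rates = []
    for r, s in mask_transitions(mask):
        rate = counts[r, s] / time_at_risk[r] if time_at_risk[r] > 0 else 0.0
        rates.append(max(rate, 1e-3))
    return np.array(rates)


def fit(
    ds,
    covariate: str | Sequence[str] | None = None,
    mask: np.ndarray = ADJACENT_MASK,
    start: IntensityModel | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedModel:
    """Maximum-likelihood fit of the panel multistate model.

    Parameters
    ----------
    ds
        Cohort dataset (or DataFrame) with ``child_id``, ``t``, ``state`` and
        any covariate columns.
    covariate
        Column name(s) to enter proportionally on every allowed transition;
        ``None`` fits the null model.  One covariate at a time is the
        intended use; several are accepted.
    start
        Optional explicit starting model; defaults to crude event rates from
        the observed pair counts (deterministic).

    Standard errors come from the inverse of the numerically differentiated
    observed information at the optimum.
    """
    cov_names: tuple[str, ...]
    if covariate is None:
        cov_names = ()
    elif isinstance(covariate, str):
        cov_names = (covariate,)
    else:
        cov_names = tuple(covariate)

    n_trans = len(mask_transitions(mask))
    if start is None:
        log_q0 = np.log(crude_initial_rates(ds, mask))
        beta0 = np.zeros((n_trans, len(cov_names))) if cov_names else None
        start = IntensityModel(log_q0, beta0, cov_names, mask)

    intervals = interval_table(ds, cov_names)
    # Boundary detection: intensities with no supporting events are pinned
    # near zero by the optimizer; flag them rather than failing.
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (intervals["from_state"] - 1, intervals["to_state"] - 1), 1.0)
    boundary = [(r + 1, s + 1) for r, s in mask_transitions(mask) if counts[r, s] == 0]
    if boundary:
        logger.warning("no observed events for transitions %s; estimates at boundary", boundary)

    groups = _grouped_counts(intervals, cov_names)

    def nll(theta: np.ndarray) -> float:
        ll = _loglik_from_groups(groups, start.unpack(theta))
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        nll,
        start.pack(),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not res.success and not boundary:
        raise RuntimeError(
            f"fit did not converge: {res.message} "
            f"(last loglik {-res.fun:.6f}, |grad| {np.abs(res.jac).max():.3g})"
        )
    fitted = start.unpack(res.x)

    hess = approx_hess(res.x, nll)
    cov = _robust_inverse(hess)
    return FittedModel(
        model=fitted,
        theta=res.x.copy(),
        cov=cov,
        loglik=-res.fun,
        converged=bool(res.success),
        n_iter=int(res.nit),
        boundary=boundary,
    )


def _robust_inverse(hess: np.ndarray) -> np.ndarray:
    """Invert the observed information, falling back to a pseudo-inverse and
    symmetrizing, so boundary fits still report usable (if wide) errors."""
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate data
        cov = np.linalg.pinv(hess)
    return 0.5 * (cov + cov.T)


def hazard_ratios(m: FittedModel) -> pd.DataFrame:
    """Per-transition hazard ratios exp(beta) with Wald 95% CIs."""
    if m.model.beta is None:
        raise ValueError("null model has no covariate effects")
    k = m.model.log_q.size
    se = m.se()[k:].reshape(m.model.beta.shape)
    rows = []
    for j, name in enumerate(m.model.covariates):
        for (r, s), b, s_e in zip(m.model.transitions, m.model.beta[:, j], se[:, j]):
            rows.append(
                {
                    "covariate": name,
                    "transition": f"{r + 1}->{s + 1}",
                    "hr": np.exp(b),
                    "lo": np.exp(b - 1.96 * s_e),
                    "hi": np.exp(b + 1.96 * s_e),
                }
            )
    return pd.DataFrame(rows)


def compare(m0: FittedModel, m1: FittedModel, tol: float = 1e-6) -> dict:
    """Likelihood-ratio test and AIC difference for nested fits (m0 in m1)."""
    df = m1.n_params - m0.n_params
    if df < 0:
        raise ValueError("m0 must be nested in m1 (fewer parameters)")
    lrt = 2.0 * (m1.loglik - m0.loglik)
    if lrt < -tol * max(1.0, abs(m0.loglik)):
        raise ValueError(
            f"larger model has lower likelihood ({m1.loglik:.4f} < {m0.loglik:.4f}); "
            "check convergence or nesting"
        )
    lrt = max(lrt, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(lrt, df))
    return {"lrt": lrt, "df": df, "p": p, "delta_aic": m1.aic - m0.aic}
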