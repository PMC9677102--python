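"""Adiposity rebound: per-child BMI-versus-age curves and their nadir.

A child's BMI typically falls through the preschool years, reaches a nadir
(the adiposity rebound, AR) somewhere around ages 4-8, and rises afterwards.
The curve family here is quadratic in age — the minimal family with an
interior minimum — fit as a linear mixed-effects model with random
intercept, slope and curvature per child; per-child curves are the fixed
effects plus the BLUP random deviations.  If the mixed fit fails to
converge (e.g. a singular random-effects structure), the fit falls back to
independent per-child ordinary least squares, and says so.

The AR age is the vertex -b1/(2 b2) of the child's curve when the curvature
b2 is positive and the vertex lies in the modeled age window; a concave or
monotone curve has no BMI minimum, so its AR age is absent.  "Late AR"
means an AR age at or after 7 years; children without an AR age are
counted as not late.  A vertex below the child's first observed age is an
extrapolation, flagged as such but still reported — school-age panels
usually begin after the true nadir.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Ages outside this window are never reported as an adiposity rebound.
DEFAULT_AGE_WINDOW = (3.0, 20.0)

LATE_AR_THRESHOLD = 7.0


def fit_bmi_curves(ds, method: str = "mixed") -> pd.DataFrame:
    """Fit quadratic BMI(age) curves per child.

    Parameters
    ----------
    ds
        Cohort dataset or DataFrame with child_id, exam_age and bmi columns.
    method
        ``"mixed"`` (default): one mixed-effects fit with per-child random
        intercept/linear/quadratic deviations; ``"ols"``: independent
        per-child least squares.

    Returns
    -------
    DataFrame with one row per child: b0, b1, b2 (curve coefficients),
    n_obs, age_min, age_max, method, and a ``flag`` column (``"too_few"``
    for children with fewer than 3 observations, whose coefficients are NaN).
    """
    df = ds.df if hasattr(ds, "df") else ds
    df = df.dropna(subset=["bmi"]).sort_values(["child_id", "exam_age"])
    sizes = df.groupby("child_id")["bmi"].size()
    too_few = set(sizes[sizes < 3].index)
    if too_few:
        logger.warning("%d children have <3 BMI observations; no curve fit", len(too_few))
    ok = df[~df["child_id"].isin(too_few)]

    if method == "mixed":
        coefs, used = _fit_mixed(ok)
    elif method == "ols":
        coefs, used = _fit_ols(ok), "ols"
    else:
        raise ValueError(f"unknown method {method!r}")

    meta = df.groupby("child_id").agg(
        n_obs=("bmi", "size"), age_min=("exam_age", "min"), age_max=("exam_age", "max")
    )
    out = meta.join(coefs, how="left").reset_index()
    out["method"] = used
    out["flag"] = np.where(out["child_id"].isin(too_few), "too_few", "")
    return out


def _fit_mixed(df: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    a = df["exam_age"].to_numpy()
    # center age for conditioning; coefficients mapped back to raw age below
    a0 = a.mean()
    X = np.column_stack([np.ones_like(a), a - a0, (a - a0) ** 2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                df["bmi"].to_numpy(), X, groups=df["child_id"].to_numpy(), exog_re=X
            )
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.isfinite(res.llf):
            raise RuntimeError("non-finite mixed-model likelihood")
    except Exception as exc:  # noqa: BLE001 - any failure triggers the fallback
        logger.warning("mixed-effects fit failed (%s); falling back to per-child OLS", exc)
        return _fit_ols(df), "ols-fallback"

    fe = np.asarray(res.fe_params)
    rows = {}
    for cid, re_vals in res.random_effects.items():
        c = fe + np.asarray(re_vals)
        rows[cid] = _uncenter(c, a0)
    coefs = pd.DataFrame.from_dict(rows, orient="index", columns=["b0", "b1", "b2"])
    coefs.index.name = "child_id"
    return coefs, "mixed"


def _uncenter(c: np.ndarray, a0: float) -> np.ndarray:
    """Map coefficients of b0 + b1 (a - a0) + b2 (a - a0)^2 to raw age."""
    b0 = c[0] - c[1] * a0 + c[2] * a0**2
    b1 = c[1] - 2.0 * c[2] * a0
    return np.array([b0, b1, c[2]])


def _fit_ols(df: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for cid, sub in df.groupby("child_id"):
        a = sub["exam_age"].to_numpy()
        X = np.column_stack([np.ones_like(a), a, a**2])
        beta, *_ = np.linalg.lstsq(X, sub["bmi"].to_numpy(), rcond=None)
        rows[cid] = beta
    coefs = pd.DataFrame.from_dict(rows, orient="index", columns=["b0", "b1", "b2"])
    coefs.index.name = "child_id"
    return coefs


def ar_age(
    b0: float,
    b1: float,
    b2: float,
    age_window: tuple[float, float] = DEFAULT_AGE_WINDOW,
) -> float:
    """Age of the BMI nadir for one quadratic curve, or NaN when absent.

    The vertex -b1/(2 b2) is an AR only for convex curves (b2 > 0) with the
    vertex inside ``age_window``; otherwise the derivative has no zero in
    range and the child has no adiposity rebound to report.
    """
    if not np.isfinite(b2) or b2 <= 0:
        return np.nan
    v = -b1 / (2.0 * b2)
    lo, hi = age_window
    if not (lo <= v <= hi):
        return np.nan
    return float(v)


def adiposity_rebound(
    curves: pd.DataFrame, age_window: tuple[float, float] = DEFAULT_AGE_WINDOW
) -> pd.DataFrame:
    """Attach ar_age, late_ar and an extrapolation flag to fitted curves."""
    out = curves.copy()
    out["ar_age"] = [
        ar_age(r.b0, r.b1, r.b2, age_window) for r in out.itertuples()
    ]
    out["late_ar"] = out["ar_age"].ge(LATE_AR_THRESHOLD).fillna(False)
    if "age_min" in out.columns:
        out["extrapolated"] = out["ar_age"].notna() & (out["ar_age"] < out["age_min"])
    return out


def late_ar_rate(results: pd.DataFrame) -> float:
    """Share of children flagged late-AR (nadir at or after age 7)."""
    if "late_ar" not in results.columns:
        raise KeyError("run adiposity_rebound first")
    if len(results) == 0:
        raise ValueError("no children in results")
    return float(results["late_ar"].mean())
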