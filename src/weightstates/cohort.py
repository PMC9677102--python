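"""Loading, validation and per-child derived features for longitudinal
height/weight panel data.

One row per child per examination: child id, sex (girl/boy), area
(urban/semi-urban), exam age in decimal years (or exam + birth dates),
height in cm, weight in kg.  Derived per record: the analysis time scale
``t`` (years since the child's first examination), BMI, and annualized
height/weight increments (AHI, AWI) over each following interval; per child:
the initial BMI at cohort entry.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import compute_bmi

logger = logging.getLogger(__name__)

REQUIRED = ["child_id", "sex", "exam_age", "height", "weight"]
SEX_VALUES = {"girl", "boy"}
AREA_VALUES = {"urban", "semi-urban"}
AGE_RANGE = (3.0, 20.0)

#: Days per year used to turn (exam date - birth date) into decimal age.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CohortDataset:
    """Validated longitudinal panel, sorted by (child, time).

    ``df`` has one row per examination with at least the columns
    child_id, sex, area, exam_age, height, weight, bmi, t; ``state``,
    ``ahi``/``awi`` and ``initial_bmi`` appear after classification and
    :func:`compute_increments`.  ``dropped`` reports rejected rows with a
    reason per row.
    """

    df: pd.DataFrame
    dropped: pd.DataFrame | None = None

    @property
    def n_children(self) -> int:
        return self.df["child_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.df)

    def child(self, child_id) -> pd.DataFrame:
        return self.df[self.df["child_id"] == child_id]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _ages_from_dates(df: pd.DataFrame, exam_col: str, birth_col: str) -> pd.Series:
    exam = pd.to_datetime(df[exam_col], format="ISO8601")
    birth = pd.to_datetime(df[birth_col], format="ISO8601")
    return (exam - birth).dt.days / DAYS_PER_YEAR


def load_panel(
    path: str | Path | pd.DataFrame,
    schema: dict[str, str] | None = None,
    complete_case: bool = True,
    strict: bool = False,
    sep: str | None = None,
) -> CohortDataset:
    """Read and validate a delimited panel file (or a prebuilt DataFrame).

    Parameters
    ----------
    schema
        Mapping from standard names (child_id, sex, area, exam_age, height,
        weight — or exam_date and birth_date in place of exam_age) to the
        file's column names.  Identity mapping by default.
    complete_case
        Drop children observed at fewer waves than the cohort maximum,
        mirroring complete-case analysis (the default for the model, which
        nevertheless tolerates unequal intervals when this is off).
    strict
        Raise on invalid rows (naming the child) instead of dropping them
        into the ``dropped`` report.

    Raises
    ------
    KeyError
        If a required column is missing after applying the schema.
    """
    if isinstance(path, pd.DataFrame):
        raw = path.copy()
    else:
        raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})

    if "exam_age" not in raw.columns:
        if {"exam_date", "birth_date"} <= set(raw.columns):
            raw["exam_age"] = _ages_from_dates(raw, "exam_date", "birth_date")
        else:
            raise KeyError("need either an exam_age column or exam_date + birth_date")
    missing = [c for c in REQUIRED if c not in raw.columns]
    if missing:
        raise KeyError(f"panel file missing required columns: {missing}")
    if "area" not in raw.columns:
        raw["area"] = "urban"

    drops: list[pd.DataFrame] = []

    def reject(mask: pd.Series, reason: str) -> None:
        nonlocal raw
        if not mask.any():
            return
        bad = raw[mask].copy()
        bad["reason"] = [
            f"{reason} (child {cid})" for cid in bad["child_id"].astype(str)
        ]
        if strict:
            raise ValueError(bad["reason"].iloc[0])
        for msg in bad["reason"].unique():
            logger.warning("rejected record(s): %s", msg)
        drops.append(bad)
        raw = raw[~mask]

    reject(~raw["sex"].isin(SEX_VALUES), "invalid sex value")
    reject(~raw["area"].isin(AREA_VALUES), "invalid area value")
    reject((raw["height"] <= 0) | raw["height"].isna(), "non-positive or missing height")
    reject((raw["weight"] <= 0) | raw["weight"].isna(), "non-positive or missing weight")
    reject(
        (raw["exam_age"] < AGE_RANGE[0]) | (raw["exam_age"] > AGE_RANGE[1]) | raw["exam_age"].isna(),
        f"exam age outside [{AGE_RANGE[0]}, {AGE_RANGE[1]}]",
    )

    raw = raw.sort_values(["child_id", "exam_age"], kind="stable")
    dup = raw.duplicated(subset=["child_id", "exam_age"], keep="first")
    reject(dup, "duplicate exam age within child")

    if complete_case and len(raw):
        waves = raw.groupby("child_id")["exam_age"].size()
        full = waves.max()
        incomplete = waves[waves < full].index
        if len(incomplete):
            logger.info(
                "complete-case filter: excluding %d children with < %d waves",
                len(incomplete),
                full,
            )
            drops.append(
                raw[raw["child_id"].isin(incomplete)].assign(reason="incomplete follow-up")
            )
            raw = raw[~raw["child_id"].isin(incomplete)]

    raw = raw.reset_index(drop=True)
    raw["t"] = raw["exam_age"] - raw.groupby("child_id")["exam_age"].transform("first")
    raw["bmi"] = compute_bmi(raw["weight"].to_numpy(), raw["height"].to_numpy())
    raw["initial_bmi"] = raw.groupby("child_id")["bmi"].transform("first")

    dropped = pd.concat(drops, ignore_index=True) if drops else None
    return CohortDataset(df=raw, dropped=dropped)


def compute_increments(ds: CohortDataset) -> CohortDataset:
    """Annualized height/weight increments per interval.

    AHI = (height change)/(time change) in cm/year, attached to the record
    that *starts* the interval; likewise AWI in kg/year.  The last record of
    each child has no following interval, so its increments are missing.
    Annualizing by the actual interval keeps unequal spacing meaningful.
    """
    df = ds.df.sort_values(["child_id", "t"], kind="stable").copy()
    single = df.groupby("child_id")["t"].transform("size") == 1
    if single.any():
        logger.warning(
            "%d children have a single record; no increments computed",
            df.loc[single, "child_id"].nunique(),
        )
    g = df.groupby("child_id", sort=False)
    dt = g["t"].shift(-1) - df["t"]
    df["ahi"] = (g["height"].shift(-1) - df["height"]) / dt
    df["awi"] = (g["weight"].shift(-1) - df["weight"]) / dt
    return dataclasses.replace(ds, df=df)


def count_transitions(ds: CohortDataset) -> np.ndarray:
    """3x3 matrix of consecutive observed state pairs (row = from, col = to).

    Counts *observed* pairs, so a child seen normal then obese a year later
    contributes to the (1,3) cell even though the underlying process must
    have passed through overweight between the examinations.
    """
    df = ds.df
    if "state" not in df.columns:
        raise ValueError("states must be assigned before counting transitions")
    df = df.sort_values(["child_id", "t"], kind="stable")
    nxt = df.groupby("child_id", sort=False)["state"].shift(-1)
    ok = nxt.notna()
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (df.loc[ok, "state"].astype(int) - 1, nxt[ok].astype(int) - 1), 1)
    return counts


def baseline_summary(ds: CohortDataset) -> pd.DataFrame:
    """Baseline (first-wave) characteristics by sex with two-group tests.

    Categorical rows report n (%) per group and a chi-square p-value;
    continuous rows report median (IQR) and a Mann-Whitney p-value.
    Groups with no children are marked absent rather than erroring.
    """
    base = ds.df[ds.df["t"] == 0]
    if base.empty:
        raise ValueError("no baseline wave (t == 0) in dataset")
    girls = base[base["sex"] == "girl"]
    boys = base[base["sex"] == "boy"]

    rows = []

    def cat_row(name: str, col: str) -> None:
        levels = sorted(base[col].dropna().unique())
        tab = pd.crosstab(base[col], base["sex"])
        p = np.nan
        if tab.shape == (len(levels), 2) and len(levels) > 1 and (tab.to_numpy() > 0).all():
            p = stats.chi2_contingency(tab)[1]
        for lev in levels:
            rows.append(
                {
                    "characteristic": f"{name}: {lev}",
                    "all": f"{(base[col] == lev).sum()} ({100 * (base[col] == lev).mean():.1f})",
                    "girls": _cat_cell(girls, col, lev),
                    "boys": _cat_cell(boys, col, lev),
                    "p": p,
                }
            )

    def num_row(name: str, col: str) -> None:
        if col not in base.columns:
            return
        x, y = girls[col].dropna(), boys[col].dropna()
        p = np.nan
        if len(x) and len(y):
            p = stats.mannwhitneyu(x, y, alternative="two-sided")[1]
        rows.append(
            {
                "characteristic": name,
                "all": _med_iqr(base[col]),
                "girls": _med_iqr(girls[col]) if len(x) else "absent",
                "boys": _med_iqr(boys[col]) if len(y) else "absent",
                "p": p,
            }
        )

    rows.append(
        {
            "characteristic": "n",
            "all": str(len(base)),
            "girls": str(len(girls)) if len(girls) else "absent",
            "boys": str(len(boys)) if len(boys) else "absent",
            "p": np.nan,
        }
    )
    cat_row("sex", "sex")
    if "state" in base.columns:
        cat_row("baseline weight status", "state")
    cat_row("area", "area")
    if "late_ar" in base.columns:
        cat_row("late adiposity rebound", "late_ar")
    num_row("age (year)", "exam_age")
    num_row("height (cm)", "height")
    num_row("weight (kg)", "weight")
    num_row("BMI (kg/m2)", "bmi")
    if "ahi" in base.columns:
        num_row("AHI (cm/year)", "ahi")
        num_row("AWI (kg/year)", "awi")
    return pd.DataFrame(rows)


def _cat_cell(group: pd.DataFrame, col: str, lev) -> str:
    if group.empty:
        return "absent"
    n = (group[col] == lev).sum()
    return f"{n} ({100 * n / len(group):.1f})"


def _med_iqr(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "absent"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q3 - q1:.1f})"
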