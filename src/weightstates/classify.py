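"""BMI computation and weight-status classification against age- and
sex-specific cutoff tables.

A cutoff table holds, per sex and half-open age bracket ``[age_lo, age_hi)``,
an overweight threshold ``c_ow`` and an obesity threshold ``c_ob`` (kg/m²).
Classification is inclusive upward: a BMI exactly at a threshold falls in the
heavier class, the usual convention for growth references.

Official growth-reference values (WHO, China Obesity Task Force, ...) are
supplied by the user as config; the tables bundled under ``data/`` are
synthetic fixtures with plausible shapes, for tests and simulation only.
Mixed standards (e.g. one reference below age 7 and another above, a common
source of heterogeneity in school-age cohorts) are supported simply by
concatenating brackets from both sources in one table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SEXES = ("girl", "boy")
COLUMNS = ["sex", "age_lo", "age_hi", "c_ow", "c_ob"]


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight in kg and height in cm."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    out = weight / (height / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CutoffTable:
    """Age- and sex-indexed BMI thresholds for overweight and obesity."""

    entries: pd.DataFrame  # columns sex, age_lo, age_hi, c_ow, c_ob
    provenance: str = "custom"

    def __post_init__(self) -> None:
        df = self.entries
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cutoff table missing columns: {sorted(missing)}")
        bad = df[df["c_ow"] >= df["c_ob"]]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"overweight cutoff must be below obesity cutoff "
                f"(sex={row['sex']}, ages [{row['age_lo']}, {row['age_hi']}))"
            )
        for sex, sub in df.groupby("sex"):
            sub = sub.sort_values("age_lo")
            lo = sub["age_lo"].to_numpy()
            hi = sub["age_hi"].to_numpy()
            if np.any(hi <= lo):
                raise ValueError(f"empty age bracket for sex={sex}")
            gaps = lo[1:] - hi[:-1]
            if np.any(gaps > 1e-9):
                i = int(np.argmax(gaps > 1e-9))
                raise ValueError(
                    f"gap in age coverage for sex={sex}: [{hi[i]}, {lo[i + 1]})"
                )
            if np.any(gaps < -1e-9):
                i = int(np.argmax(gaps < -1e-9))
                raise ValueError(
                    f"overlapping age brackets for sex={sex} around age {lo[i + 1]}"
                )
        object.__setattr__(self, "entries", df.sort_values(["sex", "age_lo"]).reset_index(drop=True))

    def age_range(self, sex: str) -> tuple[float, float]:
        sub = self.entries[self.entries["sex"] == sex]
        if sub.empty:
            raise KeyError(f"no brackets for sex={sex!r}")
        return float(sub["age_lo"].min()), float(sub["age_hi"].max())

    def lookup(self, sex: str, age: float) -> tuple[float, float]:
        """(c_ow, c_ob) for this sex at this exam age; no extrapolation."""
        sub = self.entries[self.entries["sex"] == sex]
        hit = sub[(sub["age_lo"] <= age) & (age < sub["age_hi"])]
        if hit.empty:
            lo, hi = self.age_range(sex) if not sub.empty else (np.nan, np.nan)
            raise ValueError(
                f"age {age:.2f} not covered by cutoff table for sex={sex!r} "
                f"(covered range [{lo}, {hi}))"
            )
        row = hit.iloc[0]
        return float(row["c_ow"]), float(row["c_ob"])


def classify_status(bmi: float, age: float, sex: str, table: CutoffTable) -> int:
    """Weight state from BMI: 1 normal, 2 overweight, 3 obese.

    Thresholds are inclusive upward: ``bmi == c_ow`` is overweight,
    ``bmi == c_ob`` is obese.
    """
    c_ow, c_ob = table.lookup(sex, age)
    if bmi >= c_ob:
        return 3
    if bmi >= c_ow:
        return 2
    return 1


def assign_states(ds, table: CutoffTable):
    """Attach ``bmi`` (if absent) and ``state`` columns to a cohort dataset."""
    df = ds.df if hasattr(ds, "df") else ds
    if "bmi" not in df.columns:
        df = df.assign(bmi=compute_bmi(df["weight"].to_numpy(), df["height"].to_numpy()))
    df = df.assign(
        state=[
            classify_status(b, a, s, table)
            for b, a, s in zip(df["bmi"], df["exam_age"], df["sex"])
        ]
    )
    if hasattr(ds, "df"):
        import dataclasses

        return dataclasses.replace(ds, df=df)
    return df


def load_cutoffs(path: str | Path, provenance: str | None = None) -> CutoffTable:
    """Read a cutoff table from YAML (list of entry mappings) or CSV.

    Columns/keys: sex, age_lo, age_hi, c_ow, c_ob; ages in years, brackets
    half-open ``[age_lo, age_hi)``.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text())
        if isinstance(raw, dict):
            provenance = provenance or raw.get("provenance", "custom")
            raw = raw["entries"]
        df = pd.DataFrame(raw)
    else:
        df = pd.read_csv(path)
    return CutoffTable(df[COLUMNS].astype({c: float for c in COLUMNS[1:]}), provenance or "custom")


def bundled_cutoffs(name: str = "who_style") -> CutoffTable:
    """A bundled *synthetic* fixture table: ``who_style`` or ``cotf_style``.

    These are illustrative shapes, not official reference values.
    """
    ref = resources.files("weightstates.data").joinpath(f"cutoffs_{name}.yaml")
    raw = yaml.safe_load(ref.read_text())
    return CutoffTable(pd.DataFrame(raw["entries"]), raw.get("provenance", name))
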