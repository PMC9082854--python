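"""Household expenditure survey records: schema, IO, truncation and restrictions.

The unit of observation is a household. Each record carries the monthly
premium spent on voluntary private health insurance (VPHI; 0 when none is
reported), monthly household income, head-of-household characteristics,
household composition, and the number of members (the instrument for the
premium equation).

Records live in a pandas DataFrame with canonical column names; the
:class:`AnalysisSample` bundles the derived estimation arrays (participation
indicator, observed log premium, covariate dummies, log income, instrument).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, ValidationError

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

AGE_GROUPS = ["<30", "30-39", "40-49", ">=50"]
EDUCATION_LEVELS = ["less-than-HS", "HS", "tertiary"]
INCOME_LEVELS = ["low", "middle", "middle-to-high"]
REGIONS = ["Atlantico", "Bogota", "New departments", "Eastern", "Pacific"]
OCCUPATIONS = ["private", "public", "employer", "other"]

CATEGORICALS: dict[str, list[str]] = {
    "head_age_group": AGE_GROUPS,
    "head_education": EDUCATION_LEVELS,
    "income_level": INCOME_LEVELS,
    "region": REGIONS,
    "head_occupation": OCCUPATIONS,
}

#: reference level dropped when expanding each categorical into dummies
REFERENCE_LEVELS: dict[str, str] = {
    "head_age_group": "<30",
    "head_education": "less-than-HS",
    "income_level": "low",
    "region": "Atlantico",
    "head_occupation": "other",
}

FLAGS = [
    "head_male",
    "member_over_65",
    "child_under_5",
    "head_works",
    "contributory_member",
    "head_informal",
]

COLUMNS = [
    "household_id",
    "premium_expenditure",
    "household_income",
    "head_male",
    "head_age_group",
    "head_education",
    "member_over_65",
    "child_under_5",
    "income_level",
    "region",
    "head_works",
    "contributory_member",
    "head_informal",
    "head_occupation",
    "n_members",
]

#: categoricals entering the participation-equation controls X
#: (head gender, age group, education, member over 65, income level, region)
_X_CATEGORICALS = ["head_age_group", "head_education", "income_level", "region"]
_X_FLAGS = ["head_male", "member_over_65"]

RESTRICTIONS = ("all", "non_informal", "middle_income_up")


def validate_records(df: pd.DataFrame, on_invalid: str = "error") -> pd.DataFrame:
    """Validate a canonical-column DataFrame of household records.

    Parameters
    ----------
    df
        Table with all canonical :data:`COLUMNS`.
    on_invalid
        ``"error"`` raises :class:`ValidationError` naming the first bad rows;
        ``"drop"`` silently removes them.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    if on_invalid not in ("error", "drop"):
        raise ConfigurationError(f"unknown on_invalid policy {on_invalid!r}")

    df = df[COLUMNS].copy()
    problems: list[tuple[int, str]] = []

    num = {}
    for col in ["premium_expenditure", "household_income", "n_members"]:
        num[col] = pd.to_numeric(df[col], errors="coerce")
    bad = num["premium_expenditure"].isna() | (num["premium_expenditure"] < 0)
    problems += [(i, "premium_expenditure must be >= 0") for i in df.index[bad]]
    bad = num["household_income"].isna() | (num["household_income"] <= 0)
    problems += [(i, "household_income must be > 0") for i in df.index[bad]]
    bad = num["n_members"].isna() | (num["n_members"] < 1)
    problems += [(i, "n_members must be >= 1") for i in df.index[bad]]

    for col in FLAGS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        problems += [(i, f"{col} must be 0/1") for i in df.index[bad]]
    for col, levels in CATEGORICALS.items():
        bad = ~df[col].astype(str).isin(levels)
        problems += [(i, f"{col} not in {levels}") for i in df.index[bad]]

    if problems:
        if on_invalid == "error":
            shown = "; ".join(f"row {i}: {msg}" for i, msg in problems[:5])
            raise ValidationError(
                f"{len(problems)} invalid value(s): {shown}"
                + ("; ..." if len(problems) > 5 else "")
            )
        bad_rows = sorted({i for i, _ in problems})
        df = df.drop(index=bad_rows)

    out = df.copy()
    out["premium_expenditure"] = pd.to_numeric(out["premium_expenditure"]).astype(float)
    out["household_income"] = pd.to_numeric(out["household_income"]).astype(float)
    out["n_members"] = pd.to_numeric(out["n_members"]).astype(int)
    for col in FLAGS:
        out[col] = pd.to_numeric(out[col]).astype(np.int8)
    for col, levels in CATEGORICALS.items():
        out[col] = pd.Categorical(out[col].astype(str), categories=levels)
    return out.reset_index(drop=True)


def read_survey(
    path,
    column_map: Mapping[str, str] | None = None,
    on_invalid: str = "error",
) -> pd.DataFrame:
    """Read a household survey CSV and return validated canonical records.

    ``column_map`` maps canonical names to the CSV's column names, so
    arbitrary survey exports can be adapted; omitted entries default to the
    canonical name itself.
    """
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise ConfigurationError(
                f"column {src!r} (mapped from {canon!r}) not found in {path}"
            )
        rename[src] = canon
    return validate_records(raw.rename(columns=rename), on_invalid=on_invalid)


def convert_currency(amount, rate: float):
    """Convert COP amounts to USD at ``rate`` COP per USD (e.g. 2951)."""
    if not np.isfinite(rate) or rate <= 0:
        raise DomainError(f"exchange rate must be positive, got {rate}")
    return np.asarray(amount, dtype=float) / rate if np.ndim(amount) else float(amount) / rate


# --------------------------------------------------------------------------
# Analysis sample
# --------------------------------------------------------------------------


def _build_dummies(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Expand the control covariates into a full-rank dummy matrix.

    Reference levels (and levels absent from ``df``) are dropped; a flag or
    dummy that is constant in ``df`` is dropped as well so that X plus an
    intercept stays full rank under sample restrictions.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for col in _X_FLAGS:
        v = df[col].to_numpy(dtype=float)
        if v.size and v.min() != v.max():
            cols.append(v)
            names.append(col)
    for col in _X_CATEGORICALS:
        present = [lv for lv in CATEGORICALS[col] if (df[col] == lv).any()]
        ref = REFERENCE_LEVELS[col]
        if ref not in present and present:
            ref = present[0]
        for lv in present:
            if lv == ref:
                continue
            cols.append((df[col] == lv).to_numpy(dtype=float))
            names.append(f"{col}[{lv}]")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


@dataclasses.dataclass
class AnalysisSample:
    """Estimation-ready arrays for one (possibly restricted) sample.

    ``ln_premium`` is NaN exactly where ``vphi == 0``; ``Z`` stacks the
    controls ``X`` with log income and the instrument (household size).
    """

    df: pd.DataFrame
    threshold: float
    vphi: np.ndarray
    ln_premium: np.ndarray
    X: np.ndarray
    x_names: list[str]
    ln_income: np.ndarray
    instrument: np.ndarray

    @property
    def n(self) -> int:
        return len(self.vphi)

    @property
    def n_purchasers(self) -> int:
        return int(self.vphi.sum())

    @property
    def Z(self) -> np.ndarray:
        return np.column_stack([self.X, self.ln_income, self.instrument])

    @property
    def z_names(self) -> list[str]:
        return [*self.x_names, "ln_income", "n_members"]

    def take(self, idx: np.ndarray) -> "AnalysisSample":
        """Row subset by positional index, keeping the dummy layout fixed.

        Used for bootstrap resampling; columns that become constant in the
        subsample are left in place (the estimators detect rank problems).
        """
        idx = np.asarray(idx)
        return AnalysisSample(
            df=self.df.iloc[idx].reset_index(drop=True),
            threshold=self.threshold,
            vphi=self.vphi[idx],
            ln_premium=self.ln_premium[idx],
            X=self.X[idx],
            x_names=list(self.x_names),
            ln_income=self.ln_income[idx],
            instrument=self.instrument[idx],
        )


def derive_vphi_indicator(records: pd.DataFrame, threshold: float) -> AnalysisSample:
    """Apply the truncation rule and build the analysis sample.

    Households spending at least ``threshold`` USD/month are participants
    (``vphi = 1``); households reporting zero are non-participants; positive
    amounts strictly below the threshold are treated as misclassified
    non-premium insurance payments and the rows are dropped altogether.
    With ``threshold = 0`` nothing is dropped and any positive expenditure
    counts as participation.
    """
    if not np.isfinite(threshold) or threshold < 0:
        raise DomainError(f"threshold must be >= 0, got {threshold}")
    premium = records["premium_expenditure"].to_numpy(dtype=float)
    if threshold > 0:
        keep = (premium == 0) | (premium >= threshold)
    else:
        keep = np.ones(len(records), dtype=bool)
    df = records.loc[keep].reset_index(drop=True)
    premium = premium[keep]
    vphi = (premium > 0) & (premium >= threshold)
    vphi = vphi.astype(np.int8)
    ln_premium = np.where(vphi == 1, np.log(np.where(premium > 0, premium, np.nan)), np.nan)

    X, x_names = _build_dummies(df)
    return AnalysisSample(
        df=df,
        threshold=float(threshold),
        vphi=vphi,
        ln_premium=ln_premium,
        X=X,
        x_names=x_names,
        ln_income=np.log(df["household_income"].to_numpy(dtype=float)),
        instrument=df["n_members"].to_numpy(dtype=float),
    )


def restrict_sample(sample: AnalysisSample, restriction: str) -> AnalysisSample:
    """Apply one of the reporting-sample restrictions.

    ``non_informal`` drops households whose head works an informal job;
    ``middle_income_up`` keeps middle and middle-to-high income households;
    ``all`` is the identity.
    """
    if restriction not in RESTRICTIONS:
        raise ConfigurationError(
            f"unknown restriction {restriction!r}; expected one of {RESTRICTIONS}"
        )
    if restriction == "all":
        return sample
    if restriction == "non_informal":
        keep = sample.df["head_informal"].to_numpy() == 0
    else:
        keep = sample.df["income_level"].isin(["middle", "middle-to-high"]).to_numpy()
    df = sample.df.loc[keep].reset_index(drop=True)
    X, x_names = _build_dummies(df)  # rebuild: levels may vanish under restriction
    return AnalysisSample(
        df=df,
        threshold=sample.threshold,
        vphi=sample.vphi[keep],
        ln_premium=sample.ln_premium[keep],
        X=X,
        x_names=x_names,
        ln_income=sample.ln_income[keep],
        instrument=sample.instrument[keep],
    )


# --------------------------------------------------------------------------
# Descriptives
# --------------------------------------------------------------------------

_DESCRIPTIVE_NUMERIC = ["household_income", "premium_expenditure", "n_members"]


def _group_stats(df: pd.DataFrame, premium_stats: bool) -> dict[str, tuple[float, float]]:
    stats: dict[str, tuple[float, float]] = {}
    for col in _DESCRIPTIVE_NUMERIC:
        if col == "premium_expenditure" and not premium_stats:
            stats[col] = (np.nan, np.nan)
            continue
        v = df[col].to_numpy(dtype=float)
        stats[col] = (v.mean(), v.std(ddof=1)) if v.size else (np.nan, np.nan)
    for col in FLAGS:
        v = df[col].to_numpy(dtype=float)
        stats[col] = (v.mean(), v.std(ddof=1)) if v.size else (np.nan, np.nan)
    for col, levels in CATEGORICALS.items():
        for lv in levels:
            v = (df[col] == lv).to_numpy(dtype=float)
            stats[f"{col}[{lv}]"] = (v.mean(), v.std(ddof=1)) if v.size else (np.nan, np.nan)
    return stats


def descriptive_table(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per-group means and SDs mirroring the survey descriptives layout.

    Groups: non-participants (zero reported premium), all reporting
    households (no truncation) and reporting households at or above the
    truncation threshold. An empty group gets count 0 and blank statistics.
    """
    if len(records) == 0:
        raise ValidationError("descriptive_table requires a non-empty table")
    if threshold < 0:
        raise DomainError(f"threshold must be >= 0, got {threshold}")
    premium = records["premium_expenditure"].to_numpy(dtype=float)
    groups = {
        "non_participants": records.loc[premium == 0],
        "users_no_truncation": records.loc[premium > 0],
        "users_truncated": records.loc[(premium > 0) & (premium >= threshold)],
    }
    rows = {}
    for name, sub in groups.items():
        stats = _group_stats(sub, premium_stats=name != "non_participants")
        rows[f"{name}_mean"] = {k: v[0] for k, v in stats.items()}
        rows[f"{name}_sd"] = {k: v[1] for k, v in stats.items()}
    table = pd.DataFrame(rows)
    counts = {f"{name}_mean": float(len(sub)) for name, sub in groups.items()}
    counts.update({f"{name}_sd": np.nan for name in groups})
    table.loc["observations"] = pd.Series(counts)
    table.index.name = "variable"
    return table
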