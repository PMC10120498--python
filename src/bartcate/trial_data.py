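"""Trial data model: covariate schema, table I/O, standardization, arm summaries.

The schema is fixed to the design of a two-arm dexamethasone dosing trial in
severe COVID-19: a binary treatment arm (1 = 12 mg/d, 0 = 6 mg/d), two
outcomes — days alive without life support through day 90 (DAWOLS, an integer
in [0, 90], possibly missing) and 90-day mortality (binary, possibly
missing) — and ten pre-selected baseline effect modifiers.  Covariates are
assumed complete; a missing covariate value is a data error, whereas missing
outcomes are tolerated and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaEntry",
    "CovariateSchema",
    "StandardizationParams",
    "TrialDataset",
    "default_schema",
    "load_trial_table",
    "write_trial_table",
    "standardize_covariates",
    "destandardize_value",
    "destandardize_dataset",
    "summarize_by_arm",
]

RESP_LEVELS = ("open", "niv_cpap", "imv")

OUTCOME_COLUMNS = ("dawols90", "mort90")


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    kind: str  # "continuous" | "binary" | "categorical"
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical covariate {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for {self.name!r}")


@dataclass(frozen=True)
class CovariateSchema:
    entries: tuple[SchemaEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def entry(self, name: str) -> SchemaEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def continuous(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.kind == "continuous")

    @property
    def binary(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.kind == "binary")

    @property
    def categorical(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.kind == "categorical")


def default_schema() -> CovariateSchema:
    """The ten pre-selected baseline effect modifiers.

    Respiratory support is the only categorical covariate, with three ordered
    levels: open oxygen system < non-invasive ventilation / continuous CPAP <
    invasive mechanical ventilation.
    """
    return CovariateSchema(
        entries=(
            SchemaEntry("age", "continuous"),
            SchemaEntry("limitations", "binary"),
            SchemaEntry("resp_support", "categorical", RESP_LEVELS),
            SchemaEntry("il6_inhibitor", "binary"),
            SchemaEntry("dexa_3to4d", "binary"),
            SchemaEntry("weight", "continuous"),
            SchemaEntry("diabetes", "binary"),
            SchemaEntry("ihd_hf", "binary"),
            SchemaEntry("copd", "binary"),
            SchemaEntry("immunosuppression", "binary"),
        )
    )


@dataclass(frozen=True)
class StandardizationParams:
    """Per-covariate centering/scaling constants in original units."""

    center: Mapping[str, float]
    scale: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, s in self.scale.items():
            if not (s > 0):
                raise ValueError(f"non-positive scale for covariate {name!r}")


@dataclass
class TrialDataset:
    """A per-patient trial table.

    ``df`` holds one row per patient with columns ``id``, ``arm``,
    ``dawols90``, ``mort90`` (outcomes use pandas nullable dtypes so missing
    outcomes are representable) and one column per schema covariate.
    """

    schema: CovariateSchema
    df: pd.DataFrame
    standardized: bool = False
    std_params: StandardizationParams | None = None

    def __post_init__(self) -> None:
        if self.standardized and self.std_params is None:
            raise ValueError("standardized dataset requires std_params")
        if self.df["id"].duplicated().any():
            dupes = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate record ids: {dupes[:5]}")

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.schema, self.df.copy(), self.standardized, self.std_params)

    # ---- modeling helpers -------------------------------------------------

    def design_matrix(self, include_arm: bool = True) -> tuple[np.ndarray, list[str]]:
        """Numeric design matrix for tree-ensemble modeling.

        Continuous covariates enter as-is (standardized if the dataset is),
        binaries as 0/1, and the respiratory-support factor as two indicator
        contrasts against the open-system reference level.  The treatment arm,
        when included, is the last column (named ``z``).
        """
        cols: list[np.ndarray] = []
        names: list[str] = []
        for e in self.schema.entries:
            if e.kind == "categorical":
                vals = self.df[e.name].to_numpy()
                for lev in e.levels[1:]:
                    cols.append((vals == lev).astype(float))
                    names.append(f"{e.name}={lev}")
            else:
                cols.append(self.df[e.name].to_numpy(dtype=float))
                names.append(e.name)
        if include_arm:
            cols.append(self.df["arm"].to_numpy(dtype=float))
            names.append("z")
        return np.column_stack(cols), names

    def outcome_vector(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (mask of non-missing rows, float outcome values on those rows)."""
        col = self.df[outcome]
        mask = col.notna().to_numpy()
        return mask, col[mask].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# I/O


def _err(row: int | None, column: str, message: str) -> ValueError:
    where = f"column {column!r}" if row is None else f"row {row}, column {column!r}"
    return ValueError(f"invalid trial table ({where}): {message}")


def load_trial_table(
    path,
    schema: CovariateSchema | None = None,
    *,
    missing_token: str = "NA",
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> TrialDataset:
    """Read and validate a delimited per-patient trial table.

    Outcomes may carry the ``missing_token``; covariates may not.  Validation
    errors name the offending row (0-based data row) and column.  ``column_map``
    maps the canonical names to the file's column names.
    """
    schema = schema or default_schema()
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = dict(column_map or {})
    required = ["id", "arm", *OUTCOME_COLUMNS, *schema.names]
    rename = {}
    for canon in required:
        src = colmap.get(canon, canon)
        if src not in raw.columns:
            raise _err(None, src, "column missing from file")
        rename[src] = canon
    raw = raw.rename(columns=rename)

    out = pd.DataFrame()
    out["id"] = raw["id"].astype(str)
    if out["id"].duplicated().any():
        row = int(np.flatnonzero(out["id"].duplicated())[0])
        raise _err(row, "id", f"duplicate id {out['id'].iloc[row]!r}")

    def parse_numeric(col: str, allow_missing: bool, integer: bool):
        vals = []
        for i, v in enumerate(raw[col]):
            v = v.strip()
            if v == missing_token or v == "":
                if allow_missing:
                    vals.append(None)
                    continue
                raise _err(i, col, "missing value not allowed")
            try:
                vals.append(int(v) if integer else float(v))
            except ValueError:
                raise _err(i, col, f"cannot parse {v!r}") from None
        return vals

    arm = parse_numeric("arm", False, True)
    for i, a in enumerate(arm):
        if a not in (0, 1):
            raise _err(i, "arm", f"arm must be 0 or 1, got {a}")
    out["arm"] = pd.array(arm, dtype="int64")

    daw = parse_numeric("dawols90", True, True)
    for i, d in enumerate(daw):
        if d is not None and not (0 <= d <= 90):
            raise _err(i, "dawols90", f"value {d} outside [0, 90]")
    out["dawols90"] = pd.array(daw, dtype="Int64")

    mort = parse_numeric("mort90", True, True)
    for i, m in enumerate(mort):
        if m is not None and m not in (0, 1):
            raise _err(i, "mort90", f"value {m} not in {{0, 1}}")
    out["mort90"] = pd.array(mort, dtype="Int64")

    for e in schema.entries:
        if e.kind == "categorical":
            vals = []
            for i, v in enumerate(raw[e.name]):
                v = v.strip()
                if v == missing_token or v == "":
                    raise _err(i, e.name, "missing covariate value")
                if v not in e.levels:
                    raise _err(i, e.name, f"unknown level {v!r} (expected one of {e.levels})")
                vals.append(v)
            out[e.name] = pd.Categorical(vals, categories=list(e.levels))
        else:
            vals = parse_numeric(e.name, False, False)
            if e.kind == "binary":
                for i, v in enumerate(vals):
                    if v not in (0.0, 1.0):
                        raise _err(i, e.name, f"binary covariate must be 0/1, got {v}")
            out[e.name] = np.asarray(vals, dtype=float)

    return TrialDataset(schema=schema, df=out)


def write_trial_table(ds: TrialDataset, path, *, missing_token: str = "NA", sep: str = ",") -> None:
    """Write a dataset in the same dialect :func:`load_trial_table` reads.

    Standardized datasets are back-translated to original units first so the
    file always holds original-scale values.
    """
    if ds.standardized:
        ds = destandardize_dataset(ds)
    df = ds.df.copy()
    for col in OUTCOME_COLUMNS:
        df[col] = df[col].astype(object)
        df.loc[df[col].isna(), col] = missing_token
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Standardization


def standardize_covariates(ds: TrialDataset) -> TrialDataset:
    """Center and scale continuous covariates to mean 0, sd 1 (ddof=1).

    Binary and categorical covariates are untouched.  The fitted centers and
    scales are recorded so cutpoints and values can later be back-translated
    to original units.
    """
    if ds.standardized:
        raise ValueError("dataset is already standardized")
    df = ds.df.copy()
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    for name in ds.schema.continuous:
        x = df[name].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if not (sd > 0):
            raise ValueError(f"zero-variance continuous covariate {name!r} cannot be standardized")
        df[name] = (x - mu) / sd
        center[name] = mu
        scale[name] = sd
    return TrialDataset(
        schema=ds.schema,
        df=df,
        standardized=True,
        std_params=StandardizationParams(center=center, scale=scale),
    )


def destandardize_value(name: str, x: float, params: StandardizationParams) -> float:
    """Back-translate a standardized value to original units: x*scale + center."""
    if name not in params.center:
        raise KeyError(f"{name!r} is not a standardized covariate")
    return x * params.scale[name] + params.center[name]


def destandardize_dataset(ds: TrialDataset) -> TrialDataset:
    if not ds.standardized:
        raise ValueError("dataset is not standardized")
    assert ds.std_params is not None
    df = ds.df.copy()
    for name in ds.std_params.center:
        df[name] = df[name].to_numpy(dtype=float) * ds.std_params.scale[name] + ds.std_params.center[name]
    return TrialDataset(schema=ds.schema, df=df, standardized=False, std_params=None)


# ---------------------------------------------------------------------------
# Arm summaries


def _median_iqr(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_by_arm(ds: TrialDataset) -> dict:
    """Arm-wise summary table: medians/IQRs for continuous variables and
    DAWOLS, counts and percentages for binaries/levels, deaths/total for
    mortality.  Missing outcomes are excluded from their own summary and the
    non-missing denominator is reported.

    Percentages are ``round(100*count/denominator, 1)``.
    """
    if ds.n == 0:
        raise ValueError("dataset is empty")
    if ds.standardized:
        ds = destandardize_dataset(ds)
    out: dict = {}
    for arm, label in ((1, "12mg"), (0, "6mg")):
        sub = ds.df[ds.df["arm"] == arm]
        n = len(sub)
        s: dict = {"n": n}
        for e in ds.schema.entries:
            if e.kind == "continuous":
                s[e.name] = _median_iqr(sub[e.name].to_numpy(dtype=float))
            elif e.kind == "binary":
                cnt = int(sub[e.name].sum())
                s[e.name] = {"count": cnt, "pct": round(100.0 * cnt / n, 1) if n else math.nan}
            else:
                lv = {}
                for lev in e.levels:
                    cnt = int((sub[e.name] == lev).sum())
                    lv[lev] = {"count": cnt, "pct": round(100.0 * cnt / n, 1) if n else math.nan}
                s[e.name] = lv
        daw = sub["dawols90"].dropna().to_numpy(dtype=float)
        s["dawols90"] = {**(_median_iqr(daw) if len(daw) else {"median": math.nan, "q1": math.nan, "q3": math.nan}),
                         "n_nonmissing": int(len(daw))}
        mort = sub["mort90"].dropna().to_numpy(dtype=float)
        deaths = int(mort.sum()) if len(mort) else 0
        s["mort90"] = {
            "deaths": deaths,
            "total": int(len(mort)),
            "pct": round(100.0 * deaths / len(mort), 1) if len(mort) else math.nan,
        }
        out[label] = s
    return out


def summary_to_frame(summary: dict) -> pd.DataFrame:
    """Flatten a :func:`summarize_by_arm` result to a two-column table."""
    rows = []
    for arm, s in summary.items():
        for key, val in s.items():
            if isinstance(val, dict) and "median" in val:
                rows.append((arm, key, f"{val['median']:g} ({val['q1']:g}, {val['q3']:g})"))
            elif isinstance(val, dict) and "count" in val:
                rows.append((arm, key, f"{val['count']} ({val['pct']:g}%)"))
            elif isinstance(val, dict) and "deaths" in val:
                rows.append((arm, key, f"{val['deaths']}/{val['total']} ({val['pct']:g}%)"))
            elif isinstance(val, dict):
                for lev, lv in val.items():
                    rows.append((arm, f"{key}={lev}", f"{lv['count']} ({lv['pct']:g}%)"))
            else:
                rows.append((arm, key, str(val)))
    return pd.DataFrame(rows, columns=["arm", "variable", "summary"])
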