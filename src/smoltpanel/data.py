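"""Shared data model and tabular I/O.

The package works on three tables:

* a Ct matrix (qPCR cycle-threshold values, assays x samples), wrapped in
  :class:`CtMatrix` which tracks whether the values are raw Ct, linearized
  relative quantities, or calibrated log2 relative expression;
* per-sample metadata (group, set, month ordinal, environment, physiology
  covariates, optional smolt-status label), kept as a plain
  :class:`pandas.DataFrame` validated by :func:`validate_sample_meta`;
* per-assay annotation (gene symbol, predicted direction during
  smoltification, functional group, amplification efficiency, pass flag),
  also a validated DataFrame.

All files are plain CSV.  A bundled catalogue of the published candidate
smoltification biomarkers for gill tissue (45 candidate assays, of which 8
failed amplification-efficiency screening, leaving 37) ships with the
package; see :func:`load_candidate_assays`.  Measured amplification
efficiencies were never published for those assays, so the catalogue has no
efficiency column — efficiencies are user inputs (or come from the
synthetic generator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "read_ct_table",
    "write_ct_table",
    "read_assay_table",
    "read_sample_meta",
    "validate_sample_meta",
    "validate_assay_table",
    "load_candidate_assays",
    "load_housekeeping_assays",
    "write_results",
    "read_results",
]

VALUE_KINDS = ("ct", "linear", "log2rel")
GROUPS = ("coho", "sockeye", "chinook_stream", "chinook_ocean", "other")
ENVIRONMENTS = ("FW", "SW")
STATUSES = ("pre_smolt", "smolt", "de_smolt")

#: valid raw Ct range in PCR cycles
CT_RANGE = (0.0, 50.0)
#: valid amplification-efficiency range (per-cycle fold amplification)
EFFICIENCY_RANGE = (1.0, 2.2)

META_COLUMNS = ("sample_id", "group", "set_label", "month_index", "environment")


def _check_unique(labels: Iterable[str], what: str) -> list[str]:
    labels = [str(x).strip() for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class CtMatrix:
    """Assays x samples expression matrix with a declared value kind.

    Parameters
    ----------
    data:
        DataFrame indexed by assay id with sample ids as columns.  Missing
        wells stay NaN; they are never imputed.
    value_kind:
        ``"ct"`` (raw cycle thresholds, each value in [0, 50]),
        ``"linear"`` (efficiency-linearized relative quantities in (0, 1]),
        or ``"log2rel"`` (calibrated log2 relative expression).
    """

    data: pd.DataFrame
    value_kind: str = "ct"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        df = pd.DataFrame(self.data).copy()
        df.index = pd.Index(_check_unique(df.index, "assay"), name="assay_id")
        df.columns = pd.Index(_check_unique(df.columns, "sample"), name="sample_id")
        df = df.astype(float)
        if self.value_kind == "ct":
            vals = df.to_numpy()
            bad = (vals < CT_RANGE[0]) | (vals > CT_RANGE[1])
            if np.any(bad & ~np.isnan(vals)):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValueError(
                    f"Ct value out of range [0, 50] at assay {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}: {vals[i, j]}"
                )
        self.data = df

    @property
    def assay_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Transpose to the (n_samples, n_features) layout estimators use."""
        return self.data.T

    def subset_assays(self, assay_ids: Iterable[str]) -> "CtMatrix":
        missing = [a for a in assay_ids if a not in self.data.index]
        if missing:
            raise KeyError(f"assays not in matrix: {missing}")
        return CtMatrix(self.data.loc[list(assay_ids)], self.value_kind)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CtMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return CtMatrix(self.data[list(sample_ids)], self.value_kind)

    def drop_sparse_assays(self, max_missing_frac: float = 0.5) -> "CtMatrix":
        """Drop assays missing in more than ``max_missing_frac`` of samples.

        Failed wells are retained as NaN through normalization; an assay is
        only removed (with a warning) once more than half its wells are
        missing, mirroring the 50% missingness filter used upstream in the
        discovery analyses.
        """
        frac = self.data.isna().mean(axis=1)
        bad = frac[frac > max_missing_frac]
        if len(bad):
            warnings.warn(
                f"dropping {len(bad)} assay(s) missing in >"
                f"{max_missing_frac:.0%} of samples: {list(bad.index)}",
                stacklevel=2,
            )
            return CtMatrix(self.data.drop(index=bad.index), self.value_kind)
        return self


def read_ct_table(path, dialect: str = "auto", value_kind: str = "ct") -> CtMatrix:
    """Read a Ct table in wide (assays x samples) or long form.

    Wide form: first column holds assay ids, remaining columns are samples.
    Long form: exactly three columns ``assay,sample,ct`` (any header names),
    one row per well.  ``dialect="auto"`` treats a 3-column file whose first
    two columns are non-numeric as long form.
    """
    import csv

    with open(path, newline="") as f:
        header = next(csv.reader(f), [])
    seen: set[str] = set()
    for col in (h.strip() for h in header[1:]):
        if col in seen:
            raise ValueError(f"duplicate sample column: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"empty table: {path}")
    if dialect == "auto":
        dialect = "long" if df.shape[1] == 3 else "wide"
    if dialect == "long":
        if df.shape[1] != 3:
            raise ValueError("long dialect requires exactly 3 columns")
        a, s, v = df.columns
        df[a] = df[a].str.strip()
        df[s] = df[s].str.strip()
        dup = df.duplicated(subset=[a, s])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(f"duplicate (assay, sample) pair: ({r[a]!r}, {r[s]!r})")
        vals = _numeric(df[v], path)
        wide = (
            pd.DataFrame({a: df[a], s: df[s], "value": vals})
            .pivot(index=a, columns=s, values="value")
        )
        # preserve first-appearance order from the file
        wide = wide.loc[df[a].drop_duplicates(), df[s].drop_duplicates()]
        return CtMatrix(wide, value_kind)
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    first = df.columns[0]
    assay_ids = df[first].str.strip()
    body = df.drop(columns=first)
    mat = pd.DataFrame(index=assay_ids, columns=body.columns, dtype=float)
    for col in body.columns:
        mat[col] = _numeric(body[col], path).to_numpy()
    return CtMatrix(mat, value_kind)


def _numeric(col: pd.Series, path) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        i = bad.idxmax()
        raise ValueError(
            f"non-numeric Ct value {col[i]!r} in column {col.name!r}, "
            f"row {i} of {path}"
        )
    return out.astype(float)


def write_ct_table(ct: CtMatrix, path) -> None:
    ct.data.to_csv(path)


def validate_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an assay annotation table."""
    df = df.copy()
    if "assay_id" not in df.columns:
        raise ValueError("assay table requires an 'assay_id' column")
    df["assay_id"] = df["assay_id"].astype(str).str.strip()
    _check_unique(df["assay_id"], "assay")
    if "predicted_direction" in df.columns:
        dirs = df["predicted_direction"].fillna("").astype(str).str.strip()
        bad = ~dirs.isin(["up", "down", ""])
        if bad.any():
            raise ValueError(
                f"predicted_direction must be 'up', 'down' or empty; got "
                f"{sorted(dirs[bad].unique())}"
            )
        df["predicted_direction"] = dirs.replace("", pd.NA)
    if "efficiency" in df.columns:
        eff = pd.to_numeric(df["efficiency"], errors="raise").astype(float)
        present = eff.notna()
        lo, hi = EFFICIENCY_RANGE
        bad = present & ~((eff > lo) & (eff <= hi))
        if bad.any():
            i = bad.idxmax()
            raise ValueError(
                f"amplification efficiency out of range ({lo}, {hi}] for assay "
                f"{df['assay_id'][i]!r}: {eff[i]}"
            )
        df["efficiency"] = eff
    if "passed_efficiency" in df.columns:
        df["passed_efficiency"] = df["passed_efficiency"].map(_to_bool)
    else:
        df["passed_efficiency"] = True
    if "is_housekeeping" in df.columns:
        df["is_housekeeping"] = df["is_housekeeping"].map(_to_bool)
    else:
        df["is_housekeeping"] = False
    return df.set_index("assay_id", drop=False)


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f", "", "nan"):
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean flag")


def read_assay_table(path) -> pd.DataFrame:
    """Read a per-assay annotation CSV and validate it.

    An empty file (header only, or zero bytes) yields an empty table with a
    warning rather than an error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["assay_id"])
    if len(df) == 0:
        warnings.warn(f"assay table {path} is empty", stacklevel=2)
        if "assay_id" not in df.columns:
            df["assay_id"] = pd.Series(dtype=str)
    return validate_assay_table(df)


def load_candidate_assays() -> pd.DataFrame:
    """Bundled catalogue of the 45 published candidate smoltification assays.

    Columns: gene symbol/name, predicted direction in smolts, functional
    group, and the published efficiency pass/fail screening flag (8 assays
    failed, leaving 37 usable: 20 up, 17 down).
    """
    path = resources.files("smoltpanel").joinpath("resources/candidate_assays.csv")
    with path.open() as f:
        return validate_assay_table(pd.read_csv(f))


def load_housekeeping_assays() -> pd.DataFrame:
    """The three candidate reference (housekeeping) assays used on each chip."""
    path = resources.files("smoltpanel").joinpath("resources/housekeeping_assays.csv")
    with path.open() as f:
        return validate_assay_table(pd.read_csv(f))


def validate_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Validate per-fish metadata.

    Required columns: ``sample_id, group, set_label, month_index,
    environment``.  Optional: ``nka_activity`` (umol ADP / mg protein / h,
    > 0), ``length_cm`` (> 0), ``mass_g`` (> 0), ``condition``,
    ``smolt_status`` (pre_smolt / smolt / de_smolt, training samples only),
    ``is_calibrator`` plus any numeric appearance covariates.
    """
    df = df.copy()
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    _check_unique(df["sample_id"], "sample")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise ValueError(f"unknown group labels: {sorted(df['group'][bad].unique())}")
    df["month_index"] = pd.to_numeric(df["month_index"]).astype(int)
    if (df["month_index"] < 0).any():
        raise ValueError("month_index must be non-negative")
    bad = ~df["environment"].isin(ENVIRONMENTS)
    if bad.any():
        raise ValueError(
            f"environment must be FW or SW; got {sorted(df['environment'][bad].unique())}"
        )
    for col in ("nka_activity", "length_cm", "mass_g"):
        if col in df.columns:
            v = pd.to_numeric(df[col], errors="raise").astype(float)
            if (v[v.notna()] <= 0).any():
                raise ValueError(f"{col} must be > 0 where present")
            df[col] = v
    if "smolt_status" in df.columns:
        st = df["smolt_status"].fillna("").astype(str).str.strip()
        bad = ~st.isin(list(STATUSES) + [""])
        if bad.any():
            raise ValueError(f"unknown smolt_status: {sorted(st[bad].unique())}")
        df["smolt_status"] = st.replace("", pd.NA)
    if "is_calibrator" not in df.columns:
        df["is_calibrator"] = False
    else:
        df["is_calibrator"] = df["is_calibrator"].map(_to_bool)
    return df.set_index("sample_id", drop=False)


def read_sample_meta(path) -> pd.DataFrame:
    return validate_sample_meta(pd.read_csv(path))


# ---------------------------------------------------------------------------
# result serialization
#
# every pipeline product is a DataFrame with documented columns; round trips
# are lossless for labels/integers and better than 1e-12 relative for reals.

_FLOAT_FMT = "%.17g"


def write_results(obj, path) -> None:
    """Write a pipeline result table (ranking, panel, thresholds, statuses).

    Accepts any DataFrame-like product.  Floats are written with 17
    significant digits so a read-back reproduces them exactly.
    """
    df = _as_frame(obj)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _as_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.reset_index(drop=True)
    if isinstance(obj, pd.Series):
        return obj.to_frame().T.reset_index(drop=True)
    if hasattr(obj, "to_frame"):
        out = obj.to_frame()
        return out.reset_index(drop=True) if isinstance(out, pd.DataFrame) else out
    raise TypeError(
        f"cannot serialize object of type {type(obj).__name__}; expected a "
        "DataFrame or an object with .to_frame()"
    )
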