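"""Reading, writing and pre-processing of rhythm measurement tables.

The universal in-memory container is :class:`MeasurementSet`, a thin wrapper
around a long-format :class:`pandas.DataFrame` with columns

    ``test``        group label (non-empty string)
    ``x``           time in hours (real)
    ``y``           measured value (real)
    ``individual``  optional individual/replicate label (string or missing)

Two on-disk dialects are supported, in CSV or XLSX:

* **long** — exactly the columns above (``individual`` optional);
* **wide** — first column is an entity id, remaining column headers are times
  in hours; duplicated time headers are read as replicates.

Times are plain real-valued hours throughout; no date parsing is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

LONG_COLUMNS = ("test", "x", "y")

__all__ = [
    "MeasurementSet",
    "read_measurements",
    "write_measurements",
    "write_results",
    "read_results",
    "remove_outliers",
]


@dataclass
class MeasurementSet:
    """A validated long-format collection of rhythm measurements."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if "individual" not in df.columns:
            df["individual"] = pd.Series([None] * len(df), dtype=object)
        df = df[["test", "x", "y", "individual"]].reset_index(drop=True)
        for col in ("x", "y"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rows = list(df.index[bad][:5])
                raise ParseError(f"non-numeric {col!r} value(s) at row(s) {rows}")
            if coerced.isna().any() or not np.isfinite(coerced.to_numpy(float)).all():
                rows = list(df.index[~np.isfinite(coerced.to_numpy(float))][:5])
                raise ParseError(f"non-finite {col!r} value(s) at row(s) {rows}")
            df[col] = coerced.astype(float)
        df["test"] = df["test"].astype(str)
        if (df["test"].str.len() == 0).any():
            raise ValidationError("group labels must be non-empty strings")
        self.data = df

    # -- accessors ---------------------------------------------------------

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.data["test"]))

    def __len__(self) -> int:
        return len(self.data)

    def group(self, label: str) -> pd.DataFrame:
        sub = self.data[self.data["test"] == label]
        if sub.empty:
            raise ValidationError(f"unknown group {label!r}")
        return sub.reset_index(drop=True)

    def group_arrays(self, label: str):
        """Return ``(t, y, individual)`` arrays for one group.

        ``individual`` is ``None`` when no record of the group carries an id.
        """
        sub = self.group(label)
        t = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        ind = sub["individual"].to_numpy(object)
        if all(i is None or (isinstance(i, float) and math.isnan(i)) for i in ind):
            return t, y, None
        return t, y, np.asarray([str(i) for i in ind], dtype=object)

    @classmethod
    def from_records(cls, records) -> "MeasurementSet":
        """Build from an iterable of (test, x, y[, individual]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 3:
                rec = rec + (None,)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=["test", "x", "y", "individual"]))

    def to_dataframe(self) -> pd.DataFrame:
        return self.data.copy()


def _read_table(path: Path, header):
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, header=header)
    return pd.read_csv(path, header=header)


def read_measurements(path, dialect: str = "long") -> MeasurementSet:
    """Read a measurement file in the ``long`` or ``wide`` dialect.

    Wide input is melted to long form; duplicated time headers become
    replicate records of the same (group, time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        df = _read_table(path, header=0)
        df.columns = [str(c).strip() for c in df.columns]
        return MeasurementSet(df)
    if dialect != "wide":
        raise ValidationError(f"unknown dialect {dialect!r}")
    raw = _read_table(path, header=None)
    if raw.shape[1] < 2:
        raise SchemaError("wide input needs an id column plus >=1 time column")
    header = raw.iloc[0]
    try:
        times = [float(h) for h in header.iloc[1:]]
    except (TypeError, ValueError) as exc:
        raise SchemaError(
            "wide-format column headers after the id column must be numeric hours"
        ) from exc
    rows = []
    for _, row in raw.iloc[1:].iterrows():
        label = str(row.iloc[0])
        for t, v in zip(times, row.iloc[1:]):
            if pd.isna(v):
                continue
            rows.append((label, t, v, None))
    return MeasurementSet(
        pd.DataFrame(rows, columns=["test", "x", "y", "individual"])
    )


def write_measurements(mset: MeasurementSet, path) -> Path:
    """Write a measurement set in the long dialect (CSV or XLSX by suffix)."""
    path = Path(path)
    df = mset.to_dataframe()
    if df["individual"].isna().all():
        df = df.drop(columns="individual")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def write_results(table: pd.DataFrame, path, format: str | None = None) -> Path:
    """Write a results table to CSV or XLSX.

    Round-trips through :func:`read_results` preserve values to at least six
    decimal places.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty results table")
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "xlsx":
        table.to_excel(path, index=False)
    elif fmt == "csv":
        table.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return path


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    return _read_table(path, header=0)


def remove_outliers(
    mset: MeasurementSet, threshold: float = 5.0
) -> tuple[MeasurementSet, dict[str, int]]:
    """Drop per-group outliers by robust z-score.

    For each group the score is ``|y - median| / MAD`` (MAD unscaled).  When
    the MAD is zero, values equal to the median score 0 and any deviating
    value scores infinity, so an isolated wild point in an otherwise constant
    group is still removed; a warning is emitted in that degenerate case.

    Returns the filtered set and the number of removals per group.
    """
    if not (threshold > 0):
        raise ValidationError("threshold must be positive")
    df = mset.to_dataframe()
    keep = np.ones(len(df), dtype=bool)
    removed: dict[str, int] = {}
    for label, sub in df.groupby("test", sort=False):
        if len(sub) < 4:
            raise ValidationError(
                f"group {label!r} has fewer than 4 records; outlier screening needs >=4"
            )
        y = sub["y"].to_numpy(float)
        med = np.median(y)
        mad = np.median(np.abs(y - med))
        if mad == 0:
            warnings.warn(
                f"group {label!r}: MAD is zero; only exact departures from the "
                "median can be flagged",
                stacklevel=2,
            )
            z = np.where(y == med, 0.0, np.inf)
        else:
            z = np.abs(y - med) / mad
        drop = z > threshold
        keep[sub.index[drop]] = False
        removed[str(label)] = int(drop.sum())
    return MeasurementSet(df[keep]), removed
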