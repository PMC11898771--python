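"""Per-cell feature tables and experiment designs.

The central data structure of the package is the :class:`FeatureTable`: one row
per segmented cell, a small set of metadata columns identifying where the cell
came from (image, growth condition, replicate day, timepoint), and an arbitrary
number of real-valued morphological / intensity feature columns.  Tables are
read from and written to CSV/TSV in either a ``plain`` dialect (metadata columns
named directly) or a ``cellprofiler`` dialect (``ImageNumber``/``ObjectNumber``
object keys and ``Metadata_``-prefixed annotation columns, as produced by
CellProfiler per-object exports).

Validation rules applied on construction:

* ``cell_id`` is unique within each ``image_id``;
* each ``image_id`` maps to exactly one ``(condition, replicate_day,
  timepoint_h)`` triple;
* feature columns are finite reals — rows containing any non-finite feature
  value are dropped and counted in the :class:`LoadReport`.
"""

from __future__ import annotations

import dataclasses
import numbers
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "EmptyInputError",
    "LoadReport",
    "FeatureTable",
    "ConditionDesign",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "apply_design",
]

#: metadata columns every table must carry
MANDATORY_METADATA = ("cell_id", "image_id", "condition")
#: metadata columns that are recognized but may be absent
OPTIONAL_METADATA = ("replicate_day", "timepoint_h")
#: any column with this prefix is treated as metadata, never as a feature
METADATA_PREFIX = "Metadata_"

# CellProfiler per-object export column names -> our metadata names
_CELLPROFILER_RENAMES = {
    "ImageNumber": "image_id",
    "ObjectNumber": "cell_id",
    "Metadata_Condition": "condition",
    "Metadata_ReplicateDay": "replicate_day",
    "Metadata_Timepoint": "timepoint_h",
}


class SchemaError(ValueError):
    """A table violates the per-cell data model (missing/inconsistent columns)."""


class EmptyInputError(ValueError):
    """A file or table contains no data rows."""


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Bookkeeping for one table load."""

    n_rows_read: int
    n_rows_kept: int
    drop_count: int  # rows dropped because a feature value was non-finite

    def __post_init__(self) -> None:
        assert self.n_rows_kept + self.drop_count == self.n_rows_read


@dataclasses.dataclass(frozen=True)
class ConditionDesign:
    """Design annotation for one growth condition."""

    condition: str
    serum_code: str | None = None
    medium_code: str | None = None
    is_control: bool = False


def _is_metadata_column(name: str) -> bool:
    return (
        name in MANDATORY_METADATA
        or name in OPTIONAL_METADATA
        or name.startswith(METADATA_PREFIX)
    )


class FeatureTable:
    """Validated per-cell feature table.

    Parameters
    ----------
    data:
        One row per cell.  Must contain the mandatory metadata columns;
        every numeric non-metadata column is treated as a feature.
    feature_columns:
        Explicit feature column list; by default all numeric non-metadata
        columns.
    drop_nonfinite:
        Drop (and count) rows where any feature value is NaN/inf.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_columns: "list[str] | tuple[str, ...] | None" = None,
        drop_nonfinite: bool = True,
    ):
        if data.shape[0] == 0:
            raise EmptyInputError("feature table has zero data rows")
        for col in MANDATORY_METADATA:
            if col not in data.columns:
                raise SchemaError(f"missing mandatory metadata column {col!r}")

        data = data.copy()
        if feature_columns is None:
            feature_columns = [
                c
                for c in data.columns
                if not _is_metadata_column(c)
                and pd.api.types.is_numeric_dtype(data[c])
            ]
        else:
            missing = [c for c in feature_columns if c not in data.columns]
            if missing:
                raise SchemaError(f"feature columns not in table: {missing}")
        if not feature_columns:
            raise SchemaError("feature table must have at least one feature column")

        n_read = len(data)
        feats = data[list(feature_columns)].astype(float)
        finite = np.isfinite(feats.to_numpy()).all(axis=1)
        if drop_nonfinite:
            data = data.loc[finite].reset_index(drop=True)
            drop_count = int(n_read - len(data))
        else:
            if not finite.all():
                raise SchemaError("non-finite feature values present")
            drop_count = 0
        if data.shape[0] == 0:
            raise EmptyInputError("all rows dropped as non-finite")
        data[list(feature_columns)] = data[list(feature_columns)].astype(float)

        self.data = data
        self.feature_columns: tuple[str, ...] = tuple(feature_columns)
        self.load_report = LoadReport(n_read, len(data), drop_count)
        self._validate_keys()

    # ------------------------------------------------------------------ keys
    def _validate_keys(self) -> None:
        dup = self.data.duplicated(subset=["image_id", "cell_id"])
        if dup.any():
            bad = self.data.loc[dup, ["image_id", "cell_id"]].iloc[0]
            raise SchemaError(
                f"duplicate cell_id {bad['cell_id']!r} within image {bad['image_id']!r}"
            )
        meta_cols = ["condition"] + [
            c for c in OPTIONAL_METADATA if c in self.data.columns
        ]
        n_unique = self.data.groupby("image_id", sort=False)[meta_cols].nunique()
        bad = n_unique[(n_unique > 1).any(axis=1)]
        if len(bad):
            raise SchemaError(
                f"image_id {bad.index[0]!r} maps to more than one "
                f"(condition, replicate_day, timepoint_h)"
            )

    # ------------------------------------------------------------ properties
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.data["condition"]))

    @property
    def images(self) -> list:
        return list(dict.fromkeys(self.data["image_id"]))

    def features(self) -> pd.DataFrame:
        """The numeric feature block (copy)."""
        return self.data[list(self.feature_columns)].copy()

    def subset(self, mask) -> "FeatureTable":
        """New table with rows selected by a boolean mask (features unchanged)."""
        return FeatureTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            feature_columns=self.feature_columns,
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.feature_columns == other.feature_columns
            and self.data.shape == other.data.shape
            and bool(self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True)))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FeatureTable: {self.n_cells} cells, "
            f"{len(self.feature_columns)} features, "
            f"{len(self.conditions)} conditions>"
        )


# ---------------------------------------------------------------------- I/O
def read_feature_table(path, dialect: str = "plain") -> FeatureTable:
    """Read a per-cell table from CSV/TSV.

    ``dialect="cellprofiler"`` renames CellProfiler object/metadata columns
    (``ImageNumber`` → ``image_id``, ``ObjectNumber`` → ``cell_id``,
    ``Metadata_Condition`` → ``condition``, ...) before validation; other
    ``Metadata_*`` columns are kept as non-feature metadata.  The delimiter
    (comma or tab) is auto-detected.  The returned table carries a
    ``load_report`` with the count of rows dropped for non-finite features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("plain", "cellprofiler"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no data rows")
    if dialect == "cellprofiler":
        df = df.rename(
            columns={k: v for k, v in _CELLPROFILER_RENAMES.items() if k in df.columns}
        )
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as comma-separated text; round-trips losslessly."""
    if not isinstance(table, FeatureTable):
        raise TypeError("expected a FeatureTable")
    path = Path(path)
    table.data.to_csv(path, index=False)


# ------------------------------------------------------------------- design
def read_design(path) -> pd.DataFrame:
    """Read an experiment-design file (YAML mapping image_id -> annotations).

    Each entry may set ``condition`` (required), ``replicate_day``,
    ``timepoint_h`` and ``is_control``.  Returns a data frame indexed by
    image_id.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise SchemaError("design file must be a non-empty mapping of image_id")
    rows = []
    for image_id, entry in raw.items():
        if not isinstance(entry, dict) or "condition" not in entry:
            raise SchemaError(f"design entry for {image_id!r} lacks 'condition'")
        rows.append(
            {
                "image_id": image_id,
                "condition": entry["condition"],
                "replicate_day": entry.get("replicate_day"),
                "timepoint_h": entry.get("timepoint_h"),
                "is_control": bool(entry.get("is_control", False)),
            }
        )
    return pd.DataFrame(rows).set_index("image_id")


def apply_design(data: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Annotate a raw per-cell frame (with image_id) from a design frame."""
    missing = set(data["image_id"]) - set(design.index)
    if missing:
        raise SchemaError(f"images not present in design: {sorted(missing)[:5]}")
    merged = data.merge(
        design.reset_index(), on="image_id", how="left", suffixes=("", "_design")
    )
    return merged


def validate_control_design(designs: "list[ConditionDesign]", replicate_days=None) -> None:
    """Check that exactly one condition is flagged as control."""
    n_control = sum(d.is_control for d in designs)
    if n_control != 1:
        raise SchemaError(
            f"control normalization requires exactly one is_control condition, got {n_control}"
        )
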