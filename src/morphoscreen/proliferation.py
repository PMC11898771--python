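"""Cell-count aggregation, growth rates and control normalization.

Counting runs on QC-passed per-cell tables: cells are counted per image, then
averaged per (condition, replicate day, timepoint).  Because wells plated on
different days vary in seeding density and baseline growth, counts are
normalized to a same-day control well (cells grown without a medium change)
before averaging across days.  The growth rate of a well is the fold increase
g = N(72 h) / N(24 h); for cross-condition heatmaps g is mapped onto a
normalized scale ĝ = log2(g) / mean(log2 g) anchored so that ĝ = 0 means no
growth (g = 1) and ĝ = 1 is the average growth rate of the cell line.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_tables import FeatureTable, SchemaError

__all__ = [
    "aggregate_counts",
    "records_from_well_counts",
    "growth_metrics",
    "normalize_growth_scale",
]


class UndefinedScaleError(ValueError):
    """The normalized growth scale is undefined (no net growth anywhere)."""


def aggregate_counts(table: FeatureTable) -> pd.DataFrame:
    """Mean per-image cell count per (condition, replicate_day, timepoint_h).

    One row per group with ``mean_count``, ``n_images`` and a ``low_n`` flag
    when only a single image contributed.
    """
    df = table.data
    for col in ("replicate_day", "timepoint_h"):
        if col not in df.columns or df[col].isna().any():
            raise SchemaError(f"aggregate_counts requires complete {col!r} metadata")
    per_image = (
        df.groupby(["condition", "replicate_day", "timepoint_h", "image_id"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    out = (
        per_image.groupby(["condition", "replicate_day", "timepoint_h"], sort=False)["count"]
        .agg(mean_count="mean", n_images="size")
        .reset_index()
    )
    out["low_n"] = out["n_images"] < 2
    if out["low_n"].any():
        warnings.warn("some (condition, day, timepoint) groups have a single image")
    return out


def records_from_well_counts(wells: pd.DataFrame) -> pd.DataFrame:
    """Growth records from a per-well count table.

    Expects columns condition, replicate_day, count_24h, count_72h and
    is_control; control wells provide the same-day reference counts.  Returns
    one row per non-control (condition, replicate_day) with the well counts
    and the same-day control means attached.
    """
    required = {"condition", "replicate_day", "count_24h", "count_72h", "is_control"}
    missing = required - set(wells.columns)
    if missing:
        raise SchemaError(f"well count table lacks columns: {sorted(missing)}")
    ctrl = (
        wells[wells["is_control"]]
        .groupby("replicate_day")[["count_24h", "count_72h"]]
        .mean()
        .rename(columns={"count_24h": "control_count_24h", "count_72h": "control_count_72h"})
    )
    if ctrl.empty:
        raise SchemaError("no control wells present")
    cond = (
        wells[~wells["is_control"]]
        .groupby(["condition", "replicate_day"], sort=False)[["count_24h", "count_72h"]]
        .mean()
        .reset_index()
    )
    out = cond.merge(ctrl, on="replicate_day", how="left")
    if out[["control_count_24h", "control_count_72h"]].isna().any().any():
        bad = out.loc[out["control_count_24h"].isna(), "replicate_day"].iloc[0]
        raise SchemaError(f"replicate day {bad!r} has no control well")
    return out


def growth_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Growth fold, log2 fold and control-relative ratios per condition.

    ``records`` carries one row per (condition, replicate_day) with
    count_24h/count_72h and the same-day control counts (see
    :func:`records_from_well_counts`).  Per day: g = count_72h / count_24h and
    control-relative ratios count / control_count at each timepoint (day
    effects cancel in these ratios); metrics are then averaged across days.
    """
    req = {"condition", "replicate_day", "count_24h", "count_72h",
           "control_count_24h", "control_count_72h"}
    missing = req - set(records.columns)
    if missing:
        raise SchemaError(f"growth records lack columns: {sorted(missing)}")
    for col in ("count_24h", "count_72h", "control_count_24h", "control_count_72h"):
        bad = records[records[col] <= 0]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"nonpositive {col} for condition {r['condition']!r}, "
                f"day {r['replicate_day']!r}"
            )
    per_day = records.copy()
    per_day["g"] = per_day["count_72h"] / per_day["count_24h"]
    per_day["rel_24h"] = per_day["count_24h"] / per_day["control_count_24h"]
    per_day["rel_72h"] = per_day["count_72h"] / per_day["control_count_72h"]
    out = (
        per_day.groupby("condition", sort=False)
        .agg(
            g=("g", "mean"),
            g_sd=("g", "std"),
            rel_24h=("rel_24h", "mean"),
            rel_72h=("rel_72h", "mean"),
            n_days=("g", "size"),
        )
        .reset_index()
    )
    out["log2_g"] = np.log2(out["g"])
    return out


def normalize_growth_scale(summaries: pd.DataFrame, by: "str | None" = None) -> pd.DataFrame:
    """Attach the normalized growth scale ĝ = log2(g) / mean(log2 g).

    The anchors hold by construction: ĝ = 0 exactly when g = 1 (no growth)
    and the mean of ĝ over conditions is 1 (average growth).  With ``by``
    set (e.g. a cell-line column), normalization runs within each group.
    """
    if "log2_g" not in summaries.columns:
        raise SchemaError("summaries must carry log2_g (see growth_metrics)")
    out = summaries.copy()

    def _norm(grp):
        if len(grp) < 2:
            raise ValueError("normalized growth scale needs >=2 conditions")
        m = grp["log2_g"].mean()
        if m == 0:
            raise UndefinedScaleError("mean log2 growth is zero: scale undefined")
        grp = grp.copy()
        grp["g_hat"] = grp["log2_g"] / m
        return grp

    if by is None:
        return _norm(out)
    return (
        out.groupby(by, sort=False, group_keys=False)[out.columns]
        .apply(_norm)
        .reset_index(drop=True)
    )
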