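"""Image-level quality control.

Before any condition-level statistics, images whose object count or feature
distribution substantially differs from the other images of the same
(condition, timepoint) group are flagged and removed: bad focus, debris or
density artefacts show up as such outliers.  "Substantially differs" is
quantified as a robust z-score — (x − median) / (1.4826·MAD) — exceeding a
threshold (default 3.5, the conventional outlier-labelling cut), applied to
per-image object counts and to per-image feature medians.  When the MAD is
zero the scale falls back to IQR/1.349, and when that is also zero only exact
departures from the median can be flagged.

All flags are retained in per-image reports for audit; the procedure is
idempotent (re-running QC on its own output flags nothing new).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_tables import FeatureTable

__all__ = ["ImageQCReport", "qc_images"]

_MAD_SCALE = 1.4826  # MAD -> SD for a normal distribution
_IQR_SCALE = 1.349


@dataclasses.dataclass
class ImageQCReport:
    image_id: object
    condition: str
    object_count: int
    count_z: float
    max_feature_z: float
    worst_feature: "str | None"
    flags: list
    passed: bool


def robust_z(values: np.ndarray) -> np.ndarray:
    """MAD-based robust z-scores with IQR fallback for degenerate spread."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad > 0:
        scale = _MAD_SCALE * mad
    else:
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        scale = iqr / _IQR_SCALE if iqr > 0 else 0.0
    if scale == 0.0:
        # all-tied spread: only exact departures from the median are scored
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(values == med, 0.0, np.inf * np.sign(values - med))
        return z
    return (values - med) / scale


def qc_images(
    table: FeatureTable,
    count_z_max: float = 3.5,
    feature_z_max: float = 3.5,
    min_images_kept: int = 2,
):
    """Flag and drop outlier images within each (condition, timepoint) group.

    Returns ``(filtered_table, reports)``.  Groups with fewer than three
    images pass untouched (robust statistics are meaningless there) with a
    warning.  If dropping all flagged images would leave a group with fewer
    than ``min_images_kept``, the least-outlying flagged images are kept back
    and a warning is issued.
    """
    df = table.data
    group_cols = ["condition"] + (["timepoint_h"] if "timepoint_h" in df.columns else [])

    per_image = (
        df.groupby("image_id", sort=False)
        .agg(
            condition=("condition", "first"),
            object_count=("cell_id", "size"),
            **({"timepoint_h": ("timepoint_h", "first")} if "timepoint_h" in df.columns else {}),
        )
        .reset_index()
    )
    feat_medians = df.groupby("image_id", sort=False)[list(table.feature_columns)].median()

    reports: list[ImageQCReport] = []
    dropped_images: set = set()
    for _, grp in per_image.groupby(group_cols, sort=False):
        image_ids = list(grp["image_id"])
        counts = grp["object_count"].to_numpy(dtype=float)
        if len(image_ids) < 3:
            warnings.warn(
                f"condition group {grp['condition'].iloc[0]!r} has "
                f"{len(image_ids)} image(s): QC skipped for this group"
            )
            for iid, cnt in zip(image_ids, counts):
                reports.append(
                    ImageQCReport(iid, grp["condition"].iloc[0], int(cnt),
                                  0.0, 0.0, None, ["insufficient_images"], True)
                )
            continue

        cz = robust_z(counts)
        fz = np.vstack(
            [robust_z(feat_medians.loc[image_ids, f].to_numpy()) for f in table.feature_columns]
        )  # features x images
        abs_fz = np.abs(fz)
        worst_idx = abs_fz.argmax(axis=0)

        flagged: list[tuple[float, object]] = []
        for j, iid in enumerate(image_ids):
            flags = []
            if abs(cz[j]) > count_z_max:
                flags.append("object_count_outlier")
            if abs_fz[worst_idx[j], j] > feature_z_max:
                flags.append("feature_distribution_outlier")
            rep = ImageQCReport(
                image_id=iid,
                condition=grp["condition"].iloc[0],
                object_count=int(counts[j]),
                count_z=float(cz[j]),
                max_feature_z=float(abs_fz[worst_idx[j], j]),
                worst_feature=table.feature_columns[worst_idx[j]],
                flags=flags,
                passed=not flags,
            )
            reports.append(rep)
            if flags:
                flagged.append((max(abs(cz[j]), abs_fz[worst_idx[j], j]), iid, rep))

        n_keep = len(image_ids) - len(flagged)
        if flagged and n_keep < min_images_kept:
            # keep back the least-outlying flagged images
            flagged.sort(key=lambda t: t[0])
            n_restore = min_images_kept - n_keep
            for _, iid, rep in flagged[:n_restore]:
                rep.passed = True
                rep.flags.append("kept_to_preserve_min_images")
            flagged = flagged[n_restore:]
            warnings.warn(
                f"QC would leave <{min_images_kept} images for "
                f"{grp['condition'].iloc[0]!r}; kept {n_restore} flagged image(s)"
            )
        dropped_images.update(iid for _, iid, _ in flagged)

    if dropped_images:
        filtered = table.subset(~df["image_id"].isin(dropped_images).to_numpy())
    else:
        filtered = table
    return filtered, reports


def reports_frame(reports) -> pd.DataFrame:
    """Flatten QC reports for CSV export."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "condition": r.condition,
                "object_count": r.object_count,
                "count_z": r.count_z,
                "max_feature_z": r.max_feature_z,
                "worst_feature": r.worst_feature,
                "flags": ";".join(r.flags),
                "passed": r.passed,
            }
            for r in reports
        ]
    )
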