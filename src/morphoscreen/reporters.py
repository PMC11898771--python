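"""Reporter, organelle-stain and viability readouts.

Kinase translocation reporters (KTRs) leave the nucleus when their kinase is
active, so per-cell kinase activity is read as the C/N ratio r: the median
reporter intensity in a cytoplasmic ring (15 px around the nucleus by
default) divided by the median intensity in the nucleus.  Per-image mean
ratios are mapped to a normalized activity a ∈ [0, 1] with an external
calibration (r_min = fully inhibited kinase, r_max = growth-factor-saturated
activity); values outside [0, 1] are clipped and counted.  Because r is a
ratio of intensities from the same image, a is invariant to any global
detector gain.

Organelle stains (e.g. potential-dependent mitochondrial dyes, lysosomal
dyes) are quantified per cell as mean and integrated intensity normalized to
the mean of a control population.  Resazurin viability plates are normalized
between blank wells (0 %) and vehicle-control wells (100 %).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import masks as _masks

__all__ = [
    "CalibrationError",
    "DynamicRangeError",
    "ktr_activity",
    "self_calibration",
    "stimulation_delta",
    "stain_quantify",
    "viability_normalize",
]


class CalibrationError(ValueError):
    """Invalid activity calibration (r_min >= r_max)."""


class DynamicRangeError(ValueError):
    """Plate has no usable dynamic range (vehicle <= blank)."""


def ktr_activity(
    image_set: _masks.ImageSet,
    matched: _masks.MatchedObjects,
    calibration: tuple,
    channel: str = "reporter",
    ring_width: int = 15,
):
    """Per-cell C/N ratios and calibrated activities for one image.

    Returns ``(cells, summary)``: ``cells`` has one row per matched nucleus
    with nucleus/ring medians, ratio r and activity a = clip((r − r_min) /
    (r_max − r_min), 0, 1); ``summary`` holds the per-image mean activity and
    the counts of clipped and dropped cells (cells with zero nucleus median
    cannot define a ratio and are dropped with a reason).
    """
    r_min, r_max = calibration
    if r_min >= r_max:
        raise CalibrationError(f"calibration r_min={r_min} >= r_max={r_max}")
    img = image_set.channel(channel)
    ring = _masks.ring_region(
        image_set.nucleus_mask, ring_width, cell_mask=image_set.cell_mask, matched=matched
    )
    rows, dropped = [], []
    for _, pair in matched.pairs.iterrows():
        nl = int(pair["nucleus_label"])
        nuc_med = float(np.median(img[image_set.nucleus_mask == nl]))
        ring_px = img[ring == nl]
        if nuc_med == 0.0 or ring_px.size == 0:
            dropped.append({"nucleus_label": nl,
                            "reason": "zero_nucleus_median" if nuc_med == 0.0 else "empty_ring"})
            continue
        r = float(np.median(ring_px)) / nuc_med
        a_raw = (r - r_min) / (r_max - r_min)
        rows.append(
            {"nucleus_label": nl, "cell_label": int(pair["cell_label"]),
             "nucleus_median": nuc_med, "ring_median": float(np.median(ring_px)),
             "ratio": r, "activity": float(np.clip(a_raw, 0.0, 1.0)),
             "clipped": not 0.0 <= a_raw <= 1.0}
        )
    cells = pd.DataFrame(
        rows,
        columns=["nucleus_label", "cell_label", "nucleus_median", "ring_median",
                 "ratio", "activity", "clipped"],
    )
    summary = {
        "mean_activity": float(cells["activity"].mean()) if len(cells) else float("nan"),
        "mean_ratio": float(cells["ratio"].mean()) if len(cells) else float("nan"),
        "n_cells": int(len(cells)),
        "n_clipped": int(cells["clipped"].sum()) if len(cells) else 0,
        "n_dropped": len(dropped),
        "dropped": pd.DataFrame(dropped, columns=["nucleus_label", "reason"]),
    }
    return cells, summary


def self_calibration(ratios, percentiles=(2.5, 97.5)) -> tuple:
    """Data-driven (r_min, r_max) from ratio percentiles across an experiment.

    A fallback for when no external calibration (inhibitor floor and
    growth-factor ceiling from a reference experiment) is available; the
    resulting activities are relative to the observed experiment only.
    """
    ratios = np.asarray(ratios, dtype=float)
    lo, hi = np.percentile(ratios, percentiles)
    if lo >= hi:
        raise CalibrationError("degenerate ratio distribution for self-calibration")
    return float(lo), float(hi)


@dataclasses.dataclass(frozen=True)
class StimulationDelta:
    delta: float
    sd: float  # propagated across-image SD; NaN when either arm has 1 image
    mean_stimulated: float
    mean_vehicle: float
    n_stimulated: int
    n_vehicle: int


def stimulation_delta(activity_stimulated, activity_vehicle) -> StimulationDelta:
    """Mean activity change between stimulated and vehicle arms.

    Inputs are per-image mean activities.  Δa = mean(stimulated) −
    mean(vehicle); the dispersion combines the per-arm SDs in quadrature and
    is undefined (NaN, with a warning) when an arm has a single image.
    """
    s = np.asarray(activity_stimulated, dtype=float)
    v = np.asarray(activity_vehicle, dtype=float)
    if s.size == 0 or v.size == 0:
        raise ValueError("both arms must be nonempty")
    delta = float(s.mean() - v.mean())
    if s.size < 2 or v.size < 2:
        warnings.warn("single-image arm: dispersion undefined")
        sd = float("nan")
    else:
        sd = float(np.hypot(s.std(ddof=1), v.std(ddof=1)))
    return StimulationDelta(delta, sd, float(s.mean()), float(v.mean()), s.size, v.size)


def stain_quantify(
    image_set: _masks.ImageSet,
    matched: _masks.MatchedObjects,
    control_reference: pd.DataFrame,
    channel: str,
):
    """Per-cell stain intensities normalized to a control population.

    ``control_reference`` holds per-cell ``mean`` and ``integrated``
    intensities of the same stain measured in control cells; each treated
    cell's statistic is divided by the control population mean of that
    statistic.  Returns one row per matched cell with raw and normalized
    values.
    """
    if len(control_reference) == 0:
        raise ValueError("control reference is empty")
    img = image_set.channel(channel)
    if image_set.cell_mask is None:
        raise _masks.GeometryError("stain quantification requires a cell mask")
    ctrl_mean = float(control_reference["mean"].mean())
    ctrl_integ = float(control_reference["integrated"].mean())
    if ctrl_mean == 0.0 or ctrl_integ == 0.0:
        raise ValueError("control population mean is zero: normalization undefined")
    rows = []
    for _, pair in matched.pairs.iterrows():
        cl = int(pair["cell_label"])
        vals = img[image_set.cell_mask == cl]
        rows.append(
            {"nucleus_label": int(pair["nucleus_label"]), "cell_label": cl,
             "mean": float(vals.mean()), "integrated": float(vals.sum())}
        )
    out = pd.DataFrame(rows)
    out["mean_normalized"] = out["mean"] / ctrl_mean
    out["integrated_normalized"] = out["integrated"] / ctrl_integ
    return out


def viability_normalize(plate: pd.DataFrame) -> pd.DataFrame:
    """Percent viability per well from a resazurin absorbance-shift plate.

    ``plate`` columns: well, role ∈ {treated, vehicle, blank}, raw.  V% =
    100 × (raw − mean blank) / (mean vehicle − mean blank), so blanks map to
    0 % and the vehicle mean to 100 % exactly.
    """
    required = {"well", "role", "raw"}
    if required - set(plate.columns):
        raise ValueError(f"plate table needs columns {sorted(required)}")
    roles = set(plate["role"])
    if "vehicle" not in roles or "blank" not in roles:
        raise ValueError("plate needs at least one vehicle and one blank well")
    blank = float(plate.loc[plate["role"] == "blank", "raw"].mean())
    vehicle = float(plate.loc[plate["role"] == "vehicle", "raw"].mean())
    if vehicle <= blank:
        raise DynamicRangeError(
            f"vehicle mean ({vehicle}) must exceed blank mean ({blank})"
        )
    out = plate.copy()
    out["viability_pct"] = 100.0 * (out["raw"] - blank) / (vehicle - blank)
    return out
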