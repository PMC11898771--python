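"""Label-mask geometry: object matching, ring construction, measurement.

Masks are integer label images on a row-major pixel grid: 0 is background,
objects are labelled 1..N.  Segmentation itself (e.g. Cellpose, seeded
propagation) is out of scope — masks are inputs here.

The central bookkeeping step of per-cell analysis is matching each nucleus to
the cell that contains it.  A nucleus is matched to the cell covering the
largest fraction of its pixels, provided that fraction reaches ``min_overlap``
(default 0.9, i.e. at least 90 % of the nucleus inside the cell); cells that
end up without any matched nucleus are excluded from per-cell measurements.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import gaussian

__all__ = [
    "GeometryError",
    "ImageSet",
    "MatchedObjects",
    "match_nuclei_to_cells",
    "ring_region",
    "measure_cells",
    "illumination_correct",
]


class GeometryError(ValueError):
    """Masks or channels are geometrically inconsistent."""


@dataclasses.dataclass
class ImageSet:
    """Aligned masks and intensity channels for one field of view.

    All arrays share one pixel grid.  ``cell_mask`` is optional (some assays
    only segment nuclei); ``channels`` maps channel name -> float image.
    """

    nucleus_mask: np.ndarray
    cell_mask: "np.ndarray | None" = None
    channels: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.nucleus_mask = np.asarray(self.nucleus_mask)
        shape = self.nucleus_mask.shape
        if self.nucleus_mask.ndim != 2:
            raise GeometryError("masks must be 2-D")
        if np.issubdtype(self.nucleus_mask.dtype, np.floating):
            raise GeometryError("label masks must be integer-typed")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask)
            if self.cell_mask.shape != shape:
                raise GeometryError("cell_mask shape differs from nucleus_mask")
        for name, img in self.channels.items():
            img = np.asarray(img, dtype=float)
            if img.shape != shape:
                raise GeometryError(f"channel {name!r} shape differs from masks")
            self.channels[name] = img

    @property
    def shape(self):
        return self.nucleus_mask.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present (have {sorted(self.channels)})")
        return self.channels[name]


@dataclasses.dataclass
class MatchedObjects:
    """Nucleus-cell pairing with audit trail.

    ``pairs`` has one row per matched nucleus: nucleus_label, cell_label,
    overlap (fraction of nucleus pixels inside the matched cell).
    """

    pairs: pd.DataFrame
    unmatched_nuclei: pd.DataFrame
    unmatched_cells: pd.DataFrame

    @property
    def cell_for_nucleus(self) -> dict:
        return dict(zip(self.pairs["nucleus_label"], self.pairs["cell_label"]))

    @property
    def matched_cells(self) -> np.ndarray:
        return self.pairs["cell_label"].unique()

    def __len__(self) -> int:
        return len(self.pairs)


def match_nuclei_to_cells(nucleus_mask, cell_mask, min_overlap: float = 0.9) -> MatchedObjects:
    """Match each nucleus to the cell maximizing the contained fraction.

    The overlap denominator is the nucleus area: o = |nucleus ∩ cell| /
    |nucleus|.  A nucleus is matched when its best o reaches ``min_overlap``;
    each nucleus joins at most one pair, and a cell may carry several nuclei
    (multinucleate cells keep one row per nucleus downstream).
    """
    nucleus_mask = np.asarray(nucleus_mask)
    cell_mask = np.asarray(cell_mask)
    if nucleus_mask.shape != cell_mask.shape:
        raise GeometryError("nucleus and cell masks must share a shape")
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")

    inside = nucleus_mask > 0
    nuc_labels, nuc_areas = np.unique(nucleus_mask[inside], return_counts=True)
    area_of = dict(zip(nuc_labels.tolist(), nuc_areas.tolist()))

    # joint histogram of (nucleus label, cell label) over nucleus pixels
    pair_keys, pair_counts = np.unique(
        np.stack([nucleus_mask[inside], cell_mask[inside]]), axis=1, return_counts=True
    )
    best: dict = {}
    for (nl, cl), cnt in zip(pair_keys.T.tolist(), pair_counts.tolist()):
        if cl == 0:
            continue
        frac = cnt / area_of[nl]
        # ties between cells broken toward the lower cell label (np.unique order)
        if nl not in best or frac > best[nl][1]:
            best[nl] = (cl, frac)

    pairs, un_nuc = [], []
    for nl in nuc_labels.tolist():
        if nl in best and best[nl][1] >= min_overlap:
            pairs.append({"nucleus_label": nl, "cell_label": best[nl][0], "overlap": best[nl][1]})
        elif nl in best:
            un_nuc.append({"nucleus_label": nl, "reason": "overlap_below_threshold"})
        else:
            un_nuc.append({"nucleus_label": nl, "reason": "outside_all_cells"})
    pairs_df = pd.DataFrame(pairs, columns=["nucleus_label", "cell_label", "overlap"])
    matched_cells = set(pairs_df["cell_label"])
    all_cells = np.unique(cell_mask[cell_mask > 0])
    un_cells = pd.DataFrame(
        [{"cell_label": cl, "reason": "no_matched_nucleus"} for cl in all_cells.tolist()
         if cl not in matched_cells],
        columns=["cell_label", "reason"],
    )
    return MatchedObjects(
        pairs=pairs_df,
        unmatched_nuclei=pd.DataFrame(un_nuc, columns=["nucleus_label", "reason"]),
        unmatched_cells=un_cells,
    )


def ring_region(
    nucleus_mask,
    width_px: int = 15,
    cell_mask=None,
    matched: "MatchedObjects | None" = None,
) -> np.ndarray:
    """Cytoplasmic ring label mask: pixels within ``width_px`` of a nucleus.

    The ring of nucleus n is the set of non-nucleus pixels whose Euclidean
    distance to the nearest nucleus pixel is at most ``width_px`` and whose
    nearest nucleus is n (contested pixels go to the closer nucleus; exact
    ties fall to the distance transform's scan order).  When ``cell_mask`` is
    given, each ring is clipped to the nucleus's matched cell (``matched``
    computed with the default threshold if not supplied); nuclei without a
    matched cell get no ring.
    """
    nucleus_mask = np.asarray(nucleus_mask)
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if not (nucleus_mask > 0).any():
        return np.zeros_like(nucleus_mask)

    dist, (ir, ic) = ndi.distance_transform_edt(nucleus_mask == 0, return_indices=True)
    in_ring = (dist > 0) & (dist <= width_px)
    ring = np.zeros_like(nucleus_mask)
    ring[in_ring] = nucleus_mask[ir[in_ring], ic[in_ring]]

    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask)
        if cell_mask.shape != nucleus_mask.shape:
            raise GeometryError("cell_mask shape differs from nucleus_mask")
        if matched is None:
            matched = match_nuclei_to_cells(nucleus_mask, cell_mask)
        cell_of = matched.cell_for_nucleus
        max_lab = int(nucleus_mask.max())
        lut = np.zeros(max_lab + 1, dtype=cell_mask.dtype)
        for nl, cl in cell_of.items():
            lut[nl] = cl
        keep = (ring > 0) & (lut[ring] > 0) & (cell_mask == lut[ring])
        ring = np.where(keep, ring, 0)
    return ring


def _boundary_radii(region_mask: np.ndarray, centroid) -> tuple[float, float]:
    """Max and mean distance from centroid to boundary pixels of a region."""
    eroded = ndi.binary_erosion(region_mask)
    boundary = region_mask & ~eroded
    br, bc = np.nonzero(boundary)
    d = np.hypot(br - centroid[0], bc - centroid[1])
    if d.size == 0:
        return 0.0, 0.0
    return float(d.max()), float(d.mean())


def measure_cells(
    image_set: ImageSet,
    matched: MatchedObjects,
    channels=None,
    ring_width: int = 15,
    image_id: str = "image0",
    condition: str = "unspecified",
    replicate_day: str = "d1",
    timepoint_h: float = 72.0,
):
    """Per-cell shape and intensity measurements for matched cells.

    One row per matched nucleus (``cell_id`` = nucleus label).  Shape
    features: cell area, perimeter, equivalent diameter, eccentricity, form
    factor 4πA/P², max and mean centroid-to-boundary radius, nucleus area and
    nucleus/cell area ratio.  For every requested channel: mean, median and
    integrated intensity over the nucleus, the cytoplasmic ring and the whole
    cell.  Returns a validated :class:`~morphoscreen.io_tables.FeatureTable`.
    """
    from .io_tables import FeatureTable

    if image_set.cell_mask is None:
        raise GeometryError("measure_cells requires a cell mask")
    if len(matched) == 0:
        raise ValueError("no matched cells to measure")
    if channels is None:
        channels = sorted(image_set.channels)
    for name in channels:
        image_set.channel(name)  # raises KeyError when absent

    nucleus_mask = image_set.nucleus_mask
    cell_mask = image_set.cell_mask
    ring = ring_region(nucleus_mask, ring_width, cell_mask=cell_mask, matched=matched)

    props = {
        p.label: p
        for p in skmeasure.regionprops(cell_mask)
        if p.label in set(matched.pairs["cell_label"])
    }
    nuc_areas = dict(
        zip(*np.unique(nucleus_mask[nucleus_mask > 0], return_counts=True))
    )

    rows = []
    for _, pair in matched.pairs.iterrows():
        nl, cl = int(pair["nucleus_label"]), int(pair["cell_label"])
        p = props[cl]
        area = float(p.area)
        perim = float(p.perimeter)
        cell_px = cell_mask == cl
        max_r, mean_r = _boundary_radii(cell_px, p.centroid)
        row = {
            "cell_id": nl,
            "image_id": image_id,
            "condition": condition,
            "replicate_day": replicate_day,
            "timepoint_h": timepoint_h,
            "AreaShape_Area": area,
            "AreaShape_Perimeter": perim,
            "AreaShape_EquivalentDiameter": float(p.equivalent_diameter_area),
            "AreaShape_Eccentricity": float(p.eccentricity),
            "AreaShape_FormFactor": 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan,
            "AreaShape_MaxRadius": max_r,
            "AreaShape_MeanRadius": mean_r,
            "AreaShape_NucleusArea": float(nuc_areas[nl]),
            "AreaShape_NucleusCellRatio": float(nuc_areas[nl]) / area,
        }
        nuc_px = nucleus_mask == nl
        ring_px = ring == nl
        for name in channels:
            img = image_set.channels[name]
            for region, rpx in (("Nucleus", nuc_px), ("Ring", ring_px), ("Cell", cell_px)):
                vals = img[rpx]
                if vals.size == 0:
                    mean = med = integ = np.nan
                else:
                    mean, med, integ = float(vals.mean()), float(np.median(vals)), float(vals.sum())
                row[f"Intensity_Mean_{name}_{region}"] = mean
                row[f"Intensity_Median_{name}_{region}"] = med
                row[f"Intensity_Integrated_{name}_{region}"] = integ
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


def illumination_correct(image, sigma_px: float):
    """Divide an image by its heavy Gaussian background, preserving the mean.

    Standard flat-field correction for slowly varying illumination: the
    background estimate is a Gaussian blur at scale ``sigma_px`` (large with
    respect to cell size), the image is divided by it and rescaled so the
    global mean is unchanged.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    image = np.asarray(image, dtype=float)
    total = image.mean()
    if total == 0:
        warnings.warn("all-zero image: illumination correction returns zeros")
        return np.zeros_like(image)
    background = gaussian(image, sigma=sigma_px, preserve_range=True)
    background = np.where(background <= 0, np.finfo(float).tiny, background)
    corrected = image / background
    corrected *= total / corrected.mean()
    return corrected
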