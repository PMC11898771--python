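"""Synthetic data generators with ground truth.

The study design this package targets — many growth conditions, a few images
per condition, hundreds of cells per image — relies on raw microscopy that is
rarely redistributable.  These generators produce every input the pipeline
consumes, together with truth tables sufficient to score each stage:

* :func:`generate_feature_table` — per-cell feature tables with controlled
  location/scale shifts per condition, drawn from non-Gaussian families
  (sizes and intensities are lognormal, shape ratios are bounded beta-like),
  mirroring the skewed distributions of real morphological measurements;
* :func:`generate_image_set` — two-compartment cells (nucleus disk inside a
  cytoplasm disk) with a known cytoplasm/nucleus reporter intensity ratio;
* :func:`generate_neurite_image` — soma disks with one-pixel-wide persistent
  random-walk neurites of known path length, for differentiation scoring;
* :func:`generate_growth_counts` — 24 h / 72 h well counts with multiplicative
  lognormal noise and a same-day control well.

All generators take an explicit integer seed and are deterministic given it;
there is no hidden global random state.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .masks import ImageSet

__all__ = [
    "ConfigError",
    "CapacityError",
    "EffectSpec",
    "SyntheticCellImageSpec",
    "feature_families",
    "generate_feature_table",
    "generate_image_set",
    "generate_neurite_image",
    "generate_growth_counts",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CapacityError(RuntimeError):
    """Objects could not be placed without overlap."""


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

# feature families cycle in this order; parameters are fixed per family so a
# feature's base distribution is reproducible from its name alone
_FAMILIES = (
    # (name prefix, family, params)
    ("AreaShape_Size", "lognormal", {"mu": math.log(300.0), "sigma": 0.4}),
    ("Intensity_Mean", "normal", {"mu": 100.0, "sigma": 15.0}),
    ("AreaShape_Ratio", "beta", {"a": 2.0, "b": 5.0}),
)


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Condition-level effect on a subset of features.

    ``location_shift`` is expressed in units of the feature's base population
    SD; ``scale_factor`` multiplies the spread about the base mean.  Either may
    be a single number applied to every affected feature or a mapping
    ``feature name -> value``.
    """

    condition: str
    location_shift: "float | dict" = 0.0
    scale_factor: "float | dict" = 1.0
    affected_features: tuple = ()
    n_cells_per_image: int = 100
    n_images: int = 4
    replicate_day: str = "d1"
    timepoint_h: float = 72.0

    def shift_for(self, feature: str) -> float:
        if isinstance(self.location_shift, dict):
            return float(self.location_shift.get(feature, 0.0))
        return float(self.location_shift) if feature in self.affected_features else 0.0

    def scale_for(self, feature: str) -> float:
        if isinstance(self.scale_factor, dict):
            return float(self.scale_factor.get(feature, 1.0))
        return float(self.scale_factor) if feature in self.affected_features else 1.0

    def is_reference(self) -> bool:
        shifts = (
            self.location_shift.values()
            if isinstance(self.location_shift, dict)
            else [self.location_shift]
        )
        scales = (
            self.scale_factor.values()
            if isinstance(self.scale_factor, dict)
            else [self.scale_factor]
        )
        return all(s == 0.0 for s in shifts) and all(s == 1.0 for s in scales)


def feature_families(base_features: int) -> pd.DataFrame:
    """Name and document the distribution family of each generated feature."""
    rows = []
    for j in range(base_features):
        prefix, family, params = _FAMILIES[j % len(_FAMILIES)]
        rows.append(
            {"feature": f"{prefix}_{j:03d}", "family": family, **params_to_cols(params)}
        )
    return pd.DataFrame(rows)


def params_to_cols(params: dict) -> dict:
    return {f"param_{k}": v for k, v in params.items()}


def _family_moments(family: str, params: dict) -> tuple[float, float]:
    """Population mean and SD of a base family (closed form)."""
    if family == "lognormal":
        mu, s = params["mu"], params["sigma"]
        m = math.exp(mu + s * s / 2.0)
        v = (math.exp(s * s) - 1.0) * math.exp(2 * mu + s * s)
        return m, math.sqrt(v)
    if family == "normal":
        return params["mu"], params["sigma"]
    if family == "beta":
        a, b = params["a"], params["b"]
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return m, math.sqrt(v)
    raise ConfigError(f"unknown family {family!r}")


def _draw_family(rng: np.random.Generator, family: str, params: dict, n: int):
    if family == "lognormal":
        return rng.lognormal(params["mu"], params["sigma"], n)
    if family == "normal":
        return rng.normal(params["mu"], params["sigma"], n)
    if family == "beta":
        return rng.beta(params["a"], params["b"], n)
    raise ConfigError(f"unknown family {family!r}")


def generate_feature_table(base_features: int, effects, seed: int):
    """Generate a multi-condition per-cell feature table with known effects.

    Returns ``(table, truth)`` where ``truth`` records the nominal
    standardized location shift and scale factor per (condition, feature).

    Each affected feature is transformed as ``x -> m + k (x - m) + d s`` with
    ``(m, s)`` the base family's population mean/SD, ``k`` the scale factor and
    ``d`` the location shift in SD units, so the realized standardized mean
    difference equals the nominal ``d`` up to sampling error.
    """
    from .io_tables import FeatureTable

    effects = list(effects)
    if base_features < 1:
        raise ConfigError("base_features must be >= 1")
    labels = [e.condition for e in effects]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate condition labels in effects")
    if not any(e.is_reference() for e in effects):
        raise ConfigError("at least one EffectSpec must be a zero-shift reference")
    fams = feature_families(base_features)
    names = list(fams["feature"])
    for e in effects:
        unknown = set(e.affected_features) - set(names)
        if unknown:
            raise ConfigError(f"affected features not generated: {sorted(unknown)}")
        if e.n_cells_per_image < 1 or e.n_images < 1:
            raise ConfigError("n_cells_per_image and n_images must be >= 1")
        for f in names:
            if e.scale_for(f) <= 0:
                raise ConfigError("scale_factor must be > 0")

    rng = np.random.default_rng(seed)
    frames, truth_rows = [], []
    for e in effects:
        n = e.n_cells_per_image * e.n_images
        cols = {}
        for j, name in enumerate(names):
            _, family, params = _FAMILIES[j % len(_FAMILIES)]
            x = _draw_family(rng, family, params, n)
            m, s = _family_moments(family, params)
            k, d = e.scale_for(name), e.shift_for(name)
            if k != 1.0 or d != 0.0:
                x = m + k * (x - m) + d * s
                truth_rows.append(
                    {"condition": e.condition, "feature": name,
                     "location_shift": d, "scale_factor": k}
                )
            cols[name] = x
        image_idx = np.repeat(np.arange(e.n_images), e.n_cells_per_image)
        df = pd.DataFrame(cols)
        df.insert(0, "timepoint_h", e.timepoint_h)
        df.insert(0, "replicate_day", e.replicate_day)
        df.insert(0, "condition", e.condition)
        df.insert(0, "image_id", [f"{e.condition}_im{i}" for i in image_idx])
        df.insert(0, "cell_id", np.arange(n) % e.n_cells_per_image + 1)
        frames.append(df)
    table = FeatureTable(pd.concat(frames, ignore_index=True), feature_columns=names)
    truth = pd.DataFrame(
        truth_rows, columns=["condition", "feature", "location_shift", "scale_factor"]
    )
    return table, truth


# --------------------------------------------------------------------------
# two-compartment cell images
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SyntheticCellImageSpec:
    """Geometry and intensity of synthetic two-compartment cells."""

    image_size: tuple = (512, 512)
    nucleus_radius: int = 7
    cytoplasm_radius: int = 16
    nucleus_intensity: float = 100.0
    cytoplasm_intensity: float = 50.0
    noise_sd: float = 0.0
    n_cells: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.cytoplasm_radius <= self.nucleus_radius:
            raise ConfigError("cytoplasm_radius must exceed nucleus_radius")
        if self.nucleus_intensity < 0 or self.cytoplasm_intensity < 0:
            raise ConfigError("intensities must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be nonnegative")


def _place_centers(rng, shape, n, min_sep, margin, max_tries=20000):
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    centers = []
    tries = 0
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise CapacityError("image too small for object margin")
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"placed only {len(centers)}/{n} objects without overlap"
            )
        r = margin + rng.uniform() * (h - 2 * margin)
        c = margin + rng.uniform() * (w - 2 * margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in centers):
            centers.append((r, c))
    return centers


def _disk_indices(shape, center, radius):
    r0, c0 = center
    rlo, rhi = int(max(0, r0 - radius - 1)), int(min(shape[0], r0 + radius + 2))
    clo, chi = int(max(0, c0 - radius - 1)), int(min(shape[1], c0 + radius + 2))
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return rr[inside], cc[inside]


def generate_image_set(spec: SyntheticCellImageSpec):
    """Generate nucleus/cell label masks plus a reporter channel.

    Returns ``(ImageSet, truth)``; truth columns are ``label``, ``row``,
    ``col`` (centroid) and ``true_ratio`` — the constructed cytoplasm-to-
    nucleus reporter intensity ratio (the quantity a kinase translocation
    reporter measurement should recover).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size)
    nucleus = np.zeros(shape, dtype=np.uint16)
    cell = np.zeros(shape, dtype=np.uint16)
    reporter = np.zeros(shape, dtype=float)

    if spec.nucleus_intensity <= 0:
        raise ConfigError("nucleus_intensity must be positive for a defined ratio")
    true_ratio = spec.cytoplasm_intensity / spec.nucleus_intensity

    centers = _place_centers(
        rng,
        shape,
        spec.n_cells,
        min_sep=2 * spec.cytoplasm_radius + 2,
        margin=spec.cytoplasm_radius + 1,
    )
    rows = []
    for lab, (r0, c0) in enumerate(centers, start=1):
        rr, cc = _disk_indices(shape, (r0, c0), spec.cytoplasm_radius)
        cell[rr, cc] = lab
        reporter[rr, cc] = spec.cytoplasm_intensity
        rr, cc = _disk_indices(shape, (r0, c0), spec.nucleus_radius)
        nucleus[rr, cc] = lab
        reporter[rr, cc] = spec.nucleus_intensity
        rows.append({"label": lab, "row": r0, "col": c0, "true_ratio": true_ratio})
    if spec.noise_sd > 0:
        reporter = reporter + rng.normal(0.0, spec.noise_sd, shape)
    truth = pd.DataFrame(rows, columns=["label", "row", "col", "true_ratio"])
    return ImageSet(nucleus_mask=nucleus, cell_mask=cell, channels={"reporter": reporter}), truth


# --------------------------------------------------------------------------
# neurite-bearing cells
# --------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
# 8-neighborhood steps ordered by angle, with their path-length weights
_STEPS = [
    (math.atan2(dr, dc), (dr, dc), _SQRT2 if dr and dc else 1.0)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dr, dc) != (0, 0)
]


def _sample_length(rng, mean, lo, hi, max_tries=1000):
    # exponential-family draw truncated to (lo, hi); resampling keeps the
    # stated bound by construction
    for _ in range(max_tries):
        x = rng.gamma(2.0, mean / 2.0)
        if lo < x < hi:
            return x
    return 0.5 * (lo + hi)


def _walk_neurite(rng, start, box, target_len):
    """Persistent random walk on the pixel grid, reflected at a bounding box.

    Returns (pixels, realized √2-weighted length).  The slowly drifting
    heading keeps the path from self-crossing in most draws, so the drawn
    geodesic matches the accumulated step length.
    """
    (rlo, rhi), (clo, chi) = box
    r, c = start
    theta = rng.uniform(0.0, 2.0 * math.pi)
    pixels = [(r, c)]
    length = 0.0
    while length < target_len:
        theta += rng.normal(0.0, 0.18)

        def _circ_dist(step):
            d = (step[0] - theta) % (2.0 * math.pi)
            return min(d, 2.0 * math.pi - d)

        # pick the 8-neighbor step closest to the current heading
        best = min(_STEPS, key=_circ_dist)
        dr, dc = best[1]
        nr, nc = r + dr, c + dc
        if not (rlo < nr < rhi and clo < nc < chi):
            # reflect the heading back toward the box interior
            theta += math.pi / 2.0 + rng.uniform(0, math.pi / 2.0)
            continue
        r, c = nr, nc
        pixels.append((r, c))
        length += best[2]
    return pixels, length


def generate_neurite_image(
    n_cells: int,
    length_distribution: "dict | None" = None,
    frac_long: float = 0.3,
    seed: int = 0,
    soma_radius: int = 5,
    cut_px: float = 100.0,
):
    """Generate soma+neurite cells with known skeleton path lengths.

    ``length_distribution`` gives the mean neurite length in pixels for the
    ``short`` (undifferentiated-like, default 19 px) and ``long``
    (differentiated-like, default 150 px) populations; draws are truncated at
    the classification cut (default 100 px) so class membership is exact by
    construction.  Each cell occupies a private bounding box, so neurites of
    different cells never touch.

    Returns ``(ImageSet, truth)`` with truth columns ``label``,
    ``true_length`` (neurite path length, √2-weighted) and ``is_long``.
    """
    if length_distribution is None:
        length_distribution = {"short": 19.0, "long": 150.0}
    if length_distribution["short"] <= 0 or length_distribution["long"] <= 0:
        raise ConfigError("mean lengths must be positive")
    if not 0.0 <= frac_long <= 1.0:
        raise ConfigError("frac_long must be in [0, 1]")

    rng = np.random.default_rng(seed)
    box_px = 120  # private box per cell; walks are reflected inside it
    n_side = int(math.ceil(math.sqrt(max(n_cells, 1))))
    shape = (n_side * box_px, n_side * box_px)
    nucleus = np.zeros(shape, dtype=np.uint16)
    cellmask = np.zeros(shape, dtype=np.uint16)
    rows = []
    for lab in range(1, n_cells + 1):
        gi, gj = divmod(lab - 1, n_side)
        rlo, clo = gi * box_px, gj * box_px
        box = ((rlo + 1, rlo + box_px - 2), (clo + 1, clo + box_px - 2))
        r0 = int(rng.integers(rlo + box_px // 3, rlo + 2 * box_px // 3))
        c0 = int(rng.integers(clo + box_px // 3, clo + 2 * box_px // 3))
        is_long = bool(rng.uniform() < frac_long)
        if is_long:
            target = _sample_length(
                rng, length_distribution["long"], cut_px, 3.0 * length_distribution["long"]
            )
        else:
            target = _sample_length(rng, length_distribution["short"], 1.0, cut_px)
        rr, cc = _disk_indices(shape, (r0, c0), soma_radius)
        cellmask[rr, cc] = lab
        rr, cc = _disk_indices(shape, (r0, c0), max(2, soma_radius // 2))
        nucleus[rr, cc] = lab
        pixels, realized = _walk_neurite(rng, (r0, c0), box, target)
        for pr, pc in pixels:
            cellmask[pr, pc] = lab
        rows.append({"label": lab, "true_length": realized, "is_long": is_long})
    truth = pd.DataFrame(rows, columns=["label", "true_length", "is_long"])
    return ImageSet(nucleus_mask=nucleus, cell_mask=cellmask, channels={}), truth


# --------------------------------------------------------------------------
# growth counts
# --------------------------------------------------------------------------


def generate_growth_counts(
    conditions,
    fold_increase,
    control_fold: float = 4.0,
    cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    base_count: float = 200.0,
    control_label: str = "control",
):
    """Per-well 24 h / 72 h counts with a same-day control well.

    ``fold_increase`` is a mapping condition -> true 72 h/24 h fold (or a single
    number applied to all conditions).  Multiplicative lognormal noise with
    coefficient of variation ``cv`` (unit mean) is applied independently to
    each count; ``cv=0`` reproduces the folds exactly.
    """
    conditions = list(conditions)
    if isinstance(fold_increase, (int, float)):
        fold_increase = {c: float(fold_increase) for c in conditions}
    for c in conditions:
        if fold_increase[c] <= 0:
            raise ConfigError("fold_increase must be positive")
    if control_fold <= 0:
        raise ConfigError("control_fold must be positive")
    if cv < 0:
        raise ConfigError("cv must be nonnegative")

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))

    def noise(n):
        if sigma == 0.0:
            return np.ones(n)
        return rng.lognormal(-sigma * sigma / 2.0, sigma, n)

    rows = []
    for rep in range(1, n_replicates + 1):
        day = f"day{rep}"
        for cond in conditions + [control_label]:
            fold = control_fold if cond == control_label else fold_increase[cond]
            c24 = base_count * noise(1)[0]
            c72 = c24 * fold * noise(1)[0]
            rows.append(
                {
                    "condition": cond,
                    "replicate_day": day,
                    "well": f"{cond}_{day}",
                    "count_24h": c24,
                    "count_72h": c72,
                    "is_control": cond == control_label,
                    "true_fold": fold,
                }
            )
    return pd.DataFrame(rows)
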