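"""Condition dissimilarity from per-cell feature distributions.

The headline statistic of the package.  Morphological feature distributions
in cell populations are typically non-Gaussian, so conditions are compared by
distribution distances rather than mean differences:

1. every feature is z-scored pooled across *all* cells of *all* conditions
   (so features are on a common scale and the comparison is unit-free);
2. for each pair of conditions and each feature j, the first Wasserstein
   distance (earth mover's distance, EMD) W_j between the two empirical
   per-cell distributions is computed — sensitive to location, scale and
   shape differences alike;
3. the per-feature distances are aggregated into a single condition
   dissimilarity D_ab = sqrt(Σ_j W_j²) (the Euclidean norm of the EMD
   vector), giving a symmetric zero-diagonal dissimilarity matrix;
4. the matrix is embedded in 2-D (classical MDS by default, SMACOF
   optionally) for visualization.

Useful identities: for 1-D samples the EMD equals the L1 distance between
quantile functions; W(x, x+c) = |c| for any constant shift; for two Gaussians
with equal SD the EMD equals the absolute mean difference.  These drive the
test oracles.

Per-feature screening (Kruskal–Wallis on per-image means, BH-adjusted) and
Ward-D2 hierarchical clustering of conditions round out the module.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof as _sk_smacof
from statsmodels.stats.multitest import multipletests

from .io_tables import FeatureTable

__all__ = [
    "EMDVector",
    "DissimilarityMatrix",
    "Embedding2D",
    "ClusterResult",
    "zscore_features",
    "wasserstein_1d",
    "condition_dissimilarity",
    "embed_2d",
    "screen_features",
    "cluster_conditions",
]


# ------------------------------------------------------------------- types
@dataclasses.dataclass(frozen=True)
class EMDVector:
    """Per-feature earth mover's distances for one condition pair."""

    condition_a: str
    condition_b: str
    features: tuple
    distances: np.ndarray  # aligned with features, all >= 0

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.distances))


@dataclasses.dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric, zero-diagonal condition-by-condition distance matrix."""

    conditions: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.conditions),) * 2:
            raise ValueError("matrix shape does not match condition count")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.conditions),
                            columns=list(self.conditions))

    def __getitem__(self, key):
        a, b = key
        ia = self.conditions.index(a)
        ib = self.conditions.index(b)
        return self.values[ia, ib]


@dataclasses.dataclass(frozen=True)
class Embedding2D:
    conditions: tuple
    coordinates: np.ndarray  # (n, 2)
    stress: float
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": list(self.conditions),
             "x": self.coordinates[:, 0], "y": self.coordinates[:, 1]}
        )


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    conditions: tuple
    linkage: np.ndarray  # scipy linkage matrix (Ward)
    leaf_order: tuple  # condition labels in dendrogram order


# ---------------------------------------------------------------- z-score
def zscore_features(table: FeatureTable):
    """Z-score each feature pooled across all cells of all conditions.

    Uses the population SD (ddof=0).  Zero-variance features carry no
    distributional information and are dropped with a warning.  Returns
    ``(zscored_table, dropped_feature_names)``.
    """
    if table.n_cells < 2:
        raise ValueError("z-scoring requires at least two cells")
    feats = table.features()
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    dropped = list(sd.index[sd == 0.0])
    kept = [f for f in table.feature_columns if f not in dropped]
    if not kept:
        raise ValueError("all features have zero variance: empty profile")
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped}")
    data = table.data.drop(columns=dropped).copy()
    data[kept] = (feats[kept] - mu[kept]) / sd[kept]
    return FeatureTable(data, feature_columns=kept), dropped


# -------------------------------------------------------------------- EMD
def wasserstein_1d(sample_a, sample_b) -> float:
    """First Wasserstein (earth mover's) distance between two 1-D samples.

    Computed exactly as the integral of the absolute difference of the two
    empirical CDFs (equivalently, of the quantile functions), with uniform
    weights; handles unequal sample sizes.  For equal-size samples this
    reduces to the mean absolute difference of the order statistics.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    a.sort()
    b.sort()
    support = np.concatenate([a, b])
    support.sort(kind="mergesort")
    deltas = np.diff(support)
    if deltas.size == 0:
        return 0.0
    cdf_a = np.searchsorted(a, support[:-1], side="right") / a.size
    cdf_b = np.searchsorted(b, support[:-1], side="right") / b.size
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def condition_dissimilarity(table: FeatureTable, min_cells: int = 50):
    """Per-feature EMD vectors and the aggregated condition distance matrix.

    For every unordered pair of conditions (a, b): W_j = EMD between the two
    per-cell distributions of feature j, and D_ab = sqrt(Σ_j W_j²).  The input
    table should already be z-scored (:func:`zscore_features`).  Conditions
    with fewer than ``min_cells`` cells are excluded with a warning (error if
    fewer than two remain).  Condition order follows first appearance in the
    table.  Returns ``(emd_vectors, DissimilarityMatrix)``.
    """
    counts = table.data["condition"].value_counts()
    conditions = [c for c in table.conditions if counts[c] >= min_cells]
    skipped = [c for c in table.conditions if counts[c] < min_cells]
    if skipped:
        warnings.warn(f"conditions below min_cells={min_cells} excluded: {skipped}")
    if len(conditions) < 2:
        raise ValueError("need at least two conditions with enough cells")

    feats = list(table.feature_columns)
    by_cond = {
        c: table.data.loc[table.data["condition"] == c, feats].to_numpy()
        for c in conditions
    }
    vectors = []
    n = len(conditions)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xa, xb = by_cond[conditions[i]], by_cond[conditions[j]]
            w = np.array([wasserstein_1d(xa[:, k], xb[:, k]) for k in range(len(feats))])
            vectors.append(
                EMDVector(conditions[i], conditions[j], tuple(feats), w)
            )
            D[i, j] = D[j, i] = float(np.linalg.norm(w))
    return vectors, DissimilarityMatrix(tuple(conditions), D)


def emd_long_frame(vectors) -> pd.DataFrame:
    """Long-format (condition_a, condition_b, feature, distance) table."""
    rows = []
    for v in vectors:
        for f, w in zip(v.features, v.distances):
            rows.append(
                {"condition_a": v.condition_a, "condition_b": v.condition_b,
                 "feature": f, "distance": float(w)}
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- embedding
def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Torgerson's classical scaling: double-centre D² and take top-2 eigs."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    # deterministic sign convention: largest-magnitude entry positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def embed_2d(D: DissimilarityMatrix, method: str = "classical_mds", seed=0) -> Embedding2D:
    """Embed a condition dissimilarity matrix in 2-D.

    ``classical_mds`` (default) is the deterministic eigen-solution minimizing
    strain; ``smacof`` iteratively minimizes metric stress from a seeded
    random start.  The reported stress is Kruskal's normalized stress-1 of the
    embedded configuration against the input dissimilarities.
    """
    n = len(D.conditions)
    if n < 3:
        raise ValueError("2-D embedding needs at least three conditions")
    if method == "classical_mds":
        coords = _classical_mds(D.values)
    elif method == "smacof":
        coords, _ = _sk_smacof(
            D.values, n_components=2, random_state=seed, normalized_stress=False
        )
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    d_emb = squareform(pdist(coords))
    denom = np.sum(D.values**2)
    stress = float(np.sqrt(np.sum((d_emb - D.values) ** 2) / denom)) if denom > 0 else 0.0
    return Embedding2D(D.conditions, coords, stress, method)


# -------------------------------------------------------------- screening
def screen_features(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal–Wallis screen of features across conditions on per-image means.

    Cells within an image are not independent, so each feature is first
    aggregated to per-image means; the Kruskal–Wallis H test (midranks with
    tie correction, chi-square reference with groups−1 df) then compares
    conditions, and p-values are Benjamini–Hochberg adjusted across features.
    Returns a frame with feature, H, p, q and a significance flag (q < alpha).
    """
    df = table.data
    image_means = (
        df.groupby(["condition", "image_id"], sort=False)[list(table.feature_columns)]
        .mean()
        .reset_index()
    )
    groups = list(image_means.groupby("condition", sort=False))
    if len(groups) < 2:
        raise ValueError("feature screening needs at least two condition groups")
    for cond, g in groups:
        if len(g) < 2:
            raise ValueError(f"condition {cond!r} has fewer than two images")

    rows = []
    for f in table.feature_columns:
        samples = [g[f].to_numpy() for _, g in groups]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            H, p = 0.0, 1.0  # fully tied data carries no signal
        else:
            H, p = stats.kruskal(*samples)
        rows.append({"feature": f, "H": float(H), "p": float(p)})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] < alpha
    return out


# ------------------------------------------------------------- clustering
def cluster_conditions(matrix) -> ClusterResult:
    """Ward-D2 hierarchical clustering of conditions on Euclidean distances.

    ``matrix`` may be a :class:`DissimilarityMatrix` (clustered on the
    precomputed distances) or a condition-by-metric data frame (clustered on
    Euclidean distances between rows).  Returns the merge tree and the
    dendrogram leaf order for heatmap row ordering.
    """
    if isinstance(matrix, DissimilarityMatrix):
        conditions = list(matrix.conditions)
        y = squareform(matrix.values, checks=False)
    else:
        frame = pd.DataFrame(matrix)
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite values in clustering input")
        conditions = list(frame.index)
        y = pdist(values)
    if len(conditions) < 2:
        raise ValueError("clustering needs at least two conditions")
    if not np.isfinite(y).all():
        raise ValueError("non-finite distances in clustering input")
    Z = hierarchy.linkage(y, method="ward")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(tuple(conditions), Z, tuple(conditions[i] for i in order))
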