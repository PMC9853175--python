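"""The 135-feature cell-morphology census.

Nine value distributions are summarized per slide: seven at cell level
(area, major axis, minor axis, axis ratio, and the min/max/mean Delaunay
neighbor distances) and two at patch level (count and density of
small-hyperchromatic cells).  For each distribution a cohort-wide 1-D
k-means model with 10 clusters — fitted once on cells pooled from up to 50
randomly sampled slides — defines histogram bins; a slide is described by
its 10 bin proportions plus five distribution statistics (mean, SD,
skewness, kurtosis, entropy), giving 9 x 15 = 135 named features.  Patients
with several slides get the elementwise mean of their slide vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cell_features import CellRecord, PatchCellSummary

CELL_DISTRIBUTIONS = ("area", "major_axis", "minor_axis", "axis_ratio",
                      "delaunay_min", "delaunay_max", "delaunay_mean")
PATCH_DISTRIBUTIONS = ("shc_count", "shc_density")
DISTRIBUTIONS = CELL_DISTRIBUTIONS + PATCH_DISTRIBUTIONS
STAT_NAMES = ("mean", "sd", "skewness", "kurtosis", "entropy")
N_BINS = 10

#: Fixed order of the 135 feature names: per distribution, bins 1..10 then
#: the five statistics; cell-level distributions first (105 features), then
#: the two small-hyperchromatic distributions (30 features).
FEATURE_NAMES: tuple[str, ...] = tuple(
    name
    for dist in DISTRIBUTIONS
    for name in ([f"{dist}_bin{i:02d}" for i in range(1, N_BINS + 1)]
                 + [f"{dist}_{s}" for s in STAT_NAMES])
)
N_FEATURES = len(FEATURE_NAMES)  # 135


@dataclass
class SlideMeasurements:
    """All measured values of one processed slide, keyed by distribution."""

    slide_id: str
    cells: list[CellRecord]
    patch_summaries: list[PatchCellSummary]

    def values(self, dist: str) -> np.ndarray:
        if dist in CELL_DISTRIBUTIONS:
            return np.array([getattr(c, dist) for c in self.cells], dtype=float)
        if dist == "shc_count":
            return np.array([p.shc_count for p in self.patch_summaries], dtype=float)
        if dist == "shc_density":
            return np.array([p.shc_density for p in self.patch_summaries], dtype=float)
        raise KeyError(dist)


@dataclass
class BinModel:
    """Sorted 10-centroid 1-D k-means model per distribution."""

    centroids: dict[str, np.ndarray]
    degenerate: dict[str, bool]
    n_slides: int
    seed: int

    def __post_init__(self) -> None:
        for dist, c in self.centroids.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (N_BINS,):
                raise ValueError(f"{dist}: expected {N_BINS} centroids")
            if not np.all(np.diff(c) > 0):
                raise ValueError(f"{dist}: centroids must be strictly sorted")
            self.centroids[dist] = c

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
            "degenerate": self.degenerate,
            "n_slides": self.n_slides,
            "seed": self.seed,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "BinModel":
        d = json.loads(Path(path).read_text())
        return cls({k: np.array(v) for k, v in d["centroids"].items()},
                   d["degenerate"], d["n_slides"], d["seed"])


def _fit_1d_kmeans(values: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, bool]:
    """Sorted centroids of 1-D k-means; degenerate inputs are padded.

    If the data has fewer than k unique values, the unique values become
    centroids and the remainder is padded above the maximum with tiny strictly
    increasing offsets, so assignment never lands in a padded bin.
    """
    uniq = np.unique(values)
    if len(uniq) < k:
        pad_base = uniq[-1]
        step = max(abs(pad_base) * 1e-6, 1e-6)
        pad = pad_base + step * np.arange(1, k - len(uniq) + 1)
        return np.concatenate([uniq, pad]), True
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(values.reshape(-1, 1))
    centroids = np.sort(km.cluster_centers_.ravel())
    # Numerically coincident centroids can survive on near-degenerate data.
    if not np.all(np.diff(centroids) > 0):
        keep = np.concatenate([[True], np.diff(centroids) > 0])
        centroids, _ = _fit_1d_kmeans(centroids[keep], k, seed)
        return centroids, True
    return centroids, False


def fit_bin_model(slides: list[SlideMeasurements], n_sample: int = 50,
                  k: int = N_BINS, seed: int = 0) -> BinModel:
    """Fit the cohort-wide bin model on values pooled from sampled slides.

    Up to ``n_sample`` slides are drawn without replacement (all slides when
    fewer are available); values from the sampled slides are pooled with
    equal weight per value.
    """
    rng = np.random.default_rng(seed)
    if len(slides) > n_sample:
        idx = rng.choice(len(slides), size=n_sample, replace=False)
        sampled = [slides[i] for i in sorted(idx)]
    else:
        sampled = list(slides)
    centroids: dict[str, np.ndarray] = {}
    degenerate: dict[str, bool] = {}
    for dist in DISTRIBUTIONS:
        pooled = np.concatenate([s.values(dist) for s in sampled]) if sampled else np.array([])
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise ValueError(f"no values pooled for distribution '{dist}'")
        centroids[dist], degenerate[dist] = _fit_1d_kmeans(pooled, k, seed)
    return BinModel(centroids, degenerate, n_slides=len(sampled), seed=seed)


def assign_bins(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid bin index (0-based); ties go to the lower index."""
    values = np.asarray(values, dtype=float)
    d = np.abs(values[:, None] - centroids[None, :])
    return d.argmin(axis=1)


def slide_histogram(slide: SlideMeasurements, bins: BinModel) -> dict[str, np.ndarray]:
    """Per-distribution 10 bin proportions over one slide's values."""
    out = {}
    for dist in DISTRIBUTIONS:
        v = slide.values(dist)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(
                f"slide '{slide.slide_id}' has no values for '{dist}' "
                "(zero kept patches?)"
            )
        idx = assign_bins(v, bins.centroids[dist])
        out[dist] = np.bincount(idx, minlength=N_BINS) / v.size
    return out


def distribution_statistics(values: np.ndarray, histogram: np.ndarray,
                            centroids: np.ndarray | None = None
                            ) -> tuple[float, float, float, float, float]:
    """(mean, sd, skewness, kurtosis, entropy) of one distribution.

    Moments are population moments of the raw values (n denominator);
    skewness is g1 = m3 / m2^1.5 and kurtosis is Pearson m4 / m2^2 (normal
    -> 3).  Degenerate distributions (sd = 0) report skewness and kurtosis
    as 0 by convention.  Entropy is the Shannon entropy (nats) of the 10-bin
    proportions with 0*ln(0) = 0.

    When ``centroids`` is given the moments are computed on the binned
    representation instead (centroids weighted by proportions) — a coarser
    but histogram-faithful alternative.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("distribution_statistics requires >= 1 value")
    if centroids is not None:
        p = np.asarray(histogram, dtype=float)
        c = np.asarray(centroids, dtype=float)
        m = float(p @ c)
        d = c - m
        m2 = float(p @ d ** 2)
        sd = np.sqrt(m2)
        if m2 < 1e-24:
            skew = kurt = 0.0
        else:
            skew = float(p @ d ** 3) / m2 ** 1.5
            kurt = float(p @ d ** 4) / m2 ** 2
        nz = p[p > 0]
        return m, float(sd), float(skew), float(kurt), float(-(nz * np.log(nz)).sum())
    m = v.mean()
    d = v - m
    m2 = np.mean(d ** 2)
    sd = np.sqrt(m2)
    if m2 < 1e-24:
        skew = kurt = 0.0
    else:
        skew = np.mean(d ** 3) / m2 ** 1.5
        kurt = np.mean(d ** 4) / m2 ** 2
    p = np.asarray(histogram, dtype=float)
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return float(m), float(sd), float(skew), float(kurt), entropy


def slide_feature_vector(slide: SlideMeasurements, bins: BinModel,
                         moments_on: str = "values") -> pd.Series:
    """The 135-feature census vector of one slide.

    ``moments_on='histogram'`` switches the five statistics to the binned
    representation (centroids weighted by bin proportions).
    """
    if moments_on not in ("values", "histogram"):
        raise ValueError("moments_on must be 'values' or 'histogram'")
    hist = slide_histogram(slide, bins)
    values = {}
    for dist in DISTRIBUTIONS:
        v = slide.values(dist)
        v = v[np.isfinite(v)]
        for i in range(N_BINS):
            values[f"{dist}_bin{i + 1:02d}"] = hist[dist][i]
        stats = distribution_statistics(
            v, hist[dist],
            centroids=(bins.centroids[dist] if moments_on == "histogram"
                       else None))
        for name, s in zip(STAT_NAMES, stats):
            values[f"{dist}_{name}"] = s
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def assemble_patient_vector(slide_vectors: list[pd.Series],
                            patient_id: str | None = None) -> pd.Series:
    """Elementwise mean of one patient's slide vectors."""
    if not slide_vectors:
        raise ValueError("assemble_patient_vector requires >= 1 slide vector")
    names = list(slide_vectors[0].index)
    for v in slide_vectors[1:]:
        if list(v.index) != names:
            raise ValueError("slide vectors have mismatched feature names")
    out = pd.concat(slide_vectors, axis=1).mean(axis=1)
    out.name = patient_id
    return out


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def render_feature_heatmap(patch_values: dict[tuple[int, int], float],
                           cmap: str = "viridis") -> tuple[np.ndarray, float, float]:
    """Color one block per kept patch at its grid position.

    Returns (RGBA float array of shape (rows, cols, 4), vmin, vmax).  Grid
    cells without a value (dropped patches) are fully transparent.  Colors
    are min-max scaled per slide.
    """
    import matplotlib

    if not patch_values:
        raise ValueError("no patch values to render")
    rows = max(r for r, _ in patch_values) + 1
    cols = max(c for _, c in patch_values) + 1
    vals = np.array(list(patch_values.values()), dtype=float)
    vmin, vmax = float(vals.min()), float(vals.max())
    span = vmax - vmin if vmax > vmin else 1.0
    colormap = matplotlib.colormaps[cmap]
    out = np.zeros((rows, cols, 4), dtype=float)
    for (r, c), v in patch_values.items():
        out[r, c] = colormap((v - vmin) / span)
    return out, vmin, vmax


def save_heatmap_png(patch_values: dict[tuple[int, int], float], path,
                     block_px: int = 16, cmap: str = "viridis") -> None:
    """Write the heatmap as a PNG with ``block_px``-sized blocks per patch."""
    from PIL import Image

    rgba, _, _ = render_feature_heatmap(patch_values, cmap=cmap)
    img = (np.repeat(np.repeat(rgba, block_px, axis=0), block_px, axis=1)
           * 255).round().astype(np.uint8)
    Image.fromarray(img, mode="RGBA").save(path)
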