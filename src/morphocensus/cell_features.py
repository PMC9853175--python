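"""Cell instance segmentation, morphometry and spatial statistics.

The built-in segmenter thresholds the hematoxylin concentration channel
(Otsu after Gaussian smoothing) and splits touching cells with a
distance-transform watershed.  Any external instance segmenter can be
plugged in instead by supplying masks in the same integer-label format.

Per-cell measures follow the classical moments-ellipse convention: the major
and minor axis lengths are those of the ellipse with the same normalized
second central moments as the pixel region, including the +1/12 per-pixel
spread correction (so a single pixel has axis length 4*sqrt(1/12) ~ 1.155
rather than zero).  Cell packing is summarized by the minimum, maximum and
mean Euclidean distance to Delaunay neighbors of each cell centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, QhullError
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .preprocess import StainModel, fit_stain_model, stain_concentrations
from .synthetic import TilePatch

SHC_AREA_CUTOFF = 450.0   # px^2, strict '<'
SHC_RATIO_CUTOFF = 2.0    # major/minor, strict '<'


@dataclass
class CellRecord:
    """Morphology and intensity measures of one segmented cell."""

    cell_id: int
    patch_ref: tuple[str, int, int]  # (slide_id, grid_row, grid_col)
    centroid_xy: tuple[float, float]
    area: float
    major_axis: float
    minor_axis: float
    axis_ratio: float
    mean_rgb: tuple[float, float, float]
    delaunay_min: float = np.nan
    delaunay_max: float = np.nan
    delaunay_mean: float = np.nan
    is_shc: bool = False

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.mean_rgb))


@dataclass
class PatchCellSummary:
    patch_ref: tuple[str, int, int]
    n_cells: int
    shc_count: int

    @property
    def shc_density(self) -> float:
        return self.shc_count / self.n_cells if self.n_cells else float("nan")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_cells(patch: TilePatch, stain_model: StainModel | None = None,
                  sigma: float = 1.5, min_size: int = 30,
                  min_peak_distance: int = 7) -> np.ndarray:
    """Instance-segment cells of a normalized patch.

    Returns an int32 label image with consecutive instances 1..n; 0 is
    background.  Instances touching the patch border are retained.
    """
    if stain_model is None:
        try:
            stain_model = fit_stain_model(patch)
        except ValueError:
            return np.zeros(patch.pixels.shape[:2], dtype=np.int32)
    h_channel = stain_concentrations(patch, stain_model)[0]
    smoothed = gaussian(h_channel, sigma=sigma, preserve_range=True)
    if smoothed.max() - smoothed.min() < 1e-6:
        return np.zeros(patch.pixels.shape[:2], dtype=np.int32)
    thresh = threshold_otsu(smoothed)
    binary = smoothed > thresh
    binary = remove_small_objects(binary, max_size=min_size - 1)
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return np.zeros(patch.pixels.shape[:2], dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=min_peak_distance,
                           labels=binary, exclude_border=False)
    markers = np.zeros_like(distance, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-distance, markers, mask=binary, connectivity=1)
    return _relabel_consecutive(labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    out = remap[labels]
    return out


def filter_sparse_patch(mask: np.ndarray, cutoff: int) -> bool:
    """Keep a patch iff it holds at least ``cutoff`` segmented instances."""
    n = len(np.unique(mask)) - (1 if (mask == 0).any() else 0)
    return n >= cutoff


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

def _moment_axes(coords: np.ndarray) -> tuple[float, float]:
    """Axis lengths of the equal-second-moment ellipse of a pixel set.

    Central second moments carry the +1/12 correction for the unit spread of
    each pixel; axis length = 4 * sqrt(eigenvalue of that covariance).
    """
    y = coords[:, 0].astype(float)
    x = coords[:, 1].astype(float)
    uxx = x.var() + 1.0 / 12.0
    uyy = y.var() + 1.0 / 12.0
    uxy = ((x - x.mean()) * (y - y.mean())).mean()
    common = np.sqrt((uxx - uyy) ** 2 + 4.0 * uxy ** 2)
    major = 2.0 * np.sqrt(2.0) * np.sqrt(uxx + uyy + common)
    minor = 2.0 * np.sqrt(2.0) * np.sqrt(uxx + uyy - common)
    return float(major), float(minor)


def measure_cells(mask: np.ndarray, patch: TilePatch) -> list[CellRecord]:
    """Measure every instance of ``mask``: area, axes, ratio, mean RGB.

    Delaunay fields are left unset; see :func:`delaunay_neighbor_stats`.
    """
    if not (mask > 0).any():
        return []
    ref = (patch.slide_id, patch.grid_row, patch.grid_col)
    px = patch.pixels.astype(float)
    records = []
    for rp in regionprops(mask):
        major, minor = _moment_axes(rp.coords)
        sel = tuple(rp.coords.T)
        mean_rgb = tuple(float(px[..., c][sel].mean()) for c in range(3))
        cy, cx = rp.centroid
        records.append(CellRecord(
            cell_id=int(rp.label),
            patch_ref=ref,
            centroid_xy=(float(cx), float(cy)),
            area=float(rp.area),
            major_axis=major,
            minor_axis=minor,
            axis_ratio=major / minor,
            mean_rgb=mean_rgb,
        ))
    return records


def delaunay_neighbor_stats(centroids: np.ndarray) -> np.ndarray:
    """Per-point (min, max, mean) Euclidean distance to Delaunay neighbors.

    Neighbors are points sharing a triangulation edge.  With two points, or
    when all points are collinear so no triangulation exists, every pair is
    treated as adjacent.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("delaunay_neighbor_stats requires >= 2 centroids")
    neighbors: list[set[int]] = [set() for _ in range(n)]
    use_all_pairs = n == 2
    if not use_all_pairs:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for i in range(3):
                    for j in range(i + 1, 3):
                        a, b = simplex[i], simplex[j]
                        neighbors[a].add(b)
                        neighbors[b].add(a)
        except QhullError:
            use_all_pairs = True
    if use_all_pairs:
        for i in range(n):
            neighbors[i] = set(range(n)) - {i}
    out = np.empty((n, 3))
    for i in range(n):
        d = np.linalg.norm(pts[list(neighbors[i])] - pts[i], axis=1)
        out[i] = (d.min(), d.max(), d.mean())
    return out


def attach_delaunay(cells: list[CellRecord]) -> list[CellRecord]:
    """Fill the Delaunay fields of one patch's cells in place."""
    if len(cells) < 2:
        if cells:
            warnings.warn("patch has a single cell; excluded from Delaunay features")
        return cells
    pts = np.array([c.centroid_xy for c in cells])
    stats = delaunay_neighbor_stats(pts)
    for c, (dmin, dmax, dmean) in zip(cells, stats):
        c.delaunay_min, c.delaunay_max, c.delaunay_mean = dmin, dmax, dmean
    return cells


# ---------------------------------------------------------------------------
# Small-hyperchromatic cells
# ---------------------------------------------------------------------------

def flag_small_hyperchromatic(cell: CellRecord, intensity_threshold: float) -> bool:
    """Small (< 450 px^2), round (ratio < 2) and darkly stained cells."""
    return (cell.area < SHC_AREA_CUTOFF
            and cell.axis_ratio < SHC_RATIO_CUTOFF
            and cell.mean_intensity < intensity_threshold)


def adaptive_intensity_threshold(cells: list[CellRecord],
                                 percentile: float = 40.0) -> float:
    """Slide-adaptive hyperchromasia cutoff: a low percentile of per-cell
    mean intensity, so 'dark' is relative to the slide's own staining."""
    if not cells:
        raise ValueError("no cells to derive an intensity threshold from")
    return float(np.percentile([c.mean_intensity for c in cells], percentile))


def cells_to_dataframe(cells: list[CellRecord]):
    """Per-cell table with one row per measured cell (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "slide_id": c.patch_ref[0],
        "patch": f"r{c.patch_ref[1]}_c{c.patch_ref[2]}",
        "cell_id": c.cell_id,
        "area": c.area,
        "major": c.major_axis,
        "minor": c.minor_axis,
        "ratio": c.axis_ratio,
        "r": c.mean_rgb[0], "g": c.mean_rgb[1], "b": c.mean_rgb[2],
        "dmin": c.delaunay_min, "dmax": c.delaunay_max,
        "dmean": c.delaunay_mean,
        "is_shc": int(c.is_shc),
    } for c in cells])


def summarize_patch(cells: list[CellRecord]) -> PatchCellSummary:
    """Count cells and flagged small-hyperchromatic cells of one kept patch."""
    if not cells:
        raise ValueError("summarize_patch called on an empty (dropped) patch")
    return PatchCellSummary(
        patch_ref=cells[0].patch_ref,
        n_cells=len(cells),
        shc_count=sum(c.is_shc for c in cells),
    )
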