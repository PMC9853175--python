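"""Tiling, background filtering and Macenko stain normalization.

Slides from different scanners are brought to a common working resolution of
0.25 microns per pixel by cropping squares of side ``round(512 * 0.25 / mpp)``
from the source raster and resizing them to 512x512.  Background tiles are
removed with simple RGB rules (a generic mean/SD rule set, plus a stricter
rule set for brightfield scanners whose background is bluish).  Staining is
then normalized by stain-vector estimation in optical-density space: tissue
pixels are projected onto the plane of the two leading singular vectors of
the OD matrix, and the hematoxylin/eosin directions are read off as extreme
percentiles of the projection angle (Macenko's method).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .synthetic import TilePatch, HE_STAIN_MATRIX, IO_REFERENCE

TARGET_MPP = 0.25
TILE_PX = 512


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_and_rescale(slide_image: np.ndarray, source_mpp: float,
                     slide_id: str = "slide") -> list[TilePatch]:
    """Cut a non-overlapping grid of tiles and resize each to 512x512.

    The crop side is ``round(TILE_PX * TARGET_MPP / source_mpp)`` source
    pixels so every output tile covers the same physical area regardless of
    scanner resolution.  Partial edge tiles are dropped.
    """
    if source_mpp <= 0:
        raise ValueError("source_mpp must be > 0")
    img = np.asarray(slide_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("slide_image must be HxWx3")
    side = int(round(TILE_PX * TARGET_MPP / source_mpp))
    h, w = img.shape[:2]
    n_rows, n_cols = h // side, w // side
    if n_rows == 0 or n_cols == 0:
        warnings.warn(f"image {h}x{w} smaller than one {side}px tile; no tiles")
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            crop = img[r * side:(r + 1) * side, c * side:(c + 1) * side]
            if side != TILE_PX:
                # area-weighted (anti-aliased) for downscale, bilinear for upscale
                crop = resize(
                    crop.astype(float), (TILE_PX, TILE_PX),
                    order=1, anti_aliasing=(side > TILE_PX), preserve_range=True,
                )
                crop = np.clip(np.round(crop), 0, 255)
            tiles.append(TilePatch(crop.astype(np.uint8), slide_id, r, c,
                                   source_mpp=source_mpp))
    return tiles


# ---------------------------------------------------------------------------
# Background filters
# ---------------------------------------------------------------------------

def is_background_generic(patch: TilePatch) -> tuple[bool, str | None]:
    """Drop white/black/flat patches by pooled RGB statistics.

    Statistics pool all three channels jointly.  Rules: mean >= 230 (white),
    mean <= 40 (black), SD < 20 (featureless).
    """
    px = patch.pixels.astype(float)
    mean = px.mean()
    if mean >= 230:
        return True, "mean≥230"
    if mean <= 40:
        return True, "mean≤40"
    if px.std() < 20:
        return True, "std<20"
    return False, None


def is_background_iusm(patch: TilePatch) -> tuple[bool, str | None]:
    """Stricter rule set for scanners with bluish-white background.

    Drop if any of: red channel mean <= 90% of blue mean (blue cast);
    green mean > 210 together with red mean >= 170 (white); pooled mean
    <= 40 (black).  The connective between the published criteria is a
    disjunction of these three individually testable rules.
    """
    px = patch.pixels.astype(float)
    r, g, b = (px[..., i].mean() for i in range(3))
    if r <= 0.9 * b:
        return True, "red≤0.9·blue"
    if g > 210 and r >= 170:
        return True, "green>210"
    if px.mean() <= 40:
        return True, "mean≤40"
    return False, None


def filter_patches(patches, mode: str = "generic",
                   apply_generic_first: bool = True):
    """Return (kept patches, list of (patch, reason) dropped).

    ``mode='iusm'`` applies the scanner-specific rules; by default the generic
    rules run first as well, since the stricter set was described as *further*
    processing on top of the common filter.
    """
    if mode not in ("generic", "iusm"):
        raise ValueError("mode must be 'generic' or 'iusm'")
    kept, dropped = [], []
    for p in patches:
        drop, reason = (False, None)
        if mode == "generic" or apply_generic_first:
            drop, reason = is_background_generic(p)
        if not drop and mode == "iusm":
            drop, reason = is_background_iusm(p)
        (dropped.append((p, reason)) if drop else kept.append(p))
    return kept, dropped


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

@dataclass
class StainModel:
    """Two-stain optical-density model of one image.

    ``stain_matrix`` holds unit-norm OD direction vectors as columns,
    hematoxylin first (the column with the larger blue-channel OD).
    ``max_concentrations`` are robust (99th percentile) per-stain
    concentration maxima used to match dynamic range across images.
    """

    stain_matrix: np.ndarray  # (3, 2)
    max_concentrations: np.ndarray  # (2,)
    io: float = IO_REFERENCE
    beta: float = 0.15
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain columns must have unit norm")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 < self.alpha < 50:
            raise ValueError("alpha must be in (0, 50)")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
            "io": self.io, "beta": self.beta, "alpha": self.alpha,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "StainModel":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]),
                   io=d["io"], beta=d["beta"], alpha=d["alpha"])


#: Reference stain model used when no cohort-specific reference is supplied.
#: Directions are the classic H&E OD anchors; the concentration maxima match
#: a typical well-stained tile.
DEFAULT_REFERENCE_STAIN = StainModel(
    stain_matrix=HE_STAIN_MATRIX.copy(),
    max_concentrations=np.array([1.30, 1.95]),
)


def rgb_to_od(pixels: np.ndarray, io: float = IO_REFERENCE) -> np.ndarray:
    """Optical density per channel: OD = -log10(max(I, 1) / io)."""
    I = np.maximum(pixels.astype(float), 1.0)
    return -np.log10(I / io)


def od_to_rgb(od: np.ndarray, io: float = IO_REFERENCE) -> np.ndarray:
    img = io * np.power(10.0, -od)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def fit_stain_model(patch: TilePatch, io: float = IO_REFERENCE,
                    alpha: float = 1.0, beta: float = 0.15,
                    min_tissue_pixels: int = 200) -> StainModel:
    """Estimate the two stain directions of a patch by the SVD-plane method.

    Pixels whose OD falls at or below ``beta`` in any channel are treated as
    background and excluded.  The remaining OD vectors are projected onto the
    plane of the two leading right singular vectors; the stain directions are
    the rays at the ``alpha`` and ``100 - alpha`` percentiles of the
    projection angle, sign-fixed to nonnegative OD, ordered hematoxylin
    (larger blue OD) first.
    """
    od = rgb_to_od(patch.pixels, io).reshape(-1, 3)
    tissue = od[np.all(od > beta, axis=1)]
    if tissue.shape[0] < min_tissue_pixels:
        raise ValueError(
            f"insufficient tissue: {tissue.shape[0]} pixels above OD {beta}"
        )
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    plane = vt[:2].T  # (3, 2)
    # Orient basis vectors toward the data cloud.
    for j in range(2):
        if (tissue @ plane[:, j]).sum() < 0:
            plane[:, j] = -plane[:, j]
    proj = tissue @ plane  # (N, 2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min, phi_max = np.percentile(phi, [alpha, 100 - alpha])
    v1 = plane @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v2 = plane @ np.array([np.cos(phi_max), np.sin(phi_max)])
    vecs = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        vecs.append(v / np.linalg.norm(v))
    # Hematoxylin = larger blue-channel OD.
    if vecs[0][2] < vecs[1][2]:
        vecs = vecs[::-1]
    stain = np.column_stack(vecs)
    conc, *_ = np.linalg.lstsq(stain, od.T, rcond=None)
    max_conc = np.percentile(conc, 99, axis=1)
    return StainModel(stain, max_conc, io=io, beta=beta, alpha=alpha)


def stain_concentrations(patch: TilePatch, model: StainModel) -> np.ndarray:
    """Per-pixel least-squares stain concentrations, shape (2, H, W)."""
    od = rgb_to_od(patch.pixels, model.io).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(model.stain_matrix, od.T, rcond=None)
    h, w = patch.pixels.shape[:2]
    return conc.reshape(2, h, w)


def macenko_normalize(patch: TilePatch, fitted: StainModel,
                      reference: StainModel = DEFAULT_REFERENCE_STAIN) -> TilePatch:
    """Re-render a patch through the reference stain model.

    Concentrations from the fitted model are rescaled so the fitted robust
    maxima map onto the reference maxima, then mixed through the reference
    stain matrix.  Output intensities are clipped to [0, 255].
    """
    od = rgb_to_od(patch.pixels, fitted.io).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(fitted.stain_matrix, od.T, rcond=None)
    scale = np.where(fitted.max_concentrations > 1e-12,
                     reference.max_concentrations / fitted.max_concentrations, 1.0)
    conc = conc * scale[:, None]
    od_new = (reference.stain_matrix @ conc).T
    pixels = od_to_rgb(od_new.reshape(patch.pixels.shape), reference.io)
    return TilePatch(pixels, patch.slide_id, patch.grid_row, patch.grid_col,
                     source_mpp=patch.source_mpp)
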