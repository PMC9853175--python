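"""End-to-end glue: tiles -> cells -> census vectors -> patient matrix.

``process_slide`` runs one slide's tiles through background filtering, stain
normalization, segmentation, the sparse-patch filter and morphometry,
producing a :class:`~morphocensus.census.SlideMeasurements`.  An optional
tumor classifier (or any patch predicate) restricts the census to a patch
subset; the whole-slide and tumor-region-only feature matrices therefore go
through literally the same code path, differing only in which patches enter.
``extract_cohort_features`` fits the cohort-wide bin model once on up to 50
sampled slides and assembles the patients x 135 matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .cell_features import (adaptive_intensity_threshold, attach_delaunay,
                            filter_sparse_patch, flag_small_hyperchromatic,
                            measure_cells, segment_cells, summarize_patch)
from .census import (BinModel, SlideMeasurements, assemble_patient_vector,
                     fit_bin_model, slide_feature_vector)
from .preprocess import (DEFAULT_REFERENCE_STAIN, StainModel, filter_patches,
                         fit_stain_model, macenko_normalize)
from .synthetic import Cohort, TilePatch
from .tumor_region import PatchClassifier


def process_slide(
    tiles: Iterable[TilePatch],
    slide_id: str | None = None,
    *,
    background_mode: str = "generic",
    cell_cutoff: int = 15,
    stain_reference: StainModel = DEFAULT_REFERENCE_STAIN,
    tumor_classifier: PatchClassifier | None = None,
    tumor_threshold: float = 0.5,
    patch_filter: Callable[[TilePatch], bool] | None = None,
    shc_intensity_threshold: float | None = None,
    shc_intensity_percentile: float = 40.0,
) -> SlideMeasurements:
    """Measure one slide: every kept patch yields cells with Delaunay and
    small-hyperchromatic annotations, plus a per-patch summary.

    Patches are dropped when background rules fire, when the (optional)
    tumor score falls below ``tumor_threshold``, when stain fitting finds
    insufficient tissue, or when fewer than ``cell_cutoff`` cells are
    segmented.  The hyperchromasia cutoff defaults to the slide-adaptive
    percentile of per-cell mean intensity.
    """
    tiles = list(tiles)
    if slide_id is None:
        slide_id = tiles[0].slide_id if tiles else "slide"
    kept, _ = filter_patches(tiles, mode=background_mode)
    if tumor_classifier is not None and kept:
        scores = tumor_classifier.predict_score(kept)
        kept = [p for p, s in zip(kept, scores) if s >= tumor_threshold]
    if patch_filter is not None:
        kept = [p for p in kept if patch_filter(p)]

    per_patch_cells = []
    for patch in kept:
        try:
            fitted = fit_stain_model(patch)
        except ValueError:
            continue
        normalized = macenko_normalize(patch, fitted, stain_reference)
        mask = segment_cells(normalized, stain_model=stain_reference)
        if not filter_sparse_patch(mask, cell_cutoff):
            continue
        cells = measure_cells(mask, normalized)
        attach_delaunay(cells)
        per_patch_cells.append(cells)

    all_cells = [c for cells in per_patch_cells for c in cells]
    if all_cells:
        thr = (shc_intensity_threshold if shc_intensity_threshold is not None
               else adaptive_intensity_threshold(all_cells,
                                                 shc_intensity_percentile))
        for c in all_cells:
            c.is_shc = flag_small_hyperchromatic(c, thr)
    summaries = [summarize_patch(cells) for cells in per_patch_cells]
    # Cells without Delaunay stats (single-cell patches) never pass the
    # sparse-patch cutoff in practice, but guard the census anyway.
    all_cells = [c for c in all_cells if np.isfinite(c.delaunay_min)]
    return SlideMeasurements(slide_id=slide_id, cells=all_cells,
                             patch_summaries=summaries)


@dataclass
class CohortFeatures:
    """Patient x 135 feature matrix with the bin model that produced it."""

    features: pd.DataFrame  # index patient_id, 135 named columns
    bin_model: BinModel
    slide_measurements: dict[str, SlideMeasurements]


def extract_cohort_features(
    cohort: Cohort,
    *,
    bin_model: BinModel | None = None,
    n_sample_slides: int = 50,
    seed: int = 0,
    tumor_classifier: PatchClassifier | None = None,
    patch_filter: Callable[[TilePatch], bool] | None = None,
    cell_cutoff: int = 15,
) -> CohortFeatures:
    """Run the census over a synthetic cohort.

    The bin model is fitted once on up to ``n_sample_slides`` randomly
    sampled slides and then held fixed; pass ``bin_model`` explicitly to
    reuse a previously fitted model (e.g. for a tumor-region-only rerun so
    both feature matrices share bins).
    """
    measurements: dict[str, SlideMeasurements] = {}
    for sid in cohort.slide_specs:
        tiles = [patch for patch, _ in cohort.iter_tiles(sid)]
        m = process_slide(tiles, slide_id=sid, cell_cutoff=cell_cutoff,
                          tumor_classifier=tumor_classifier,
                          patch_filter=patch_filter)
        if m.cells and m.patch_summaries:
            measurements[sid] = m
        else:
            warnings.warn(f"slide {sid} produced no usable patches; skipped")

    if bin_model is None:
        bin_model = fit_bin_model(list(measurements.values()),
                                  n_sample=n_sample_slides, seed=seed)

    rows = {}
    for _, rec in cohort.clinical.iterrows():
        vecs = [slide_feature_vector(measurements[sid], bin_model)
                for sid in rec.slide_ids.split(";") if sid in measurements]
        if not vecs:
            warnings.warn(f"patient {rec.patient_id} has no usable slides")
            continue
        rows[rec.patient_id] = assemble_patient_vector(vecs, rec.patient_id)
    features = pd.DataFrame(rows).T
    features.index.name = "patient_id"
    return CohortFeatures(features=features, bin_model=bin_model,
                          slide_measurements=measurements)
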