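"""Tumor-vs-normal patch triage.

A biopsy contains variable amounts of normal tissue, so the census can be
restricted to tumor patches before feature extraction.  The trainable
baseline here is a regularized logistic model on ~20 per-patch summary
descriptors (channel statistics, stain-concentration summaries and a
dark-object count); any external patch scorer — e.g. a CNN — can be plugged
in through :class:`ExternalPatchScorer` and used interchangeably downstream.

Training/validation splits are patient-disjoint: all patches of a patient
fall on one side of the split, so validation scores are not inflated by
within-patient correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import DEFAULT_REFERENCE_STAIN, stain_concentrations
from .synthetic import TilePatch

FEATURE_RECIPE = (
    "r_mean", "g_mean", "b_mean", "r_sd", "g_sd", "b_sd",
    "pooled_mean", "pooled_sd",
    "h_mean", "h_sd", "h_p90", "e_mean", "e_sd", "e_p90",
    "dark_fraction", "dark_object_count",
    "h_above_half", "grad_mean", "grad_sd", "saturation_mean",
)


def patch_descriptors(patch: TilePatch) -> np.ndarray:
    """Summary descriptor vector of one patch (see FEATURE_RECIPE)."""
    px = patch.pixels.astype(float)
    conc = stain_concentrations(patch, DEFAULT_REFERENCE_STAIN)
    h, e = conc[0], conc[1]
    pooled = px.mean(axis=2)
    dark = pooled < 120
    n_dark_objects = 0
    if dark.any():
        lab, n = ndi.label(dark)
        sizes = np.bincount(lab.ravel())[1:]
        n_dark_objects = int((sizes >= 20).sum())
    gy, gx = np.gradient(pooled)
    grad = np.hypot(gy, gx)
    mx, mn = px.max(axis=2), px.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1), 0.0)
    vals = [
        px[..., 0].mean(), px[..., 1].mean(), px[..., 2].mean(),
        px[..., 0].std(), px[..., 1].std(), px[..., 2].std(),
        px.mean(), px.std(),
        h.mean(), h.std(), np.percentile(h, 90),
        e.mean(), e.std(), np.percentile(e, 90),
        dark.mean(), n_dark_objects,
        (h > 0.5 * max(h.max(), 1e-9)).mean(),
        grad.mean(), grad.std(), sat.mean(),
    ]
    return np.asarray(vals, dtype=float)


@dataclass
class PatchLabelSet:
    """Labeled patches with provenance for patient-disjoint splitting."""

    patches: list[TilePatch]
    labels: np.ndarray  # 'tumor' / 'normal'
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.patient_ids = np.asarray(self.patient_ids)
        if not (len(self.patches) == len(self.labels) == len(self.patient_ids)):
            raise ValueError("patches, labels and patient_ids must align")
        bad = set(np.unique(self.labels)) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"labels must be 'tumor'/'normal'; got {bad}")

    def subset(self, idx) -> "PatchLabelSet":
        idx = np.asarray(idx)
        return PatchLabelSet([self.patches[i] for i in idx],
                             self.labels[idx], self.patient_ids[idx])

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class PatchClassifier:
    """Tumor-score model: maps any 512x512 RGB patch to a score in [0, 1]."""

    kind: str  # 'baseline' or 'external-adapter'
    feature_recipe: tuple[str, ...] = FEATURE_RECIPE
    _pipeline: Pipeline | None = None
    _scorer: Callable[[TilePatch], float] | None = None

    def predict_score(self, patches: Sequence[TilePatch]) -> np.ndarray:
        if self.kind == "external-adapter":
            return np.array([float(self._scorer(p)) for p in patches])
        X = np.stack([patch_descriptors(p) for p in patches])
        proba = self._pipeline.predict_proba(X)
        tumor_col = list(self._pipeline.classes_).index("tumor")
        return proba[:, tumor_col]


def ExternalPatchScorer(fn: Callable[[TilePatch], float]) -> PatchClassifier:
    """Wrap any callable patch -> tumor score in the classifier interface."""
    return PatchClassifier(kind="external-adapter", feature_recipe=(), _scorer=fn)


def train_patch_classifier(train: PatchLabelSet, seed: int = 0) -> PatchClassifier:
    """Fit the baseline logistic scorer on per-patch summary descriptors."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    X = np.stack([patch_descriptors(p) for p in train.patches])
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=1.0, max_iter=5000, random_state=seed)),
    ])
    pipe.fit(X, train.labels)
    clf = PatchClassifier(kind="baseline")
    clf._pipeline = pipe
    return clf


def split_by_patient(labels: PatchLabelSet, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[PatchLabelSet, PatchLabelSet]:
    """Patient-disjoint train/validation split by patient count."""
    patients = np.unique(labels.patient_ids)
    if len(patients) < 2:
        raise ValueError("split_by_patient requires >= 2 patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    n_train = int(round(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_set = set(perm[:n_train])
    tr_idx = [i for i, p in enumerate(labels.patient_ids) if p in train_set]
    va_idx = [i for i, p in enumerate(labels.patient_ids) if p not in train_set]
    return labels.subset(tr_idx), labels.subset(va_idx)


def evaluate_patch_classifier(model: PatchClassifier,
                              validation: PatchLabelSet,
                              threshold: float = 0.5
                              ) -> tuple[float, float, float]:
    """(sensitivity, specificity, F1) with tumor positive at score >= 0.5."""
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    if len(np.unique(validation.labels)) < 2:
        raise ValueError("validation set must contain both classes")
    scores = model.predict_score(validation.patches)
    pred_tumor = scores >= threshold
    is_tumor = validation.labels == "tumor"
    tp = int(np.sum(pred_tumor & is_tumor))
    fn = int(np.sum(~pred_tumor & is_tumor))
    fp = int(np.sum(pred_tumor & ~is_tumor))
    tn = int(np.sum(~pred_tumor & ~is_tumor))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return float(sens), float(spec), float(f1)
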