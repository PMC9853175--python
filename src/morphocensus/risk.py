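"""Five-year risk labeling, LASSO-Cox feature gating and classifier CV.

Patients are labeled high/low risk for a binary five-year endpoint; patients
censored before the horizon carry no label and are excluded from model
training and testing.  An L1-penalized Cox model fitted along a decreasing
penalty path, with cross-validated Harrell concordance, yields two nested
feature sets: "min" (penalty maximizing mean CV concordance) and "1se"
(largest penalty within one standard error of that maximum).  Classifiers
restricted to a selected feature set are evaluated by patient-disjoint
five-fold cross-validation with the minority class of each training fold
upsampled to the majority count; held-out predictions from all folds are
concatenated before computing sensitivity, specificity and F1 (high risk is
the positive class throughout).  An AJCC-stage rule (Stage III = high risk)
serves as the clinical baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

DAYS_PER_YEAR = 365.25
MODEL_KINDS = ("logistic", "knn", "svm", "random_forest")


# ---------------------------------------------------------------------------
# Risk labels
# ---------------------------------------------------------------------------

def assign_risk_labels(clinical: pd.DataFrame, endpoint: str,
                       horizon_years: float = 5.0) -> pd.DataFrame:
    """High/low/excluded five-year risk labels per patient.

    Survival endpoint: high = death within the horizon; low = event-free
    follow-up reaching the horizon; excluded = censored before the horizon.
    Metastasis endpoint: high = metastasis at *any* time; low =
    metastasis-free follow-up reaching the horizon; excluded otherwise.
    """
    if endpoint not in ("survival", "metastasis"):
        raise ValueError("endpoint must be 'survival' or 'metastasis'")
    tcol, ecol = (("surv_time_days", "death_event") if endpoint == "survival"
                  else ("met_time_days", "met_event"))
    t = clinical[tcol].to_numpy(dtype=float)
    e = clinical[ecol].to_numpy(dtype=int)
    if np.any(t < 0):
        raise ValueError("negative follow-up times")
    horizon = horizon_years * DAYS_PER_YEAR
    if endpoint == "survival":
        high = (e == 1) & (t <= horizon)
        low = (t >= horizon) & ~high
    else:
        high = e == 1
        low = (e == 0) & (t >= horizon)
    label = np.where(high, "high", np.where(low, "low", "excluded"))
    return pd.DataFrame({
        "patient_id": clinical["patient_id"].to_numpy(),
        "endpoint": endpoint,
        "label": label,
    })


# ---------------------------------------------------------------------------
# LASSO-Cox feature gating
# ---------------------------------------------------------------------------

@dataclass
class FeatureSetSelection:
    """Penalty path with cross-validated concordance and the two feature sets."""

    alphas: np.ndarray
    cv_concordance_mean: np.ndarray
    cv_concordance_se: np.ndarray
    alpha_min: float
    alpha_1se: float
    features_min: list[str]
    features_1se: list[str]
    coefficients: pd.DataFrame  # original-scale coefs, columns 'min' and '1se'
    coef_path: pd.DataFrame | None = None  # features x alphas, original scale

    def selected(self, which: str) -> list[str]:
        if which == "min":
            return self.features_min
        if which == "1se":
            return self.features_1se
        raise ValueError("which must be 'min' or '1se'")


def patient_folds(patient_ids, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Shuffle patients into k folds whose sizes differ by at most one."""
    ids = list(patient_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need >= {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    out = {}
    for f, idx in enumerate(folds):
        for i in idx:
            out[ids[i]] = f
    return out


def _coxnet_scores(model: CoxnetSurvivalAnalysis, X: np.ndarray,
                   alpha: float) -> np.ndarray:
    return model.predict(X, alpha=alpha)


def lasso_cox_path(X: pd.DataFrame, times, events, n_folds: int = 5,
                   seed: int = 0, n_alphas: int = 50) -> FeatureSetSelection:
    """L1-penalized Cox path with cross-validated Harrell concordance.

    Features are z-scored internally before penalization; reported
    coefficients are rescaled to the original feature units.  Ties in the
    partial likelihood are handled by the Breslow approximation.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise ValueError("lasso_cox_path requires >= 2 events")
    mu = X.mean(axis=0).to_numpy()
    sigma = X.std(axis=0, ddof=0).to_numpy()
    sigma = np.where(sigma > 0, sigma, 1.0)
    Z = (X.to_numpy() - mu) / sigma
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    path_model.fit(Z, y)
    alphas = np.asarray(path_model.alphas_)

    folds = patient_folds(range(len(X)), k=n_folds, seed=seed)
    fold_of = np.array([folds[i] for i in range(len(X))])
    cindex = np.full((n_folds, len(alphas)), np.nan)
    for f in range(n_folds):
        tr, te = fold_of != f, fold_of == f
        if events[te].sum() == 0 or events[tr].sum() < 2:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                   fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Z[tr], y[tr])
        fitted = np.asarray(m.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - a)))
            scores = m.predict(Z[te], alpha=fitted[jj])
            if np.ptp(scores) == 0:
                cindex[f, j] = 0.5
            else:
                cindex[f, j] = concordance_index_censored(
                    events[te].astype(bool), times[te], scores)[0]
    mean_c = np.nanmean(cindex, axis=0)
    n_eff = np.sum(~np.isnan(cindex), axis=0)
    se_c = np.nanstd(cindex, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))

    # alphas_ is decreasing; prefer the larger (sparser) alpha on ties.
    best = int(np.argmax(mean_c))
    alpha_min = float(alphas[best])
    thresh = mean_c[best] - se_c[best]
    ok = np.where(mean_c >= thresh)[0]
    alpha_1se = float(alphas[ok.min()])  # earliest index = largest alpha

    def _coef(alpha: float) -> np.ndarray:
        c = path_model.coef_[:, int(np.argmin(np.abs(alphas - alpha)))]
        return c / sigma  # back to original scale

    coef_min, coef_1se = _coef(alpha_min), _coef(alpha_1se)
    names = list(X.columns)
    coefficients = pd.DataFrame({"min": coef_min, "1se": coef_1se}, index=names)
    return FeatureSetSelection(
        alphas=alphas,
        cv_concordance_mean=mean_c,
        cv_concordance_se=se_c,
        alpha_min=alpha_min,
        alpha_1se=alpha_1se,
        features_min=[n for n, c in zip(names, coef_min) if c != 0],
        features_1se=[n for n, c in zip(names, coef_1se) if c != 0],
        coefficients=coefficients,
        coef_path=pd.DataFrame(path_model.coef_ / sigma[:, None], index=names,
                               columns=[f"{a:.6g}" for a in alphas]),
    )


# ---------------------------------------------------------------------------
# Balanced patient-disjoint classifier evaluation
# ---------------------------------------------------------------------------

def balance_upsample(labels, seed: int = 0) -> np.ndarray:
    """Indices with the minority class upsampled (with replacement) to the
    majority count; every original index is retained."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balance_upsample requires both classes present")
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(seed)
    majority = counts.max()
    idx = [np.arange(len(labels))]
    for cls, cnt in zip(classes, counts):
        if cnt < majority:
            pool = np.flatnonzero(labels == cls)
            idx.append(rng.choice(pool, size=majority - cnt, replace=True))
    return np.concatenate(idx)


def _make_model(kind: str, seed: int):
    if kind == "logistic":
        # ridge 1e-4 -> C = 1e4: effectively unpenalized but numerically stable
        clf = LogisticRegression(C=1e4, max_iter=5000, random_state=seed)
    elif kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif kind == "svm":
        clf = SVC(kernel="rbf", C=1.0, random_state=seed)
    elif kind == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    else:
        raise ValueError(f"unknown model kind '{kind}'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def binary_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(sensitivity, specificity, F1) with 'high' as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = np.sum((y_true == "high") & (y_pred == "high"))
    fn = np.sum((y_true == "high") & (y_pred != "high"))
    fp = np.sum((y_true != "high") & (y_pred == "high"))
    tn = np.sum((y_true != "high") & (y_pred != "high"))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return float(sens), float(spec), float(f1)


@dataclass
class ClassifierEval:
    kind: str
    sensitivity: float
    specificity: float
    f1: float
    predictions: pd.DataFrame  # patient_id, fold, label, prediction
    coefficients: pd.DataFrame | None = None  # logistic only: one row per fold


def evaluate_classifiers(X: pd.DataFrame, labels: pd.Series,
                         folds: dict, model_kinds=MODEL_KINDS,
                         seed: int = 0,
                         selected_features: list[str] | None = None
                         ) -> dict[str, ClassifierEval]:
    """Balanced patient-disjoint k-fold evaluation of each classifier kind.

    ``labels`` must contain only 'high'/'low' (excluded patients removed
    upstream); its index gives the patient ids keying ``folds``.  Held-out
    predictions of all folds are concatenated before computing metrics, so
    every labeled patient is predicted exactly once.
    """
    if selected_features is not None:
        if not selected_features:
            raise ValueError("selected feature set is empty")
        X = X[selected_features]
    if set(labels.unique()) - {"high", "low"}:
        raise ValueError("labels must be 'high'/'low' only")
    ids = list(labels.index)
    fold_of = np.array([folds[i] for i in ids])
    results = {}
    for kind in model_kinds:
        preds_rows = []
        coef_rows = []
        for f in sorted(set(fold_of)):
            tr = fold_of != f
            te = ~tr
            y_tr = labels.to_numpy()[tr]
            if len(np.unique(y_tr)) < 2:
                raise ValueError(f"training split of fold {f} is single-class")
            up = balance_upsample(y_tr, seed=seed * 1000 + f)
            model = _make_model(kind, seed)
            Xtr = X.to_numpy()[tr][up]
            model.fit(Xtr, y_tr[up])
            y_hat = model.predict(X.to_numpy()[te])
            for pid, yt, yp in zip(np.array(ids)[te], labels.to_numpy()[te], y_hat):
                preds_rows.append(dict(patient_id=pid, fold=f, label=yt,
                                       prediction=yp))
            if kind == "logistic":
                clf = model.named_steps["clf"]
                scale = model.named_steps["scale"].scale_
                sign = 1.0 if clf.classes_[1] == "high" else -1.0
                coef_rows.append(pd.Series(sign * clf.coef_[0] / scale,
                                           index=X.columns, name=f"fold{f}"))
        preds = pd.DataFrame(preds_rows)
        sens, spec, f1 = binary_metrics(preds.label, preds.prediction)
        results[kind] = ClassifierEval(
            kind=kind, sensitivity=sens, specificity=spec, f1=f1,
            predictions=preds,
            coefficients=pd.DataFrame(coef_rows) if coef_rows else None,
        )
    return results


def strong_coefficient_signs(coef_table: pd.DataFrame) -> pd.Series:
    """Signs of features whose fold-mean coefficient exceeds the fold SD.

    ``coef_table`` has one row per CV fold (as produced for the logistic
    model).  Only such "strong" features are informative for direction
    comparisons; weak ones flip sign by noise.
    """
    mean = coef_table.mean(axis=0)
    sd = coef_table.std(axis=0, ddof=1).fillna(0.0)
    strong = mean.abs() > sd
    return np.sign(mean[strong])


def sign_agreement(signs_a: pd.Series, signs_b: pd.Series) -> float:
    """Fraction of features strong in both runs whose signs agree."""
    common = signs_a.index.intersection(signs_b.index)
    if len(common) == 0:
        return float("nan")
    return float((signs_a[common] == signs_b[common]).mean())


def stage_baseline(clinical: pd.DataFrame, labels: pd.DataFrame) -> ClassifierEval:
    """AJCC-stage rule: predict high risk iff Stage III."""
    lab = labels[labels.label != "excluded"]
    merged = lab.merge(clinical[["patient_id", "stage"]], on="patient_id",
                       how="left")
    missing = merged.loc[merged.stage.isna(), "patient_id"].tolist()
    if missing:
        raise ValueError(f"missing stage for patients: {missing}")
    pred = np.where(merged.stage == "III", "high", "low")
    sens, spec, f1 = binary_metrics(merged.label, pred)
    preds = pd.DataFrame(dict(patient_id=merged.patient_id, fold=-1,
                              label=merged.label, prediction=pred))
    return ClassifierEval("stage_baseline", sens, spec, f1, preds)
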