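"""Individual-level classification from estimated latent factors.

Leave-one-out cross-validated logistic (or SVM) models on SIFA scores, with
ROC/AUC summaries (DeLong confidence intervals) and threshold metrics.  Two
cross-validation protocols are supported:

- ``transductive`` (default): factor scores are estimated once on all
  subjects and only the classifier is cross-validated;
- ``strict``: within each fold the factor model itself is refitted on the
  n-1 training subjects and the held-out subject is scored by closed-form
  posterior conditioning, so no held-out information reaches training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .data_model import DataModelError, MultiModalDataset
from .sifa import SIFARanks, em_fit, posterior_scores

CLASSIFIERS = ("logistic", "svm-linear", "svm-poly", "svm-radial")


@dataclass
class ROCResult:
    probabilities: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    threshold: float
    youden_threshold: float
    model_tag: str = ""
    classifier_tag: str = ""


def _make_classifier(tag: str, seed: int):
    if tag == "logistic":
        return LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    kernel = {"svm-linear": "linear", "svm-poly": "poly", "svm-radial": "rbf"}.get(tag)
    if kernel is None:
        raise DataModelError(f"unknown classifier {tag!r}")
    return SVC(kernel=kernel, probability=True, random_state=seed)


def _fit_predict(clf_tag, seed, Xtr, ytr, Xte):
    clf = _make_classifier(clf_tag, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(Xtr, ytr)
        except ConvergenceWarning:
            # separation: refit with a whisper of ridge
            if clf_tag == "logistic":
                clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xtr, ytr)
        return clf.predict_proba(Xte)[:, 1]


def loocv_predict(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "logistic",
    mode: str = "transductive",
    ds: MultiModalDataset | None = None,
    ranks: SIFARanks | None = None,
    em_kwargs: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-out cross-validated class-1 probabilities.

    In ``strict`` mode ``features`` is ignored; ``ds`` and ``ranks`` define
    the per-fold factor refit, and the held-out subject is scored via
    posterior conditioning under the training-fold model.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DataModelError("binary labels required")
    y = (labels == classes[1]).astype(int)
    n = len(y)
    if n < 10:
        raise DataModelError("need n >= 10 for leave-one-out evaluation")
    probs = np.empty(n)
    if mode == "transductive":
        X = np.asarray(features, float)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            if len(np.unique(y[tr])) < 2:
                raise DataModelError("a class is absent from a training fold")
            probs[i] = _fit_predict(classifier, seed, X[tr], y[tr], X[i : i + 1])[0]
    elif mode == "strict":
        if ds is None or ranks is None:
            raise DataModelError("strict mode needs ds and ranks")
        em_kwargs = dict(em_kwargs or {})
        em_kwargs.setdefault("tol", 1e-6)
        em_kwargs.setdefault("max_iter", 200)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            if len(np.unique(y[tr])) < 2:
                raise DataModelError("a class is absent from a training fold")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = em_fit(ds.subset(tr), ranks, **em_kwargs)
            Xtr = np.hstack([fit.U0_hat] + fit.Uk_hat)
            U0_te, Uk_te = posterior_scores(fit.model, ds.subset([i]))
            Xte = np.hstack([U0_te] + Uk_te)
            probs[i] = _fit_predict(classifier, seed, Xtr, y[tr], Xte)[0]
    else:
        raise DataModelError(f"unknown mode {mode!r}")
    return probs


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_auc_ci(
    probabilities: np.ndarray, labels01: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """AUC by the Mann–Whitney statistic with midrank ties, and its DeLong
    variance/CI.  Returns (auc, (lo, hi), variance)."""
    scores = np.asarray(probabilities, float)
    y = np.asarray(labels01, int)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DataModelError("both classes required")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    V10 = (all_r[:m] - pos_r) / n  # structural components for positives
    V01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = V10.mean()
    if m > 1 and n > 1:
        var = np.var(V10, ddof=1) / m + np.var(V01, ddof=1) / n
    else:
        var = np.nan
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var) if np.isfinite(var) else np.nan
    lo = max(0.0, auc - half) if np.isfinite(half) else np.nan
    hi = min(1.0, auc + half) if np.isfinite(half) else np.nan
    return float(auc), (float(lo), float(hi)), float(var)


def threshold_metrics(
    probabilities: np.ndarray, labels01: np.ndarray, threshold: float = 0.5
) -> dict:
    """Confusion-matrix metrics at a probability threshold, plus the
    Youden-J-optimal threshold."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels01, int)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    fpr, tpr, thr = roc_curve(y, p)
    youden = float(thr[np.argmax(tpr - fpr)])
    return {
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
        "accuracy": (tp + tn) / len(y),
        "youden_threshold": youden,
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def roc_auc(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    level: float = 0.95,
    model_tag: str = "",
    classifier_tag: str = "",
) -> ROCResult:
    """Cross-validated ROC summary: curve points at every distinct
    threshold, AUC with DeLong CI, and threshold metrics."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DataModelError("both classes required")
    y = (labels == classes[1]).astype(int)
    p = np.asarray(probabilities, float)
    if np.all(p == p[0]):
        warnings.warn("constant probabilities: degenerate ROC", RuntimeWarning)
        auc, ci = 0.5, (np.nan, np.nan)
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    else:
        auc, ci, _ = delong_auc_ci(p, y, level)
        fpr, tpr, _ = roc_curve(y, p)
    tm = threshold_metrics(p, y, threshold)
    return ROCResult(
        probabilities=p,
        labels=y,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_ci=ci,
        sensitivity=tm["sensitivity"],
        specificity=tm["specificity"],
        f1=tm["f1"],
        accuracy=tm["accuracy"],
        threshold=threshold,
        youden_threshold=tm["youden_threshold"],
        model_tag=model_tag,
        classifier_tag=classifier_tag,
    )


# ---------------------------------------------------------------------------
# Modality comparison grid
# ---------------------------------------------------------------------------

def _single_block_dataset(ds: MultiModalDataset, modality: str) -> MultiModalDataset:
    return MultiModalDataset([ds.block(modality)], ds.covariates)


def drop_group_covariates(ds: MultiModalDataset) -> MultiModalDataset:
    """Remove group-dummy columns from the covariate design.

    Factor scores are posterior means given both data and covariates; if the
    group dummies stay in the design, the class label reaches the
    'predictive' features through the score prior (Y B) and classification
    becomes circular.  Factors used for prediction are therefore estimated
    with nuisance covariates only.
    """
    from .data_model import CovariateDesign

    cov = ds.covariates
    keep = [j for j, c in enumerate(cov.column_names)
            if not c.startswith("group_")]
    new_cov = CovariateDesign(
        Y=cov.Y[:, keep],
        column_names=[cov.column_names[j] for j in keep],
        group_labels=cov.group_labels,
        subject_ids=list(cov.subject_ids),
        encoding_spec=dict(cov.encoding_spec),
        allow_zero_columns=True,
    )
    return MultiModalDataset(ds.blocks, new_cov, ds.standardization)


def modality_comparison(
    ds: MultiModalDataset,
    ranks: SIFARanks,
    contrast: tuple[str, str],
    classifiers=("logistic",),
    mode: str = "transductive",
    em_kwargs: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """AUC(CI) grid over feature sets x classifiers for one group contrast.

    Feature sets: all modalities (common + individual factors of the full
    fit) and each single modality (factors of a one-block refit with the
    same per-block factor budget).  Returns (grid, {(set, clf): ROCResult}).
    """
    em_kwargs = dict(em_kwargs or {})
    ga, gb = contrast
    keep = np.flatnonzero(np.isin(ds.covariates.group_labels, [ga, gb]))
    sub = drop_group_covariates(ds.subset(keep))
    labels = (sub.covariates.group_labels == gb).astype(int)

    feature_sets: dict[str, tuple[MultiModalDataset, SIFARanks]] = {
        "all": (sub, ranks)
    }
    for k, blk in enumerate(ds.blocks):
        feature_sets[blk.modality] = (
            _single_block_dataset(sub, blk.modality),
            SIFARanks(ranks.r0, (ranks.r[k],)),
        )

    rows, results = [], {}
    for set_name, (d, rk) in feature_sets.items():
        if mode == "transductive":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = em_fit(d, rk, **em_kwargs)
            feats = np.hstack([fit.U0_hat] + fit.Uk_hat)
        else:
            feats = None
        row = {"feature_set": set_name}
        for clf in classifiers:
            probs = loocv_predict(
                feats, labels, classifier=clf, mode=mode,
                ds=d, ranks=rk, em_kwargs=em_kwargs, seed=seed,
            )
            res = roc_auc(probs, labels, model_tag=set_name, classifier_tag=clf)
            results[(set_name, clf)] = res
            row[f"{clf}_auc"] = res.auc
            row[f"{clf}_ci"] = f"{res.auc:.2f} ({res.auc_ci[0]:.2f}-{res.auc_ci[1]:.2f})"
        rows.append(row)
    return pd.DataFrame(rows), results
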