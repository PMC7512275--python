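"""Random-forest classification from entropy feature vectors.

Two tasks:

* Condition (control vs CP): each subject is a 15-vector of per-channel
  mean entropy; a random forest is validated by leave-one-out
  cross-validation, pooling the out-of-fold class probabilities into a
  single ROC curve and AUC.  Feature importance is measured by the AUC
  drop when one channel is deleted and the whole LOO procedure rerun —
  near-zero (or negative) drops flag channels whose information is
  redundant with the rest.
* GMFCS staging (healthy, I-IV as five ordered classes): per-cycle
  15-vectors, leave-one-subject-out by default so no cycle of the
  held-out subject leaks into training.  Agreement is summarized by the
  weighted Cohen's kappa with a subject-bootstrap CI, and feature
  importance by the increase in classification error when a channel is
  randomly permuted.

Forest hyperparameters (500 trees, sqrt(15) features per split,
unlimited depth) follow common random-forest practice and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    auc as _auc,
    cohen_kappa_score,
    confusion_matrix,
    roc_curve,
)

from .channels import CHANNEL_LABELS

GMFCS_CLASSES = ("healthy", "I", "II", "III", "IV")


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters shared by both tasks."""

    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None

    def build(self, seed: int | None) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=seed,
        )


@dataclass
class ConditionClassifierReport:
    roc_points: np.ndarray  # (n_thresholds, 2): (fall-out, sensitivity)
    auc: float
    scores: pd.Series  # out-of-fold CP probability per subject
    auc_drop: dict[str, float] = field(default_factory=dict)


@dataclass
class GMFCSClassifierReport:
    confusion: pd.DataFrame  # 5x5, rows = truth, cols = predicted
    weighted_kappa: float
    kappa_ci: tuple[float, float]
    permutation_importance: dict[str, float]
    predictions: pd.DataFrame  # cycle-level truth/prediction/subject


def _validate_features(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in CHANNEL_LABELS if c in features.columns]
    cols += [
        c
        for c in features.columns
        if c not in cols and c not in ("subject_id", "side", "cycle_id")
    ]
    X = features[cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    return X, cols


def _loo_scores(
    X: np.ndarray, y: np.ndarray, rf: RFConfig, seed: int
) -> np.ndarray:
    """Out-of-fold positive-class probability for every instance."""
    scores = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        clf = rf.build(seed)
        clf.fit(X[mask], y[mask])
        pos = list(clf.classes_).index(1)
        scores[i] = clf.predict_proba(X[i][None, :])[0, pos]
    return scores


def loo_condition_rf(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
) -> ConditionClassifierReport:
    """Leave-one-out condition classification from subject mean entropy.

    ``features`` is the per-subject 15-channel frame from
    :func:`gaitpe.entropy.subject_mean_pe`; ``labels`` the matching
    condition strings.  The forest is retrained once per held-out
    subject; the pooled out-of-fold CP probabilities give the ROC curve
    and its AUC.
    """
    X, _ = _validate_features(features)
    y = np.asarray([1 if c == "cp" else 0 for c in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both conditions must be present")
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("each condition needs >= 2 subjects")
    scores = _loo_scores(X, y, rf_config, seed)
    fpr, tpr, _ = roc_curve(y, scores)
    return ConditionClassifierReport(
        roc_points=np.column_stack([fpr, tpr]),
        auc=float(_auc(fpr, tpr)),
        scores=pd.Series(scores, index=features.index, name="p_cp"),
    )


def feature_drop_importance(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
) -> dict[str, float]:
    """AUC drop when each channel is deleted and LOO-CV rerun in full.

    Positive values mark channels the classifier cannot do without;
    values near zero (or negative) mark channels whose signal other
    channels carry as well.
    """
    X, cols = _validate_features(features)
    y = np.asarray([1 if c == "cp" else 0 for c in labels])
    full_auc = loo_condition_rf(features, labels, rf_config, seed).auc
    drops: dict[str, float] = {}
    for j, ch in enumerate(cols):
        X_wo = np.delete(X, j, axis=1)
        scores = _loo_scores(X_wo, y, rf_config, seed)
        fpr, tpr, _ = roc_curve(y, scores)
        drops[ch] = full_auc - float(_auc(fpr, tpr))
    return drops


def weighted_kappa(
    truth: Sequence[str],
    predicted: Sequence[str],
    weights: str = "linear",
    categories: Sequence[str] = GMFCS_CLASSES,
) -> float:
    """Chance-corrected ordinal agreement between two label sequences.

    Disagreement between categories ``i`` and ``j`` is weighted by their
    ordinal distance (``linear``) or its square (``quadratic``); perfect
    agreement gives 1, chance-level agreement 0.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError(f"unknown weighting {weights!r}")
    cats = list(categories)
    code = {c: i for i, c in enumerate(cats)}
    try:
        y1 = [code[c] for c in truth]
        y2 = [code[c] for c in predicted]
    except KeyError as err:
        raise ValueError(f"label {err.args[0]!r} not in categories {cats}") from err
    if len(y1) != len(y2):
        raise ValueError("label sequences differ in length")
    return float(
        cohen_kappa_score(y1, y2, weights=weights, labels=list(range(len(cats))))
    )


def gmfcs_permutation_importance(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Per-channel increase in classification error under permutation.

    A forest is fitted on all cycles; each channel is then shuffled
    across cycles ``n_repeats`` times and the mean rise in
    misclassification rate recorded.  Channels the forest leans on show
    large increases; uninformative channels stay near zero.
    """
    X, cols = _validate_features(features)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    clf = rf_config.build(seed)
    clf.fit(X, y)
    base_err = float(np.mean(clf.predict(X) != y))
    importance: dict[str, float] = {}
    for j, ch in enumerate(cols):
        errs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            errs.append(float(np.mean(clf.predict(Xp) != y)))
        importance[ch] = float(np.mean(errs)) - base_err
    return importance


def loo_gmfcs_rf(
    cycle_features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
    unit: str = "subject",
    kappa_weights: str = "linear",
    kappa_ci_replicates: int = 2000,
) -> GMFCSClassifierReport:
    """Five-class GMFCS staging of gait cycles with cross-validated kappa.

    ``cycle_features`` must carry a ``subject_id`` column plus the 15
    channel columns; ``labels`` the per-cycle stage in
    ``("healthy", "I", "II", "III", "IV")``.  With ``unit="subject"``
    (default) every cycle of one subject is held out together, so
    subject identity cannot leak; ``unit="cycle"`` holds out one cycle
    at a time.  The kappa CI resamples subjects with replacement over
    the out-of-fold predictions (percentile interval).
    """
    if "subject_id" not in cycle_features.columns:
        raise ValueError("cycle_features must carry a subject_id column")
    if unit not in ("subject", "cycle"):
        raise ValueError(f"unknown unit {unit!r}")
    X, _ = _validate_features(cycle_features)
    y = np.asarray(labels)
    present = set(y)
    for cls in present:
        if cls not in GMFCS_CLASSES:
            raise ValueError(f"unknown stage label {cls!r}")
    for cls in GMFCS_CLASSES:
        if np.sum(y == cls) < 2:
            raise ValueError(f"stage {cls!r} has fewer than 2 cycles")
    groups = cycle_features["subject_id"].to_numpy()

    folds = (
        [groups == g for g in np.unique(groups)]
        if unit == "subject"
        else [np.arange(len(y)) == i for i in range(len(y))]
    )
    pred = np.empty(len(y), dtype=object)
    for held in folds:
        clf = rf_config.build(seed)
        clf.fit(X[~held], y[~held])
        pred[held] = clf.predict(X[held])
    pred = pred.astype(str)

    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=list(GMFCS_CLASSES)),
        index=list(GMFCS_CLASSES),
        columns=list(GMFCS_CLASSES),
    )
    kappa = weighted_kappa(y, pred, weights=kappa_weights)

    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    boots = []
    for _ in range(kappa_ci_replicates):
        draw = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([np.flatnonzero(groups == g) for g in draw])
        if len(set(y[idx])) < 2:
            continue
        boots.append(weighted_kappa(y[idx], pred[idx], weights=kappa_weights))
    ci = tuple(np.quantile(boots, [0.025, 0.975])) if boots else (kappa, kappa)

    importance = gmfcs_permutation_importance(
        cycle_features, y, rf_config=rf_config, seed=seed
    )
    return GMFCSClassifierReport(
        confusion=conf,
        weighted_kappa=kappa,
        kappa_ci=(float(ci[0]), float(ci[1])),
        permutation_importance=importance,
        predictions=pd.DataFrame(
            {"subject_id": groups, "truth": y, "predicted": pred}
        ),
    )
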