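"""Random-forest reading-profile classifier.

The classifier sees each participant's age and five test scores only —
sex and site inform imputation but never classification — and is a
500-tree random forest with 2 candidate predictors per split (mtry = 2),
optionally tuned by repeated cross-validation (fivefold, 10 repeats)
over a small mtry grid.  Multiply-imputed datasets are classified per
imputation; a consensus label per row is the modal label across
imputations with a fixed tie-break, and per-profile counts are reported
as mean +/- SD across imputations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from ._rng import child_int_seed
from .imputation import ImputationSet
from .tabular_io import CLASSIFICATION_VARS, PROFILES, BehavioralTable

#: Classification features, in fixed order.
FEATURE_ORDER = ("age",) + CLASSIFICATION_VARS

#: Tie-break priority for consensus labels (highest priority first).
TIE_BREAK_ORDER = ("Control", "PoorDecoder", "PoorComprehender", "GenerallyPoorReader")


class ClassifierError(ValueError):
    pass


@dataclass
class ClassifierModel:
    estimator: RandomForestClassifier
    mtry: int
    n_trees: int
    feature_order: tuple[str, ...]
    training_seed: int
    tuning_record: pd.DataFrame | None = None


@dataclass
class ConfusionSummary:
    """Accuracy plus one-vs-rest sensitivity/specificity per profile."""

    accuracy: float
    sensitivity: dict
    specificity: dict

    def reduction_from(self, baseline: "ConfusionSummary") -> "ConfusionSummary":
        """Degradation vs a baseline, in percentage points (positive = worse)."""
        return ConfusionSummary(
            accuracy=100.0 * (baseline.accuracy - self.accuracy),
            sensitivity={
                c: 100.0 * (baseline.sensitivity[c] - self.sensitivity[c])
                if np.isfinite(self.sensitivity[c]) and np.isfinite(baseline.sensitivity[c])
                else np.nan
                for c in PROFILES
            },
            specificity={
                c: 100.0 * (baseline.specificity[c] - self.specificity[c])
                for c in PROFILES
            },
        )


@dataclass
class ClassificationResult:
    per_imputation_labels: np.ndarray  # m x N
    pooled_labels: np.ndarray  # N
    profile_counts: pd.DataFrame  # index = profile, columns = mean, sd
    baseline_labels: np.ndarray | None = None


def _feature_matrix(table: BehavioralTable) -> np.ndarray:
    sub = table.df[list(FEATURE_ORDER)]
    if sub.isna().any().any():
        raise ClassifierError(
            "classification features contain missing cells; impute before classifying"
        )
    return sub.to_numpy(float)


def train_classifier(
    training: BehavioralTable,
    seed: int = 0,
    tune: bool = True,
    mtry: int = 2,
    n_trees: int = 500,
    mtry_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    cv_folds: int = 5,
    cv_repeats: int = 10,
    class_weight=None,
) -> ClassifierModel:
    """Fit the profile classifier on a complete, labeled training table.

    With ``tune=True`` the number of candidate predictors per split is
    selected by repeated stratified cross-validation over ``mtry_grid``
    before the final 500-tree fit; ``tune=False`` pins ``mtry`` directly.
    Class imbalance is left unweighted by default (the four profiles are
    classified as-is); pass ``class_weight="balanced"`` to reweight.
    """
    if not training.has_labels:
        raise ClassifierError("training table must be labeled")
    X = _feature_matrix(training)
    y = training.labels.to_numpy()
    # canonicalize row order so training is invariant to row permutation
    order = np.lexsort(tuple(X.T) + (y,))
    X, y = X[order], y[order]
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ClassifierError("need at least 2 rows per profile to train")
    rf_seed = child_int_seed(seed, "rf-train")
    record = None
    if tune:
        cv = RepeatedStratifiedKFold(
            n_splits=cv_folds, n_repeats=cv_repeats,
            random_state=child_int_seed(seed, "rf-tune"),
        )
        rows = []
        for cand in mtry_grid:
            est = RandomForestClassifier(
                n_estimators=n_trees, max_features=cand, random_state=rf_seed,
                class_weight=class_weight, n_jobs=1,
            )
            scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy", n_jobs=1)
            rows.append({"mtry": cand, "cv_accuracy": float(scores.mean())})
        record = pd.DataFrame(rows)
        mtry = int(record.loc[record["cv_accuracy"].idxmax(), "mtry"])
    est = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=rf_seed,
        class_weight=class_weight, n_jobs=1,
    )
    est.fit(X, y)
    return ClassifierModel(
        estimator=est,
        mtry=mtry,
        n_trees=n_trees,
        feature_order=FEATURE_ORDER,
        training_seed=seed,
        tuning_record=record,
    )


def classify(model: ClassifierModel, table: BehavioralTable) -> np.ndarray:
    """Majority-vote label per row; raises if any feature cell is missing."""
    return model.estimator.predict(_feature_matrix(table))


def loo_accuracy(
    table: BehavioralTable, mtry: int = 2, n_trees: int = 500, seed: int = 0
) -> float:
    """Leave-one-out cross-validated accuracy of the profile classifier."""
    X = _feature_matrix(table)
    y = table.labels.to_numpy()
    rf_seed = child_int_seed(seed, "rf-loo")
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        est = RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry, random_state=rf_seed, n_jobs=1
        )
        est.fit(X[keep], y[keep])
        correct += int(est.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def _modal_labels(label_matrix: np.ndarray) -> np.ndarray:
    """Per-row modal label across imputations with fixed tie-break priority."""
    m, n = label_matrix.shape
    pooled = np.empty(n, dtype=object)
    for i in range(n):
        vals, counts = np.unique(label_matrix[:, i], return_counts=True)
        best = counts.max()
        tied = set(vals[counts == best])
        pooled[i] = next(c for c in TIE_BREAK_ORDER if c in tied)
    return pooled


def classify_imputed(
    model: ClassifierModel,
    imps: ImputationSet,
    baseline_table: BehavioralTable | None = None,
) -> ClassificationResult:
    """Classify each imputed table; pool labels and per-profile counts."""
    labels = np.stack([classify(model, t) for t in imps.tables])
    pooled = _modal_labels(labels)
    per_imp_counts = pd.DataFrame(
        [{c: int((row == c).sum()) for c in PROFILES} for row in labels]
    )
    counts = pd.DataFrame(
        {"mean": per_imp_counts.mean(axis=0), "sd": per_imp_counts.std(axis=0, ddof=1 if imps.m > 1 else 0)}
    )
    baseline = classify(model, baseline_table) if baseline_table is not None else None
    return ClassificationResult(
        per_imputation_labels=labels,
        pooled_labels=pooled,
        profile_counts=counts,
        baseline_labels=baseline,
    )


def save_model(model: ClassifierModel, path) -> None:
    """Persist the fitted ensemble (joblib) with a JSON sidecar of
    hyperparameters and the tuning record."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": 1,
        "mtry": model.mtry,
        "n_trees": model.n_trees,
        "feature_order": list(model.feature_order),
        "training_seed": model.training_seed,
        "tuning_record": (
            model.tuning_record.to_dict("records") if model.tuning_record is not None else None
        ),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> ClassifierModel:
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    record = meta["tuning_record"]
    return ClassifierModel(
        estimator=joblib.load(path),
        mtry=meta["mtry"],
        n_trees=meta["n_trees"],
        feature_order=tuple(meta["feature_order"]),
        training_seed=meta["training_seed"],
        tuning_record=pd.DataFrame(record) if record is not None else None,
    )


def confusion_metrics(predicted, truth) -> ConfusionSummary:
    """Accuracy and one-vs-rest sensitivity/specificity over the 4 profiles.

    A profile absent from the truth vector has undefined sensitivity
    (reported as NaN).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ClassifierError("predicted and truth must have equal length")
    bad = (set(predicted) | set(truth)) - set(PROFILES)
    if bad:
        raise ClassifierError(f"labels outside the profile vocabulary: {sorted(bad)}")
    n = len(truth)
    accuracy = float((predicted == truth).mean())
    sens, spec = {}, {}
    for c in PROFILES:
        tp = int(((predicted == c) & (truth == c)).sum())
        fn = int(((predicted != c) & (truth == c)).sum())
        tn = int(((predicted != c) & (truth != c)).sum())
        fp = int(((predicted == c) & (truth != c)).sum())
        sens[c] = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec[c] = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return ConfusionSummary(accuracy=accuracy, sensitivity=sens, specificity=spec)
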