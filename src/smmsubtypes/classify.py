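"""Random-forest subtype classifier for external cohorts.

Subtypes discovered in a primary cohort are transferred to unseen cohorts by
a random forest trained on the features shared between the cohorts (and
carried by a minimum number of primary-cohort patients), with stratified
k-fold cross-validation and a randomized hyperparameter search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold

from .alterations import AlterationMatrix

logger = logging.getLogger(__name__)

# search space for the randomized grid search; tree count, depth and
# features-per-split dominate forest behaviour on small binary matrices
DEFAULT_PARAM_GRID = {
    "n_estimators": [100, 200, 300],
    "max_depth": [None, 5, 10, 20],
    "max_features": ["sqrt", 0.3, 0.5],
    "min_samples_leaf": [1, 2, 4],
}


def select_shared_features(
    cohort_a: AlterationMatrix,
    cohort_b: AlterationMatrix,
    min_patients: int = 3,
) -> list[str]:
    """Features present in both catalogs and carried by at least
    ``min_patients`` patients of cohort_a, in cohort_a order."""
    in_b = set(cohort_b.feature_ids)
    counts = cohort_a.values.sum(axis=0)
    shared = [
        f
        for f, cnt in zip(cohort_a.feature_ids, counts)
        if f in in_b and cnt >= min_patients
    ]
    if not shared:
        raise ValueError("no shared features meet the carrier threshold")
    return shared


@dataclass
class SubtypeModel:
    """A trained subtype classifier with its CV record."""

    feature_ids: list[str]
    estimator: RandomForestClassifier
    classes: list
    cv_folds: int
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    search_record: pd.DataFrame = field(repr=False, default=None)
    seed: int = 0

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "SubtypeModel":
        model = joblib.load(Path(path))
        if not isinstance(model, SubtypeModel):
            raise TypeError(f"{path} does not contain a SubtypeModel")
        return model


def train_subtype_classifier(
    X: AlterationMatrix,
    labels: Sequence,
    seed: int = 0,
    cv_folds: int = 5,
    search_iters: int = 50,
    param_grid: dict | None = None,
) -> SubtypeModel:
    """Train a random forest with randomized hyperparameter search.

    Stratified ``cv_folds``-fold CV accuracy scores each sampled
    configuration; the best configuration's mean/sd are recorded and the
    final model is refit on all data. Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if y.shape[0] != X.n_patients:
        raise ValueError("labels must cover all patients")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < cv_folds]
    if small.size:
        raise ValueError(
            f"class(es) {list(small)} have fewer than cv_folds={cv_folds} members"
        )
    grid = param_grid or DEFAULT_PARAM_GRID
    n_grid = int(np.prod([len(v) for v in grid.values()]))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        param_distributions=grid,
        n_iter=min(search_iters, n_grid),
        scoring="accuracy",
        cv=cv,
        random_state=seed,
        refit=True,
        n_jobs=1,
    )
    search.fit(X.values, y)
    record = pd.DataFrame(search.cv_results_)
    best = search.best_index_
    return SubtypeModel(
        feature_ids=list(X.feature_ids),
        estimator=search.best_estimator_,
        classes=list(search.best_estimator_.classes_),
        cv_folds=cv_folds,
        cv_accuracy_mean=float(record.loc[best, "mean_test_score"]),
        cv_accuracy_sd=float(record.loc[best, "std_test_score"]),
        search_record=record,
        seed=seed,
    )


def predict_subtypes(
    model: SubtypeModel,
    X_new: AlterationMatrix,
    allow_missing: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign subtypes to an unseen cohort.

    Returns per-patient argmax labels (ties broken by lowest class index)
    and the full probability table. Features the model expects but the new
    cohort lacks raise an error unless ``allow_missing``, in which case they
    are zero-filled with a logged warning.
    """
    missing = [f for f in model.feature_ids if f not in X_new.feature_ids]
    if missing:
        if not allow_missing:
            raise ValueError(f"cohort lacks model features: {missing}")
        logger.warning("zero-filling %d missing feature(s): %s", len(missing), missing)
    frame = X_new.to_frame().reindex(columns=model.feature_ids, fill_value=0)
    proba = model.estimator.predict_proba(frame.to_numpy())
    # argmax with lowest-index tie-break (np.argmax is first-max)
    labels = np.asarray(model.classes)[np.argmax(proba, axis=1)]
    proba_df = pd.DataFrame(
        proba, index=X_new.patient_ids, columns=[str(c) for c in model.classes]
    )
    return labels, proba_df
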