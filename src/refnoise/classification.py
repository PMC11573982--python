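"""Classifier training under stratified cross-validation.

Two classifiers sit behind one interface: a random forest (``rf``) and an
L1-penalized logistic regression with a cross-validated penalty
(``lasso_logistic``).  Training yields pooled out-of-fold scores on the
training samples (the training evaluation surface) plus a final model refit
on the full training set, which scores the untouched hold-out samples.

Anti-leakage contract: standardization statistics are computed within each
training fold (inside the sklearn pipeline), and no hold-out sample ever
reaches the fitting path.  By default the feature selection feeding each
fold's model is likewise re-run on that fold's training portion
(``selector_fn``): selecting once on the full training set and then scoring
out-of-fold lets chance label-correlated features leak into every fold and
inflates the training surfaces, most visibly at heavy label noise where the
out-of-fold AUC against the permuted labels should approach 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .data_model import FeatureTable, ValidationError
from .feature_selection import SelectionResult
from .reference_permutation import PermutedReference

log = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("rf", "lasso_logistic")


@dataclass(frozen=True)
class PipelineSpec:
    """One cell of the selector x classifier grid."""

    selector: str
    classifier: str
    cv_folds: int
    seed: int = 0

    def __post_init__(self):
        if self.classifier not in CLASSIFIER_NAMES:
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    @property
    def name(self) -> str:
        return f"{self.selector}+{self.classifier}"


@dataclass
class PredictionSet:
    """Out-of-fold training scores, fold assignment, and the refit final model."""

    sample_ids: tuple[str, ...]
    oof_scores: np.ndarray
    fold_assignment: np.ndarray
    model: object
    feature_names: tuple[str, ...]
    holdout_scores: np.ndarray | None = None


def default_cv_folds(n_train: int) -> int:
    """10-fold when the training set is large (>= 150 samples), else 5-fold."""
    return 10 if n_train >= 150 else 5


def build_classifier(name: str, seed: int, rf_n_estimators: int = 500):
    """Construct an unfitted classifier with documented default parameters."""
    if name == "rf":
        return RandomForestClassifier(
            n_estimators=rf_n_estimators, max_features="sqrt",
            random_state=seed, n_jobs=1,
        )
    if name == "lasso_logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegressionCV(
                        Cs=np.logspace(-2, 2, 8),
                        penalty="l1",
                        solver="liblinear",
                        scoring="neg_log_loss",
                        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
                        random_state=seed,
                        max_iter=1000,
                    ),
                ),
            ]
        )
    raise ValidationError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


def crossval_train(
    table: FeatureTable,
    permuted: PermutedReference,
    selection: SelectionResult,
    spec: PipelineSpec,
    rf_n_estimators: int = 500,
    selector_fn=None,
) -> PredictionSet:
    """Stratified K-fold training on the (possibly permuted) training labels.

    Folds are stratified on the permuted labels; each fold's model is fit on
    the complement and scored on the fold, giving every training sample
    exactly one out-of-fold class-1 probability.  When ``selector_fn`` is
    given (signature ``(fold_table, fold_labels, fold_index) ->
    SelectionResult``) the feature subset for each fold's model is re-derived
    on that fold's training portion, so out-of-fold scores are free of
    selection leakage; otherwise the supplied ``selection`` is used for every
    fold.  The final model — used for hold-out scoring — is always refit on
    the full training set with the supplied ``selection``.  Deterministic
    given ``spec.seed``.
    """
    if table.sample_ids != permuted.sample_ids:
        raise ValidationError("feature table and permuted reference are not aligned")
    y = permuted.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("permuted labels contain a single class")

    minority = int(min(np.bincount(y)))
    folds = spec.cv_folds
    if minority < folds:
        log.warning("reducing CV folds from %d to %d (minority class has %d members)",
                    folds, minority, minority)
        folds = minority
    if folds < 2:
        raise ValidationError("minority class too small for cross-validation")

    proto = build_classifier(spec.classifier, spec.seed, rf_n_estimators)
    skf = StratifiedKFold(folds, shuffle=True, random_state=spec.seed)
    ids = np.asarray(table.sample_ids, dtype=object)
    oof = np.full(len(y), np.nan)
    fold_assignment = np.full(len(y), -1, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        for fold, (tr, te) in enumerate(skf.split(ids, y)):
            if selector_fn is None:
                fold_features = selection.selected
            else:
                fold_table = table.subset_rows(ids[tr])
                fold_features = selector_fn(fold_table, y[tr], fold).selected
            X = table.select_features(fold_features).values
            model = clone(proto)
            model.fit(X[tr], y[tr])
            oof[te] = model.predict_proba(X[te])[:, 1]
            fold_assignment[te] = fold
        assert not np.isnan(oof).any()

        final = clone(proto)
        final.fit(table.select_features(selection.selected).values, y)
    return PredictionSet(
        sample_ids=table.sample_ids,
        oof_scores=oof,
        fold_assignment=fold_assignment,
        model=final,
        feature_names=tuple(selection.selected),
    )


def predict_holdout(prediction: PredictionSet, test_table: FeatureTable) -> np.ndarray:
    """Score hold-out samples with the final model refit on training data.

    Test features are restricted to the selected columns (error if any is
    missing) and transformed with training-set statistics only.
    """
    X = test_table.select_features(prediction.feature_names).values
    scores = prediction.model.predict_proba(X)[:, 1]
    prediction.holdout_scores = scores
    return scores
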