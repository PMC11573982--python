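"""Four radiomics feature selectors and the multi-set Jaccard stability index.

Selectors: Mann-Whitney U filtering (two-sided, alpha = 0.05, unadjusted),
recursive feature elimination (RFE) over an L2-logistic ranker, L1-penalized
logistic regression (LASSO) with a cross-validated penalty, and greedy
minimum-redundancy-maximum-relevance (mRMR) under the MID (mutual-information
difference) criterion.

Every selector returns a named, ordered feature subset plus per-feature
diagnostic scores, and guarantees a non-empty selection: when nothing
survives, all features are returned with ``fallback_used=True``.  This
fallback is load-bearing — with heavily noised labels a sparse selector can
legitimately retain nothing, and returning the full panel (with a flag)
keeps the downstream pipeline defined and makes the stability index jump to
1 when the fallback fires for every repetition.

Stability across repetitions is the multi-set Jaccard similarity
coefficient JSC = |intersection of all sets| / |union of all sets|.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .data_model import FeatureTable, ReferenceVector, ValidationError

log = logging.getLogger(__name__)

SELECTOR_NAMES = ("mannwhitney", "rfe", "lasso", "mrmr")

#: Default L1 penalty grid (inverse regularization strengths) for the LASSO selector.
DEFAULT_LASSO_CS = np.logspace(-3, 3, 13)


@dataclass(frozen=True)
class SelectionResult:
    """A named feature subset with per-feature diagnostics for one selector."""

    method: str
    selected: tuple[str, ...]
    scores: dict[str, float]
    fallback_used: bool = False

    def __post_init__(self):
        if not self.selected:
            raise ValidationError("selection must be non-empty (fallback guarantees this)")


@dataclass(frozen=True)
class StabilityRecord:
    """JSC of one selector across the repetitions at one permutation level."""

    method: str
    level: float
    jsc: float
    n_sets: int

    def __post_init__(self):
        if not 0 <= self.jsc <= 1:
            raise ValidationError(f"jsc must lie in [0,1], got {self.jsc}")


def _as_labels(ref) -> np.ndarray:
    y = ref.labels if isinstance(ref, ReferenceVector) else np.asarray(ref)
    y = y.astype(int)
    if not np.isin(y, [0, 1]).all():
        raise ValidationError("labels must be binary in {0,1}")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    return y


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns stay constant (zero) after centering
    return (X - mu) / sd


def default_n_target(n_train: int) -> int:
    """Default subset size for RFE and mRMR: min(30, floor(n_train / 5)).

    Caps model complexity relative to the training sample size.
    """
    return max(1, min(30, n_train // 5))


def select_mannwhitney(table: FeatureTable, ref, alpha: float = 0.05) -> SelectionResult:
    """Features whose two-sided Mann-Whitney U p-value is below ``alpha``.

    P-values use the midrank normal approximation with tie correction and
    continuity correction, unadjusted for multiplicity.  Constant features
    are assigned p = 1 and never selected.
    """
    y = _as_labels(ref)
    X = table.values
    x1, x0 = X[y == 1], X[y == 0]
    if min(len(x1), len(x0)) < 2:
        raise ValidationError("each class needs >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x1, x0, axis=0, alternative="two-sided", method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance (all-tied) features

    mask = pvals < alpha
    scores = dict(zip(table.feature_names, pvals.tolist()))
    if mask.any():
        selected = tuple(f for f, m in zip(table.feature_names, mask) if m)
        return SelectionResult("mannwhitney", selected, scores, fallback_used=False)
    return SelectionResult("mannwhitney", table.feature_names, scores, fallback_used=True)


def select_lasso(
    table: FeatureTable,
    ref,
    folds: int = 5,
    seed: int = 0,
    Cs=None,
) -> SelectionResult:
    """Features with nonzero coefficients in a CV-tuned L1 logistic model.

    Features are z-scored on the given data; the penalty is chosen by
    stratified cross-validation on the binomial deviance.  If the chosen
    penalty zeroes every coefficient, all features are returned with
    ``fallback_used=True``.
    """
    y = _as_labels(ref)
    X = _zscore(table.values)
    minority = int(min(np.bincount(y)))
    eff_folds = min(folds, minority)
    if eff_folds < 2:
        raise ValidationError("minority class too small for cross-validation")
    if eff_folds < folds:
        log.warning("lasso selector: reducing CV folds from %d to %d (minority class size)",
                    folds, eff_folds)
    model = LogisticRegressionCV(
        Cs=DEFAULT_LASSO_CS if Cs is None else Cs,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        cv=StratifiedKFold(eff_folds, shuffle=True, random_state=seed),
        random_state=seed,
        max_iter=1000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    coef = model.coef_.ravel()
    scores = dict(zip(table.feature_names, np.abs(coef).tolist()))
    mask = coef != 0
    if mask.any():
        selected = tuple(f for f, m in zip(table.feature_names, mask) if m)
        return SelectionResult("lasso", selected, scores, fallback_used=False)
    return SelectionResult("lasso", table.feature_names, scores, fallback_used=True)


def select_rfe(
    table: FeatureTable, ref, n_target: int, step: int | None = None
) -> SelectionResult:
    """Recursive feature elimination down to ``n_target`` features.

    The ranker is an L2-penalized logistic regression on z-scored features;
    at each round the lowest-|coefficient| features are dropped.  With
    ``step=None`` the batch size is ``max(1, p // 50)`` until twice the
    target remains, then 1 — a large-p speedup that ends with single-feature
    elimination.  Scores record the elimination order (higher = survived
    longer; survivors share the top score).
    """
    y = _as_labels(ref)
    p = table.p
    if not 1 <= n_target <= p:
        raise ValidationError(f"n_target must lie in [1, {p}], got {n_target}")
    X = _zscore(table.values)

    remaining = list(range(p))
    elimination_order: list[int] = []  # first eliminated first
    big_step = max(1, p // 50) if step is None else max(1, int(step))
    while len(remaining) > n_target:
        model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)  # ridge-penalized ranker
        model.fit(X[:, remaining], y)
        importance = np.abs(model.coef_.ravel())
        cur = big_step if (step is not None or len(remaining) > 2 * n_target) else 1
        cur = min(cur, len(remaining) - n_target)
        drop = np.argsort(importance, kind="stable")[:cur]
        for j in sorted(drop, reverse=True):
            elimination_order.append(remaining.pop(j))

    scores = {table.feature_names[j]: float(i + 1) for i, j in enumerate(elimination_order)}
    for j in remaining:
        scores[table.feature_names[j]] = float(p)  # survivors share the top rank
    selected = tuple(table.feature_names[j] for j in remaining)
    return SelectionResult("rfe", selected, scores, fallback_used=False)


def _equal_frequency_bins(values: np.ndarray, nbins: int) -> np.ndarray:
    """Rank-based equal-frequency discretization; deterministic under ties."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * nbins) // n


def mutual_information_discrete(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    """Plug-in mutual information (nats) between two discrete codes."""
    n = len(a)
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / denom[nz])))


def select_mrmr(table: FeatureTable, ref, n_target: int) -> SelectionResult:
    """Greedy mRMR forward selection under the MID criterion.

    At each step the feature maximizing ``I(f; y) - mean_{s in S} I(f; s)``
    is added, with mutual information estimated by the plug-in formula on
    equal-frequency bins (``ceil(sqrt(n))`` bins per feature).  The first
    pick is the max-relevance feature; ties break deterministically toward
    the earlier feature column.
    """
    y = _as_labels(ref)
    n, p = table.values.shape
    if not 1 <= n_target <= p:
        raise ValidationError(f"n_target must lie in [1, {p}], got {n_target}")
    nbins = math.ceil(math.sqrt(n))
    D = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        D[:, j] = _equal_frequency_bins(table.values[:, j], nbins)

    relevance = np.array(
        [mutual_information_discrete(D[:, j], y, nbins, 2) for j in range(p)]
    )
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    selected_idx: list[int] = []
    scores = {}
    for t in range(n_target):
        crit = relevance - (redundancy_sum / t if t else 0.0)
        crit[~available] = -np.inf
        j = int(np.argmax(crit))  # argmax takes the first maximum: tie-break by order
        scores[table.feature_names[j]] = float(crit[j])
        selected_idx.append(j)
        available[j] = False
        if t < n_target - 1:
            for i in np.flatnonzero(available):
                redundancy_sum[i] += mutual_information_discrete(D[:, j], D[:, i], nbins, nbins)

    final_crit = relevance - redundancy_sum / len(selected_idx)
    for i in np.flatnonzero(available):
        scores[table.feature_names[i]] = float(final_crit[i])
    selected = tuple(table.feature_names[j] for j in selected_idx)
    return SelectionResult("mrmr", selected, scores, fallback_used=False)


def jaccard_multi(sets) -> float:
    """Multi-set Jaccard similarity: |intersection of all| / |union of all|.

    Requires at least two sets.  Returns 1.0 when the union is empty (the
    degenerate all-empty case), by convention.
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValidationError("jaccard_multi needs >= 2 sets")
    union = set().union(*sets)
    if not union:
        return 1.0
    inter = set.intersection(*sets)
    return len(inter) / len(union)


def run_selector(
    name: str,
    table: FeatureTable,
    ref,
    *,
    alpha: float = 0.05,
    n_target: int | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Dispatch to one of the four selectors by name."""
    if name == "mannwhitney":
        return select_mannwhitney(table, ref, alpha=alpha)
    if name == "lasso":
        return select_lasso(table, ref, folds=folds, seed=seed)
    nt = default_n_target(table.n) if n_target is None else n_target
    nt = min(nt, table.p)
    if name == "rfe":
        return select_rfe(table, ref, n_target=nt)
    if name == "mrmr":
        return select_mrmr(table, ref, n_target=nt)
    raise ValidationError(f"unknown selector {name!r}; expected one of {SELECTOR_NAMES}")
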