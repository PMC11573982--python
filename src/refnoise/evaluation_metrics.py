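"""Performance metrics, level-wise statistics, and the noisy-AUC oracle.

Metrics are computed on three evaluation surfaces: out-of-fold training
scores against the permuted labels the model was trained on
(``train_vs_permuted``), the same scores against the true training labels
(``train_vs_true``), and hold-out scores against true hold-out labels
(``holdout_vs_true``).

``expected_noisy_auc`` gives the closed-form AUC obtained when a fixed
scoring rule of true AUC A is evaluated against labels with
balance-preserving flips: each noisy class is a mixture of true positives
and true negatives, so

    AUC_noisy = w_pp * w_nn * A + w_pn * w_np * (1 - A)
               + (w_pp * w_np + w_pn * w_nn) / 2

where w_pp (w_pn) is the fraction of the noisy-positive group that is truly
positive (negative), and w_nn, w_np likewise for the noisy-negative group,
all implied by the per-class flip counts.  Ties are assumed negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_away
from .data_model import ValidationError
from .reference_permutation import class_flip_counts

SURFACES = ("train_vs_permuted", "train_vs_true", "holdout_vs_true")


@dataclass(frozen=True)
class MetricRecord:
    """One (pipeline, level, repetition, surface) row of performance metrics."""

    pipeline: str
    level: float
    repetition: int
    surface: str
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float

    def __post_init__(self):
        if self.surface not in SURFACES:
            raise ValidationError(f"unknown surface {self.surface!r}")


@dataclass(frozen=True)
class LevelComparison:
    """One-way ANOVA across levels plus Bonferroni-adjusted pairwise tests."""

    metric: str
    pipeline: str
    surface: str
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[float, float], float]  # (level_a, level_b) -> adjusted p


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to compute metrics")
    return y


def roc_auc(scores, labels) -> float:
    """Tie-corrected (midrank) ROC AUC.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2 — the Mann-Whitney U statistic scaled to
    [0, 1].
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)  # midranks
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(scores, labels, cutoff: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at ``prediction = score >= cutoff``."""
    y = _check_binary(labels)
    pred = (np.asarray(scores, dtype=float) >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


def metrics_from_scores(
    pipeline: str, level: float, repetition: int, surface: str, scores, labels,
    cutoff: float = 0.5,
) -> MetricRecord:
    """Bundle AUC and threshold metrics into one record."""
    acc, sens, spec = confusion_metrics(scores, labels, cutoff)
    return MetricRecord(
        pipeline=pipeline, level=float(level), repetition=int(repetition), surface=surface,
        auc=roc_auc(scores, labels), accuracy=acc, sensitivity=sens, specificity=spec,
    )


def expected_noisy_auc(true_auc: float, level: float, prevalence: float, n: int) -> float:
    """Closed-form AUC of a fixed scorer evaluated against noised labels.

    Flip counts per class follow the same balance-preserving rule as the
    permutation module (``round(level * n)`` flips, split evenly with the
    odd remainder to the majority class).  Identity at level 0; exactly 0.5
    at level 0.5 with balanced classes.
    """
    if not 0.5 <= true_auc <= 1:
        raise ValidationError(f"true_auc must lie in [0.5, 1], got {true_auc}")
    if not 0 <= level <= 0.5:
        raise ValidationError(f"level must lie in [0, 0.5], got {level}")
    n_pos = round_half_away(prevalence * n)
    n_neg = n - n_pos
    k = round_half_away(level * n)
    k_pos, k_neg = class_flip_counts(n_pos, n_neg, k)

    noisy_pos = n_pos - k_pos + k_neg  # size of the group labelled positive after flips
    noisy_neg = n_neg - k_neg + k_pos
    w_pp = (n_pos - k_pos) / noisy_pos
    w_pn = k_neg / noisy_pos
    w_nn = (n_neg - k_neg) / noisy_neg
    w_np = k_pos / noisy_neg
    A = true_auc
    return float(w_pp * w_nn * A + w_pn * w_np * (1 - A) + (w_pp * w_np + w_pn * w_nn) * 0.5)


def compare_levels(
    records: pd.DataFrame, metric: str = "auc", pipeline: str = "", surface: str = ""
) -> LevelComparison:
    """One-way ANOVA of a metric across permutation levels, repetitions as
    replicates, with all-pairs Bonferroni-adjusted t-tests.

    ``records`` needs columns ``level`` and ``metric``.  Degenerate inputs
    (identical values everywhere) yield F = 0 and all adjusted p = 1.
    """
    if metric not in records.columns:
        raise ValidationError(f"records lack a {metric!r} column")
    groups = {lv: g[metric].to_numpy(dtype=float) for lv, g in records.groupby("level")}
    levels = sorted(groups)
    if len(levels) < 2:
        raise ValidationError("need >= 2 levels to compare")
    if any(len(g) < 2 for g in groups.values()):
        raise ValidationError("need >= 2 repetitions per level")

    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        F, p_anova = 0.0, 1.0
    else:
        F, p_anova = stats.f_oneway(*[groups[lv] for lv in levels])
        F, p_anova = float(F), float(p_anova)

    m = len(levels) * (len(levels) - 1) // 2
    pairwise = {}
    for a, b in combinations(levels, 2):
        ga, gb = groups[a], groups[b]
        if np.ptp(ga) == 0 and np.ptp(gb) == 0:
            raw = 1.0 if ga[0] == gb[0] else 0.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = float(stats.ttest_ind(ga, gb, equal_var=True).pvalue)
            if np.isnan(raw):
                raw = 1.0
        pairwise[(a, b)] = min(1.0, raw * m)
    return LevelComparison(metric, pipeline, surface, F, p_anova, pairwise)


def comparison_to_frame(cmp: LevelComparison) -> pd.DataFrame:
    """Tidy one-row-per-pair frame of a level comparison."""
    rows = [
        {
            "pipeline": cmp.pipeline, "surface": cmp.surface, "metric": cmp.metric,
            "level_a": a, "level_b": b, "adjusted_p": p,
            "anova_F": cmp.anova_F, "anova_p": cmp.anova_p,
            "significant": p < 0.05,
        }
        for (a, b), p in sorted(cmp.pairwise.items())
    ]
    return pd.DataFrame(rows)
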