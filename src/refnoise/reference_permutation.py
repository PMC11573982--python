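"""Balance-preserving random inversion of clinical reference labels.

The uncertainty simulation flips the labels of ``round(level * n)`` training
samples, drawn uniformly without replacement, with the flip budget split as
evenly as possible between the two classes so that class prevalence is
preserved up to 1/n.  Levels run from 0 to 0.5 in 5% steps by default, each
repeated 20 times with independent draws.  Permutation applies to training
references only; hold-out labels are never touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import derive_seed, round_half_away
from .data_model import ReferenceVector, ValidationError

#: 0%..50% in 5% increments — 11 levels.
DEFAULT_LEVELS: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(11))


class PermutationError(ValueError):
    """Raised when a flip quota cannot be satisfied."""


@dataclass(frozen=True)
class PermutationPlan:
    """Grid of permutation levels and seeded repetitions."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    repetitions: int = 20
    master_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        for lv in self.levels:
            if not 0 <= lv <= 0.5:
                raise ValidationError(f"levels must lie in [0, 0.5], got {lv}")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")


@dataclass(frozen=True)
class PermutedReference:
    """A noised copy of a reference vector plus full flip provenance."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray
    level: float
    repetition: int
    flipped_pos_ids: tuple[str, ...]  # flipped 1 -> 0
    flipped_neg_ids: tuple[str, ...]  # flipped 0 -> 1
    seed: int

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_flipped(self) -> int:
        return len(self.flipped_pos_ids) + len(self.flipped_neg_ids)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.labels))


def class_flip_counts(n_pos: int, n_neg: int, k: int) -> tuple[int, int]:
    """Split a flip budget of ``k`` between the classes.

    Half goes to each class; an odd remainder goes to the majority class
    (ties resolved toward the negative class), which keeps the prevalence
    drift within 1/n.  If one class cannot supply its quota the excess is
    reassigned to the other class — a documented extension for extreme
    imbalance, under which the 1/n drift bound no longer holds.
    """
    if k < 0 or k > n_pos + n_neg:
        raise PermutationError(f"flip count {k} infeasible for {n_pos}+{n_neg} samples")
    lo, hi = k // 2, k - k // 2
    k_pos, k_neg = (hi, lo) if n_pos > n_neg else (lo, hi)
    excess = max(0, k_pos - n_pos)
    k_pos, k_neg = k_pos - excess, k_neg + excess
    excess = max(0, k_neg - n_neg)
    k_neg, k_pos = k_neg - excess, k_pos + excess
    if k_pos > n_pos:
        raise PermutationError(
            f"positive class ({n_pos} members) cannot supply its flip quota of {k_pos}"
        )
    return k_pos, k_neg


def permute_reference(
    ref: ReferenceVector, level: float, seed: int, repetition: int = 1
) -> PermutedReference:
    """Flip exactly ``round(level * n)`` labels, balanced across classes.

    Deterministic given the seed; ``level=0`` returns an identical copy with
    empty flip sets.
    """
    if not 0 <= level <= 0.5:
        raise ValidationError(f"permutation level must lie in [0, 0.5], got {level}")
    n = ref.n
    k = round_half_away(level * n)
    pos_idx = np.flatnonzero(ref.labels == 1)
    neg_idx = np.flatnonzero(ref.labels == 0)
    k_pos, k_neg = class_flip_counts(len(pos_idx), len(neg_idx), k)

    rng = np.random.default_rng(seed)
    flip_pos = np.sort(rng.choice(pos_idx, size=k_pos, replace=False)) if k_pos else np.array([], int)
    flip_neg = np.sort(rng.choice(neg_idx, size=k_neg, replace=False)) if k_neg else np.array([], int)

    labels = ref.labels.copy()
    labels[flip_pos] = 0
    labels[flip_neg] = 1
    ids = ref.sample_ids
    return PermutedReference(
        sample_ids=ids,
        labels=labels,
        level=float(level),
        repetition=int(repetition),
        flipped_pos_ids=tuple(ids[i] for i in flip_pos),
        flipped_neg_ids=tuple(ids[i] for i in flip_neg),
        seed=int(seed),
    )


def generate_repetitions(ref: ReferenceVector, plan: PermutationPlan) -> list[PermutedReference]:
    """One permuted reference per (level, repetition) cell of the plan.

    The per-cell seed is derived from ``(master_seed, level_index,
    repetition_index)`` so any single cell is reproducible in isolation.
    """
    out = []
    for li, level in enumerate(plan.levels):
        for r in range(1, plan.repetitions + 1):
            seed = derive_seed(plan.master_seed, li, r)
            out.append(permute_reference(ref, level, seed, repetition=r))
    return out


def write_permutations(perms: list[PermutedReference], out_dir) -> dict[str, Path]:
    """Persist permuted labels as CSV and flip provenance as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    prov = []
    for p in perms:
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": list(p.sample_ids),
                    "label": p.labels,
                    "level": p.level,
                    "repetition": p.repetition,
                }
            )
        )
        prov.append(
            {
                "level": p.level,
                "repetition": p.repetition,
                "seed": p.seed,
                "flipped_pos_ids": list(p.flipped_pos_ids),
                "flipped_neg_ids": list(p.flipped_neg_ids),
            }
        )
    paths = {
        "labels": out / "permuted_labels.csv",
        "provenance": out / "permutation_provenance.json",
    }
    pd.concat(rows, ignore_index=True).to_csv(paths["labels"], index=False)
    paths["provenance"].write_text(json.dumps(prov, indent=2))
    return paths
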