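"""Radiomics-like synthetic feature tables with known ground-truth signal.

The generator emulates the two public prostate-MRI radiomics profiles used
throughout the package's experiments: a moderate-dimension balanced cohort
(260 lesions x 265 features, 49% positive) and a small high-dimensional
imbalanced cohort (100 lesions x 7106 features, 80% positive).

Signal model
------------
Class-conditional features are equal-variance Gaussians.  Each of the
``n_informative`` features carries a standardized mean difference
``effect_size`` (Cohen's d) between the two outcome classes; the remaining
features are label-independent noise.  A single informative Gaussian
feature with standardized difference d has a closed-form ROC AUC of
``Phi(d / sqrt(2))``, which serves as the calibration oracle for the
generator.

Noise features are organized into equicorrelated blocks built from a shared
latent factor (pairwise correlation ``block_rho`` within a block), mimicking
the redundant feature families typical of radiomics panels; informative
features are mutually independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._utils import round_half_away
from .data_model import FeatureTable, ReferenceVector, ValidationError


@dataclass(frozen=True)
class DatasetProfile:
    """Shape and signal parameters for one synthetic cohort.

    Parameters
    ----------
    n_samples, n_features
        Cohort size and panel width.
    prevalence
        Proportion of samples labelled 1 (clinically significant), in (0,1).
        The generated positive count is exactly ``round(prevalence * n)``.
    n_informative
        Number of features carrying signal.
    effect_size
        Standardized mean difference d per informative feature; the realised
        mean shift is ``effect_size * noise_sd``.
    block_size, block_rho
        Noise features are grouped into consecutive blocks of ``block_size``
        with within-block correlation ``block_rho`` (0 disables blocking).
    noise_sd
        Common within-class standard deviation of every feature.
    """

    name: str
    n_samples: int
    n_features: int
    prevalence: float
    n_informative: int = 10
    effect_size: float = 1.0
    block_size: int = 5
    block_rho: float = 0.8
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValidationError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError("n_informative must satisfy 0 <= n_informative <= n_features")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.block_rho < 1:
            raise ValidationError(f"block_rho must be in [0,1), got {self.block_rho}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")


def profile_dataset1() -> DatasetProfile:
    """Balanced moderate-dimension profile: 260 samples, 265 features, 49% positive."""
    return DatasetProfile(
        name="dataset1", n_samples=260, n_features=265, prevalence=0.49,
        n_informative=10, effect_size=1.0, block_size=5, block_rho=0.8,
    )


def profile_dataset2() -> DatasetProfile:
    """Small high-dimensional imbalanced profile: 100 samples, 7106 features, 80% positive."""
    return DatasetProfile(
        name="dataset2", n_samples=100, n_features=7106, prevalence=0.80,
        n_informative=20, effect_size=1.0, block_size=5, block_rho=0.8,
    )


_NAMED_PROFILES = {"dataset1": profile_dataset1, "dataset2": profile_dataset2}


def get_profile(name_or_profile) -> DatasetProfile:
    """Resolve a profile from its name, a mapping, or pass one through."""
    if isinstance(name_or_profile, DatasetProfile):
        return name_or_profile
    if isinstance(name_or_profile, str):
        if name_or_profile in _NAMED_PROFILES:
            return _NAMED_PROFILES[name_or_profile]()
        path = Path(name_or_profile)
        if path.suffix in {".yaml", ".yml"} and path.exists():
            return get_profile(yaml.safe_load(path.read_text()))
        raise ValidationError(
            f"unknown profile {name_or_profile!r}; expected dataset1, dataset2, or a YAML path"
        )
    if isinstance(name_or_profile, dict):
        return DatasetProfile(**name_or_profile)
    raise ValidationError(f"cannot interpret profile {name_or_profile!r}")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated cohort: features, labels, and the ground-truth signal map."""

    features: FeatureTable
    labels: ReferenceVector
    truth: dict[str, float]  # informative feature name -> effect size
    seed: int


def generate(profile: DatasetProfile, seed: int) -> SyntheticDataset:
    """Draw one cohort from the profile; bit-for-bit reproducible from the seed.

    Exactly ``round(prevalence * n)`` samples are labelled 1.  Informative
    features have a population mean difference of ``effect_size * noise_sd``
    between classes; non-informative features are independent of the label.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    n, p = profile.n_samples, profile.n_features
    k = profile.n_informative

    n_pos = round_half_away(profile.prevalence * n)
    n_pos = min(max(n_pos, 1), n - 1)  # both classes must exist
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.permutation(n)[:n_pos]] = 1

    X = rng.standard_normal((n, p))
    if profile.block_rho > 0 and profile.block_size > 1:
        root_rho = math.sqrt(profile.block_rho)
        root_res = math.sqrt(1.0 - profile.block_rho)
        for start in range(k, p, profile.block_size):
            stop = min(start + profile.block_size, p)
            if stop - start < 2:
                continue
            factor = rng.standard_normal(n)
            X[:, start:stop] = root_rho * factor[:, None] + root_res * X[:, start:stop]
    if k:
        X[:, :k] += profile.effect_size * labels[:, None]
    X *= profile.noise_sd

    width = max(4, len(str(p)))
    names = tuple(f"f{j + 1:0{width}d}" for j in range(p))
    idw = max(3, len(str(n)))
    ids = tuple(f"s{i + 1:0{idw}d}" for i in range(n))

    return SyntheticDataset(
        features=FeatureTable(ids, names, X),
        labels=ReferenceVector(ids, labels),
        truth={names[j]: profile.effect_size for j in range(k)},
        seed=int(seed),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Persist a cohort as features.csv, labels.csv and a truth.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.csv",
        "labels": out / "labels.csv",
        "truth": out / "truth.json",
    }
    dataset.features.write_csv(paths["features"])
    dataset.labels.write_csv(paths["labels"])
    paths["truth"].write_text(
        json.dumps({"seed": dataset.seed, "informative": dataset.truth}, indent=2)
    )
    return paths
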