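"""Orchestration: factorial bookkeeping, reproducibility, leakage guards."""

import numpy as np
import pandas as pd
import pytest

from refnoise import DatasetProfile, generate, write_dataset
from refnoise.experiment import ExperimentConfig, run_experiment, summarize, write_result

SMALL_PROFILE = dict(
    name="tiny", n_samples=60, n_features=18, prevalence=0.5,
    n_informative=4, effect_size=1.5, block_size=3, block_rho=0.5,
)


def _config(**kw):
    base = dict(
        dataset=dict(SMALL_PROFILE),
        seed=5,
        levels=(0.0, 0.2),
        repetitions=2,
        selectors=("mannwhitney", "mrmr"),
        classifiers=("rf", "lasso_logistic"),
        rf_n_estimators=50,
        n_target=5,
    )
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="module")
def small_result():
    return run_experiment(_config())


class TestFactorialBookkeeping:
    def test_metric_record_count(self, small_result):
        # levels x repetitions x (selectors x classifiers) x surfaces
        assert len(small_result.metrics) == 2 * 2 * 4 * 3

    def test_jsc_rows_per_selector_level(self, small_result):
        assert len(small_result.jsc) == 2 * 2
        assert small_result.jsc["jsc"].between(0, 1).all()

    def test_level_zero_repetitions_identical(self, small_result):
        m = small_result.metrics
        lvl0 = m[m.level == 0.0]
        for (pipe, surf), grp in lvl0.groupby(["pipeline", "surface"]):
            assert grp["auc"].nunique() == 1

    def test_level_zero_jsc_is_one(self, small_result):
        jsc0 = small_result.jsc[small_result.jsc.level == 0.0]
        assert (jsc0["jsc"] == 1.0).all()

    def test_comparisons_present_and_bonferroni_bounded(self, small_result):
        c = small_result.comparisons
        assert set(c["pipeline"]) == set(small_result.metrics["pipeline"])
        assert c["adjusted_p"].between(0, 1).all()


class TestReproducibility:
    def test_rerun_writes_byte_identical_metrics(self, tmp_path):
        cfg = _config(selectors=("mannwhitney",), classifiers=("lasso_logistic",))
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        write_result(a, tmp_path / "a")
        write_result(b, tmp_path / "b")
        assert (tmp_path / "a" / "metrics.csv").read_bytes() == (
            tmp_path / "b" / "metrics.csv"
        ).read_bytes()

    def test_manifest_records_config_hash(self, small_result):
        assert small_result.manifest["config_sha256"] == _config().sha256()
        assert small_result.manifest["n_train"] + small_result.manifest["n_test"] == 60


class TestLeakageGuards:
    def test_permutation_touches_only_training_ids(self, small_result):
        train = set(small_result.train_ids)
        for cell in small_result.provenance:
            flipped = set(cell["flipped_pos_ids"]) | set(cell["flipped_neg_ids"])
            assert flipped <= train

    def test_holdout_rows_cannot_influence_training_surfaces(self, tmp_path):
        """Poisoning hold-out feature rows with sentinels leaves every
        training-surface metric and the selection provenance unchanged."""
        ds = generate(DatasetProfile(**SMALL_PROFILE), seed=900)
        clean_dir = tmp_path / "clean"
        write_dataset(ds, clean_dir)

        cfg = _config(
            dataset={"features_csv": str(clean_dir / "features.csv"),
                     "labels_csv": str(clean_dir / "labels.csv")},
            selectors=("mannwhitney",), classifiers=("lasso_logistic",),
        )
        res_clean = run_experiment(cfg)

        poisoned = tmp_path / "poisoned"
        poisoned.mkdir()
        feats = pd.read_csv(clean_dir / "features.csv")
        test_ids = set(res_clean.test_ids)
        mask = feats["sample_id"].isin(test_ids)
        feats.loc[mask, feats.columns[1:]] = 1e6  # sentinel values
        feats.to_csv(poisoned / "features.csv", index=False)
        (poisoned / "labels.csv").write_bytes((clean_dir / "labels.csv").read_bytes())

        cfg2 = _config(
            dataset={"features_csv": str(poisoned / "features.csv"),
                     "labels_csv": str(poisoned / "labels.csv")},
            selectors=("mannwhitney",), classifiers=("lasso_logistic",),
        )
        res_poison = run_experiment(cfg2)

        assert res_clean.train_ids == res_poison.train_ids
        train_surfaces = ["train_vs_permuted", "train_vs_true"]
        a = res_clean.metrics.query("surface in @train_surfaces").reset_index(drop=True)
        b = res_poison.metrics.query("surface in @train_surfaces").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        # hold-out metrics must of course differ
        ha = res_clean.metrics.query("surface == 'holdout_vs_true'")["auc"].to_numpy()
        hb = res_poison.metrics.query("surface == 'holdout_vs_true'")["auc"].to_numpy()
        assert not np.allclose(ha, hb)


class TestSummaries:
    def test_summary_shapes_and_constant_sd(self, small_result):
        tables = summarize(small_result)
        msum = tables["metrics"]
        assert len(msum) == 4 * 3 * 2 * 4  # pipelines x surfaces x levels x metrics
        lvl0 = msum[(msum.level == 0.0)]
        assert (lvl0["std"].fillna(0) == 0).all()  # level-0 repetitions identical

    def test_mannwhitney_null_selection_rate_near_alpha(self):
        """On label-independent data the proportion of features passing the
        alpha = 0.05 filter is binomial around alpha."""
        profile = dict(name="null", n_samples=120, n_features=300, prevalence=0.5,
                       n_informative=0, effect_size=0.0, block_rho=0.0)
        cfg = ExperimentConfig(
            dataset=profile, seed=17, levels=(0.0,), repetitions=2,
            selectors=("mannwhitney",), classifiers=(),
        )
        res = run_experiment(cfg)
        prop = res.selection_sizes["prop_selected"].iloc[0]
        se = np.sqrt(0.05 * 0.95 / 300)
        assert abs(prop - 0.05) <= 3 * se

    def test_classifier_free_run_has_no_metrics(self):
        cfg = _config(classifiers=(), selectors=("mannwhitney",))
        res = run_experiment(cfg)
        assert res.metrics.empty
        assert not res.jsc.empty


def test_small_highdim_imbalanced_profile_has_larger_variability():
    """A small, high-dimensional, imbalanced cohort shows larger
    between-repetition spread of training AUC than a larger balanced one
    at matched permutation levels (scaled-down analogues of the two
    cohort profiles)."""
    common = dict(levels=(0.1, 0.3), repetitions=8,
                  selectors=("mannwhitney",), classifiers=("lasso_logistic",))
    balanced = ExperimentConfig(
        dataset=dict(name="d1like", n_samples=260, n_features=80, prevalence=0.49,
                     n_informative=10, effect_size=1.0, block_size=5, block_rho=0.8),
        seed=71, **common)
    highdim = ExperimentConfig(
        dataset=dict(name="d2like", n_samples=100, n_features=300, prevalence=0.80,
                     n_informative=20, effect_size=1.0, block_size=5, block_rho=0.8),
        seed=72, **common)
    sd1 = (run_experiment(balanced).metrics.query("surface == 'train_vs_permuted'")
           .groupby("level")["auc"].std().mean())
    sd2 = (run_experiment(highdim).metrics.query("surface == 'train_vs_permuted'")
           .groupby("level")["auc"].std().mean())
    assert sd2 / sd1 > 1.0
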