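"""Cascade growth, feature augmentation, prediction alignment,
reproducibility and the out-of-fold anti-leakage guard."""

import dataclasses

import numpy as np
import pytest

from dfsc import (
    CascadeConfig,
    GeneratorConfig,
    cascade_predict_risk,
    cascade_predict_survival,
    fit_cascade,
    generate,
    load_model,
    save_model,
)
from dfsc.synthetic_data import split_by_partition
from conftest import make_dataset

FAST = dict(n_trees_per_forest=15, max_levels=1)


def _cohort(seed=0, n=140, p=25, n_causal=3, **kw):
    data, truth = generate(GeneratorConfig(
        n_samples=n, n_genes=p, n_causal=n_causal, correlation_block_size=1,
        test_fraction=0.2, random_seed=seed, **kw,
    ))
    lab, _, test = split_by_partition(data, truth)
    return lab, test


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_forests_per_level": 3},
        {"n_forests_per_level": 0},
        {"max_levels": 0},
        {"elasticnet_l1_ratio": 1.5},
        {"validation_fraction": 0.0},
    ])
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CascadeConfig(**kw)


class TestFitCascade:
    def test_requires_events_and_genes(self):
        ds = make_dataset(np.arange(1, 31), np.zeros(30, int), n_genes=4)
        with pytest.raises(ValueError):
            fit_cascade(ds, CascadeConfig(**FAST))

    def test_requires_minimum_cohort(self):
        ds = make_dataset(np.arange(1, 11), np.ones(10, int), n_genes=4)
        with pytest.raises(ValueError, match="20"):
            fit_cascade(ds, CascadeConfig(**FAST))

    def test_reproducible_bit_identical(self):
        lab, test = _cohort(seed=1)
        cc = CascadeConfig(random_seed=9, **FAST)
        a = fit_cascade(lab, cc)
        b = fit_cascade(lab, cc)
        np.testing.assert_array_equal(
            cascade_predict_risk(a, test), cascade_predict_risk(b, test)
        )

    def test_first_level_independent_of_depth_budget(self):
        # the degenerate max_levels=1 model is exactly the deeper model's
        # first level (seeding is per-level, not global)
        lab, test = _cohort(seed=2)
        shallow = fit_cascade(lab, CascadeConfig(n_trees_per_forest=15, max_levels=1,
                                                 random_seed=4))
        deep = fit_cascade(lab, CascadeConfig(n_trees_per_forest=15, max_levels=3,
                                              random_seed=4))
        assert shallow.validation_history[0] == deep.validation_history[0]
        if len(deep.levels) == 1:
            np.testing.assert_array_equal(
                cascade_predict_risk(shallow, test), cascade_predict_risk(deep, test)
            )

    def test_augmented_dimension_contract(self):
        # 100 genes + 4 forests x 1 output feature -> level-2 forests see 104
        lab, _ = _cohort(seed=3, p=100, n=120)
        cc = CascadeConfig(n_trees_per_forest=10, max_levels=2, patience=1,
                           min_improvement=-1.0, random_seed=0)  # force 2 levels
        model = fit_cascade(lab, cc)
        assert len(model.levels) == 2
        lvl2_forest = model.levels[1].forest_fold_models[0][0]
        assert lvl2_forest.n_features_in_ == 104
        # Cox link sees originals + this level's forest outputs
        assert len(model.levels[1].cox_link_coefficients) == 104

    def test_retained_validation_is_running_max_within_margin(self):
        lab, _ = _cohort(seed=4)
        cc = CascadeConfig(n_trees_per_forest=10, max_levels=3, min_improvement=0.0,
                           random_seed=1)
        model = fit_cascade(lab, cc)
        assert model.levels[-1].validation_cindex == pytest.approx(
            max(model.validation_history)
        )
        cc2 = dataclasses.replace(cc, min_improvement=0.005)
        model2 = fit_cascade(lab, cc2)
        assert model2.levels[-1].validation_cindex >= (
            max(model2.validation_history) - cc2.min_improvement
        )


class TestPrediction:
    def test_training_predictions_reproduce_baseline_eta(self):
        lab, _ = _cohort(seed=5)
        model = fit_cascade(lab, CascadeConfig(random_seed=5, **FAST))
        np.testing.assert_array_equal(cascade_predict_risk(model, lab), model.train_eta)

    def test_duplicated_sample_scores_identically(self):
        lab, test = _cohort(seed=6)
        model = fit_cascade(lab, CascadeConfig(random_seed=6, **FAST))
        X = test.X[[0, 0, 1]]
        eta = cascade_predict_risk(model, X)
        assert eta[0] == eta[1]

    def test_gene_permutation_invariance_by_id(self):
        lab, test = _cohort(seed=7)
        model = fit_cascade(lab, CascadeConfig(random_seed=7, **FAST))
        perm = np.random.default_rng(0).permutation(test.n_genes)
        shuffled = test.subset(np.arange(test.n_samples))
        shuffled.X = test.X[:, perm]
        shuffled.gene_ids = [test.gene_ids[j] for j in perm]
        np.testing.assert_allclose(
            cascade_predict_risk(model, test), cascade_predict_risk(model, shuffled),
            atol=0,
        )

    def test_unknown_genes_reported(self):
        lab, test = _cohort(seed=8)
        model = fit_cascade(lab, CascadeConfig(random_seed=8, **FAST))
        bad = test.subset(np.arange(test.n_samples))
        bad.gene_ids = ["MYSTERY"] + bad.gene_ids[1:]
        with pytest.raises(KeyError, match="G00000"):
            cascade_predict_risk(model, bad)

    def test_survival_curves_valid_and_ordered(self):
        lab, test = _cohort(seed=9)
        model = fit_cascade(lab, CascadeConfig(random_seed=9, **FAST))
        times = np.linspace(0, float(lab.time.max()), 8)
        S = cascade_predict_survival(model, test, times)
        np.testing.assert_allclose(S[:, 0], 1.0)
        assert (np.diff(S, axis=1) <= 1e-12).all()
        assert (S > 0).all() and (S <= 1).all()
        eta = cascade_predict_risk(model, test)
        hi, lo = int(np.argmax(eta)), int(np.argmin(eta))
        assert (S[hi] <= S[lo] + 1e-12).all()

    def test_curves_match_closed_form_from_baseline(self):
        lab, test = _cohort(seed=10)
        model = fit_cascade(lab, CascadeConfig(random_seed=10, **FAST))
        sub = test.subset(np.arange(5))
        eta = cascade_predict_risk(model, sub)
        grid = model.baseline.event_times[:4]
        S = cascade_predict_survival(model, sub, grid)
        H = model.baseline.cumulative_hazard[:4]
        np.testing.assert_allclose(S, np.exp(-np.outer(np.exp(eta), H)), atol=1e-12)

    def test_serialization_roundtrip(self, tmp_path):
        lab, test = _cohort(seed=11)
        model = fit_cascade(lab, CascadeConfig(random_seed=11, **FAST))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            cascade_predict_risk(model, test), cascade_predict_risk(loaded, test)
        )


class TestAntiLeakage:
    def test_out_of_fold_features_prevent_validation_optimism(self):
        """On pure-noise outcomes, in-fold feature computation inflates the
        validation concordance dramatically; the out-of-fold path stays at
        chance level."""
        oof, leak = [], []
        for seed in range(10):
            data, _ = generate(GeneratorConfig(
                n_samples=200, n_genes=40, n_causal=0, censoring_rate=0.2,
                test_fraction=0.1, correlation_block_size=1, random_seed=200 + seed,
            ))
            lab = data.labeled()
            cc = CascadeConfig(n_trees_per_forest=20, max_levels=1,
                               validation_fraction=0.3, random_seed=seed)
            oof.append(fit_cascade(lab, cc).validation_history[0])
            leak.append(fit_cascade(lab, cc, _leak_validation=True).validation_history[0])
        assert abs(float(np.mean(oof)) - 0.5) <= 0.05
        assert float(np.mean(leak)) > float(np.mean(oof)) + 0.1
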