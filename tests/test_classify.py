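"""CFS merit, best-first search, models, and leakage-free LOO validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cptmethsig.classify import (CVReport, best_first_search, cfs_merit,
                                 correlation_inputs, fit_logistic,
                                 fit_naive_bayes, loo_cross_validate)
from cptmethsig.diffmeth import CARCINOMA, PAPILLOMA
from cptmethsig.io import BetaMatrix
from cptmethsig.simulate import SimulationConfig, simulate_cohort

from conftest import null_config


class TestMerit:
    def test_single_feature_reduces_to_class_correlation(self):
        r_cf = np.array([0.8, 0.2])
        r_ff = np.eye(2)
        assert cfs_merit([0], r_cf, r_ff) == pytest.approx(0.8)

    def test_two_uncorrelated_features(self):
        r_cf = np.array([0.5, 0.5])
        r_ff = np.eye(2)
        assert cfs_merit([0, 1], r_cf, r_ff) == pytest.approx(1 / np.sqrt(2),
                                                              abs=1e-4)

    def test_exact_duplicates_gain_nothing(self):
        """k exact copies of one feature have the same merit as the feature
        alone: the redundancy penalty exactly cancels the relevance gain,
        so stacking duplicates can never beat keeping one."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            r = rng.uniform(0.1, 0.9)
            r_cf = np.full(n, r)
            r_ff = np.ones((n, n))
            for k in range(1, n + 1):
                assert cfs_merit(list(range(k)), r_cf, r_ff) == \
                    pytest.approx(r, abs=1e-12)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            cfs_merit([], np.array([0.5]), np.eye(1))


class TestBestFirst:
    @staticmethod
    def _exhaustive(r_cf, r_ff):
        n = len(r_cf)
        best, best_m = None, -1
        for k in range(1, n + 1):
            for sub in itertools.combinations(range(n), k):
                m = cfs_merit(sub, r_cf, r_ff)
                if m > best_m + 1e-12:
                    best, best_m = sub, m
        return best_m

    def test_single_feature_selected(self):
        assert best_first_search(np.array([0.7]), np.eye(1)) == [0]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(2, 9)
            r_cf = rng.uniform(0, 1, n)
            A = rng.uniform(0, 1, size=(n, n))
            r_ff = (A + A.T) / 2
            np.fill_diagonal(r_ff, 1.0)
            sel = best_first_search(r_cf, r_ff)
            assert cfs_merit(sel, r_cf, r_ff) == pytest.approx(
                self._exhaustive(r_cf, r_ff), abs=1e-9)

    def test_identical_informative_features_pick_one(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 10)
        f = y + rng.normal(0, 0.3, 20)
        X = np.column_stack([f, f])  # exact duplicates
        r_cf, r_ff = correlation_inputs(X, y)
        sel = best_first_search(r_cf, r_ff)
        assert len(sel) == 1


class TestModels:
    def test_odds_ratio_is_exponential_of_coefficient(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(40, 2))
        y = (X[:, 0] + rng.normal(0, 0.2, 40) > 0.5).astype(int)
        model = fit_logistic(X, y, ridge_lambda=1.0)
        np.testing.assert_allclose(model.odds_ratios,
                                   np.exp(model.coefficients))
        assert (model.odds_ratios > 0).all()

    def test_single_class_rejected(self):
        X = np.zeros((5, 1))
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(X, np.ones(5))
        with pytest.raises(ValueError, match="single class"):
            fit_naive_bayes(X, np.ones(5))

    def test_naive_bayes_symmetric_posterior(self):
        # classes with means 0 and 1, equal variances and priors:
        # posterior at the midpoint is 0.5/0.5
        X = np.array([[-1.0], [0.0], [1.0], [0.0], [1.0], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_naive_bayes(X, y)
        assert model.predict_score([[0.5]])[0] == pytest.approx(0.5, abs=1e-9)


class TestLOO:
    def test_perfect_separation_on_planted_signature(self, recovery_filtered,
                                                     recovery_labels):
        report = loo_cross_validate(recovery_filtered, recovery_labels,
                                    model="logistic", features="signature")
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.auroc == 1.0

    def test_confusion_margins_equal_class_sizes(self, recovery_filtered,
                                                 recovery_labels):
        report = loo_cross_validate(recovery_filtered, recovery_labels,
                                    model="nb", features="signature")
        c = report.confusion
        assert c["tp"] + c["fn"] == (recovery_labels == CARCINOMA).sum()
        assert c["tn"] + c["fp"] == (recovery_labels == PAPILLOMA).sum()

    def test_held_out_sample_never_in_training(self, recovery_filtered,
                                               recovery_labels):
        seen = []

        def spy(held, train_ids):
            seen.append((held, held in train_ids, len(train_ids)))

        loo_cross_validate(recovery_filtered, recovery_labels,
                           features=["cg00000001"], fold_callback=spy)
        assert len(seen) == recovery_filtered.shape[1]
        assert not any(leaked for _, leaked, _ in seen)
        assert all(n == recovery_filtered.shape[1] - 1 for _, _, n in seen)

    def test_cfs_mode_selects_compact_feature_sets(self, recovery_filtered,
                                                   recovery_labels):
        report = loo_cross_validate(recovery_filtered, recovery_labels,
                                    model="logistic", features="cfs")
        assert report.sensitivity == 1.0 and report.specificity == 1.0
        full = loo_cross_validate(recovery_filtered, recovery_labels,
                                  model="logistic", features="signature")
        assert report.folds["n_features"].mean() < \
            full.folds["n_features"].mean()

    def test_fixed_minimal_panel_perfect_auroc(self, recovery_cohort,
                                               recovery_filtered,
                                               recovery_labels,
                                               recovery_tier2):
        # a minimal panel: the three most significant planted CpGs
        planted = set(recovery_cohort.truth.loc[
            recovery_cohort.truth["planted"], "probe_id"])
        panel = [p for p in recovery_tier2.probe_ids if p in planted][:3]
        for model in ("logistic", "nb"):
            report = loo_cross_validate(recovery_filtered, recovery_labels,
                                        model=model, features=panel)
            assert report.auroc == 1.0

    def test_empty_fold_signature_falls_back_to_prior(self):
        cohort = simulate_cohort(null_config(n_probes=200, seed=9))
        from cptmethsig.diffmeth import labels_from_diagnosis
        labels = labels_from_diagnosis(cohort.metadata["diagnosis"])
        report = loo_cross_validate(cohort.beta, labels)
        assert (report.folds["n_features"] == 0).all()
        # papilloma majority: every prediction is the prior class
        assert (report.folds["predicted"] == PAPILLOMA).all()

    def test_label_permutation_destroys_performance(self):
        """Null behavior under shuffled labels: mean LOO AUROC near chance,
        demonstrating that per-fold signature re-derivation does not leak."""
        from cptmethsig.diffmeth import labels_from_diagnosis
        from cptmethsig.simulate import PlantedTier
        cfg = SimulationConfig(n_probes=400, planted=(PlantedTier(40, 0.4),),
                               n_cpc_hom=4, n_cpc_het=4, n_cpc_wt=2,
                               n_acpp=2, n_cpp=8, n_promoter_linked=2,
                               n_body_linked=2, seed=13)
        cohort = simulate_cohort(cfg)
        labels = labels_from_diagnosis(cohort.metadata["diagnosis"])
        rng = np.random.default_rng(99)
        aurocs = []
        for _ in range(50):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            report = loo_cross_validate(cohort.beta, perm)
            aurocs.append(report.auroc)
        assert 0.3 <= np.mean(aurocs) <= 0.7
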