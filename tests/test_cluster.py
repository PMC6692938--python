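"""Hierarchical clustering, PCA and external-cohort projection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cptmethsig.cluster import (hierarchical_cluster, pca_project,
                                project_external)
from cptmethsig.diffmeth import Signature
from cptmethsig.io import BetaMatrix
from cptmethsig.simulate import (GROUP_PAPILLOMA, PlantedTier,
                                 SimulationConfig, simulate_cohort)


def _matrix(cols: dict) -> BetaMatrix:
    return BetaMatrix(pd.DataFrame(cols, index=[f"cg{i}" for i in
                                                range(len(next(iter(cols.values()))))]))


def test_duplicated_samples_merge_first_at_height_zero():
    rng = np.random.default_rng(0)
    x = rng.uniform(0.1, 0.9, 10)
    m = _matrix({"A": x, "B": x, "C": rng.uniform(0.1, 0.9, 10)})
    res = hierarchical_cluster(m, metric="euclidean", linkage="average", k=2)
    assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
    assert res.labels["A"] == res.labels["B"] != res.labels["C"]


def test_pearson_distance_ignores_affine_rescaling():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.1, 0.6, 20)
    m = _matrix({"A": x, "B": 0.4 * x + 0.2,
                 "C": rng.uniform(0.1, 0.9, 20)})
    res = hierarchical_cluster(m, metric="pearson", linkage="average", k=2)
    assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert res.labels["A"] == res.labels["B"]


def test_constant_profile_rejected_by_name():
    m = _matrix({"A": np.linspace(0.1, 0.9, 5),
                 "Flat": np.full(5, 0.5)})
    with pytest.raises(ValueError, match="Flat"):
        hierarchical_cluster(m, metric="pearson", k=2)


def test_two_planted_groups_recovered_exactly():
    cfg = SimulationConfig(n_probes=300, planted=(PlantedTier(60, 0.5),),
                           n_cpc_hom=0, n_cpc_het=3, n_cpc_wt=0,
                           n_acpp=0, n_cpp=3, tp53_extra_delta=0.0,
                           n_promoter_linked=2, n_body_linked=2, seed=4)
    cohort = simulate_cohort(cfg)
    planted = cohort.truth.loc[cohort.truth["planted"], "probe_id"]
    m = cohort.beta.restrict_probes(planted)
    res = hierarchical_cluster(m, metric="pearson", linkage="average", k=2)
    truth = (cohort.metadata["sim_group"] == GROUP_PAPILLOMA).astype(int)
    assert adjusted_rand_score(truth, res.labels) == 1.0


def test_three_group_trichotomy_recovered(recovery_cohort, recovery_filtered,
                                          recovery_tier2):
    """k=3 cut separates hom-TP53 carcinomas, other carcinomas, papillomas.

    Signature-level clustering uses the Euclidean metric: correlation
    distance is scale-free, so it cannot see a subgroup whose aberration
    amplifies the same CpG pattern."""
    m = recovery_filtered.restrict_probes(recovery_tier2.probe_ids)
    res = hierarchical_cluster(m, metric="euclidean", linkage="average", k=3)
    ari = adjusted_rand_score(recovery_cohort.metadata["sim_group"],
                              res.labels)
    assert ari >= 0.8


def test_partition_invariant_to_sample_order(recovery_filtered,
                                             recovery_tier2):
    m = recovery_filtered.restrict_probes(recovery_tier2.probe_ids)
    res1 = hierarchical_cluster(m, k=3)
    rng = np.random.default_rng(8)
    shuffled = m.restrict_samples(rng.permutation(m.sample_ids))
    res2 = hierarchical_cluster(shuffled, k=3)
    joined = pd.concat([res1.labels, res2.labels], axis=1)
    assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0


class TestPCA:
    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.9, 15)
        m = _matrix({"A": x, "B": x, "C": rng.uniform(0.1, 0.9, 15),
                     "D": rng.uniform(0.1, 0.9, 15)})
        scores, _ = pca_project(m, n_components=2)
        np.testing.assert_allclose(scores.loc["A"], scores.loc["B"],
                                   atol=1e-10)

    def test_two_samples_one_component_explains_everything(self):
        rng = np.random.default_rng(0)
        m = _matrix({"A": rng.uniform(0.1, 0.9, 10),
                     "B": rng.uniform(0.1, 0.9, 10)})
        _, evr = pca_project(m, n_components=3)
        assert evr[0] == pytest.approx(1.0)

    def test_explained_variance_non_increasing_and_bounded(self,
                                                           recovery_filtered,
                                                           recovery_tier2):
        m = recovery_filtered.restrict_probes(recovery_tier2.probe_ids)
        _, evr = pca_project(m)
        assert evr.sum() <= 1 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)

    def test_projection_reproducible(self, recovery_filtered, recovery_tier2):
        m = recovery_filtered.restrict_probes(recovery_tier2.probe_ids)
        s1, _ = pca_project(m)
        s2, _ = pca_project(m)
        pd.testing.assert_frame_equal(s1, s2)
        # sign convention: dominant loading positive => scores deterministic
        assert not s1.isna().any().any()


class TestProjection:
    def _signature(self, probes):
        return Signature(pd.DataFrame({
            "probe_id": probes, "gene": "", "delta_beta": 0.4,
            "q": 1e-4, "tier": "tier2"}), "tier2", 0.001, 0.40)

    def test_full_overlap_coverage_one(self, recovery_filtered,
                                       recovery_tier2):
        restricted, cov = project_external(recovery_filtered, recovery_tier2)
        assert cov == 1.0
        assert restricted.shape[0] == len(recovery_tier2)

    def test_partial_overlap_counts(self, recovery_filtered):
        probes = recovery_filtered.probe_ids[:50]
        sig = self._signature(list(probes) + [f"cgFAKE{i}" for i in range(9)])
        restricted, cov = project_external(recovery_filtered, sig)
        assert restricted.shape[0] == 50
        assert cov == pytest.approx(50 / 59)

    def test_zero_overlap_rejected(self, recovery_filtered):
        with pytest.raises(ValueError, match="no signature probes"):
            project_external(recovery_filtered, self._signature(["cgNOPE"]))

    def test_replication_cohort_separates_on_projected_signature(
            self, recovery_tier2):
        """An independent draw from the same generative groups clusters into
        carcinoma-like vs papilloma-like using the discovery signature."""
        from conftest import recovery_config
        import dataclasses
        cfg = dataclasses.replace(recovery_config(), seed=777,
                                  architecture_seed=101,
                                  cohort_label="replication")
        rep = simulate_cohort(cfg)
        restricted, cov = project_external(rep.beta, recovery_tier2)
        assert cov > 0.9
        res = hierarchical_cluster(restricted, metric="euclidean",
                                   linkage="average", k=2)
        truth = (rep.metadata["sim_group"] == GROUP_PAPILLOMA).astype(int)
        assert adjusted_rand_score(truth, res.labels) >= 0.8
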