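"""Mann-Whitney differential methylation, BH-FDR, tiers, volcano, r^2."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cptmethsig.diffmeth import (bh_fdr, differential_methylation,
                                 extract_signature, labels_from_diagnosis,
                                 mann_whitney_per_probe, platform_concordance,
                                 r_squared, volcano_table)
from cptmethsig.io import BetaMatrix


def _matrix_from_groups(carc, pap):
    """Single- or multi-probe matrix plus labels from per-group value lists."""
    carc, pap = np.atleast_2d(carc), np.atleast_2d(pap)
    vals = np.hstack([carc, pap])
    cols = [f"C{i}" for i in range(carc.shape[1])] + \
           [f"P{i}" for i in range(pap.shape[1])]
    m = BetaMatrix(pd.DataFrame(vals, columns=cols,
                                index=[f"cg{i}" for i in range(vals.shape[0])]))
    labels = pd.Series(["carcinoma"] * carc.shape[1] +
                       ["papilloma"] * pap.shape[1], index=cols)
    return m, labels


def exact_mw_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sps.mannwhitneyu(x, y, method="asymptotic").statistic  # U only
    dist = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        # U for the first group via rank sum
        ranks = sps.rankdata(np.concatenate([xs, ys]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        dist.append(u)
    dist = np.asarray(dist)
    lo = np.mean(dist <= u_obs + 1e-9)
    hi = np.mean(dist >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_separated_triples_give_exact_p_point_one(self):
        m, labels = _matrix_from_groups([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        res = mann_whitney_per_probe(m, labels)
        assert res["u"].iloc[0] == 0
        assert res["p_raw"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert res["delta_beta"].iloc[0] == pytest.approx(-0.3)

    def test_identical_groups_give_p_one(self):
        m, labels = _matrix_from_groups([0.2, 0.5, 0.8], [0.8, 0.2, 0.5])
        res = mann_whitney_per_probe(m, labels)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_exact_p_matches_permutation_enumeration(self):
        """Brute-force enumeration over all C(n, n1) assignments, n <= 12."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1 = rng.integers(2, 7)
            n2 = rng.integers(2, 13 - n1)
            x = rng.uniform(0, 1, n1).round(4)
            y = rng.uniform(0, 1, n2).round(4)
            if len(np.unique(np.concatenate([x, y]))) < n1 + n2:
                continue
            m, labels = _matrix_from_groups(x, y)
            got = mann_whitney_per_probe(m, labels)["p_raw"].iloc[0]
            assert got == pytest.approx(exact_mw_oracle(x, y), abs=1e-12)

    def test_label_swap_negates_delta_and_keeps_p(self, recovery_filtered,
                                                  recovery_labels):
        swapped = recovery_labels.map(
            {"carcinoma": "papilloma", "papilloma": "carcinoma"})
        sub = BetaMatrix(recovery_filtered.values.iloc[:100])
        a = mann_whitney_per_probe(sub, recovery_labels)
        b = mann_whitney_per_probe(sub, swapped)
        np.testing.assert_allclose(a["delta_beta"], -b["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], rtol=1e-10)

    def test_probe_with_empty_group_skipped(self):
        vals = pd.DataFrame({"C0": [0.1, np.nan], "C1": [0.2, np.nan],
                             "P0": [0.8, 0.5], "P1": [0.9, 0.6]},
                            index=["cgA", "cgB"])
        labels = pd.Series(["carcinoma", "carcinoma", "papilloma", "papilloma"],
                           index=vals.columns)
        res = mann_whitney_per_probe(BetaMatrix(vals), labels)
        assert list(res["probe_id"]) == ["cgA"]

    def test_empty_class_is_configuration_error(self):
        m, labels = _matrix_from_groups([0.1, 0.2], [0.8, 0.9])
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_per_probe(m, labels.replace("papilloma", "carcinoma"))


class TestBH:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_matches_reference_step_up_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSignature:
    def test_tier2_is_subset_of_tier1(self, recovery_diffmeth):
        t1 = set(extract_signature(recovery_diffmeth, "tier1").probe_ids)
        t2 = set(extract_signature(recovery_diffmeth, "tier2").probe_ids)
        assert t2 <= t1

    def test_planted_probes_recovered(self, recovery_cohort, recovery_tier2):
        truth = recovery_cohort.truth
        planted = set(truth.loc[truth["planted"], "probe_id"])
        found = set(recovery_tier2.probe_ids)
        assert len(found & planted) / len(planted) >= 0.90
        assert len(found - planted) / max(len(found), 1) <= 0.05

    def test_records_pass_their_thresholds(self, recovery_tier1):
        t = recovery_tier1.table
        assert (t["q"] < 0.05).all()
        assert (t["delta_beta"].abs() >= 0.30).all()

    def test_direction_counts_sum(self, recovery_tier1):
        d = recovery_tier1.direction_counts
        assert d["hyper"] + d["hypo"] == len(recovery_tier1)


class TestVolcano:
    def test_log_arithmetic(self):
        res = pd.DataFrame({"probe_id": ["a", "b"], "p_raw": [0.01, 1.0],
                            "delta_beta": [0.5, 0.0],
                            "tier": ["tier1", "none"]})
        v = volcano_table(res)
        assert v["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        assert v["neg_log10_p"].iloc[1] == 0.0
        assert len(v) == len(res)


class TestConcordance:
    def test_perfect_correlation(self):
        assert r_squared([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_hand_pearson(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9643, abs=1e-4)

    def test_constant_vector_is_missing_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = r_squared([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert np.isnan(out)

    def test_platform_concordance_on_replicate_arrays(self, small_cohort):
        a = small_cohort.beta
        rng = np.random.default_rng(3)
        noisy = np.clip(a.values + rng.normal(0, 0.01, a.values.shape), 0, 1)
        b = BetaMatrix(pd.DataFrame(noisy, index=a.values.index,
                                    columns=a.values.columns))
        r2 = platform_concordance(a, b).dropna()
        assert ((r2 >= 0) & (r2 <= 1)).all()
        assert r2.median() > 0.9
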