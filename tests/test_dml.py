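import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from methyldelay import dml
from methyldelay.dml import (
    ComparisonSpec,
    DMLDetector,
    call_dml,
    cluster_samples,
    ks_two_sample,
    permutation_pvalues,
    probe_stats,
    squeeze_variances,
    trigamma_inverse,
    ttest_two_sample,
)


def brute_force_exhaustive_p(X, n1):
    """Plain-loop oracle: enumerate every balanced assignment, compute the
    moderated t per assignment with scalar arithmetic, count as the
    vectorised engine should."""
    n = X.shape[1]
    n2 = n - n1
    d = n1 + n2 - 2

    def t_for(case_idx):
        case = X[:, list(case_idx)]
        ctrl = X[:, [j for j in range(n) if j not in case_idx]]
        delta = case.mean(axis=1) - ctrl.mean(axis=1)
        s2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / d
        s2_post, _, _ = squeeze_variances(s2, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(s2_post * (1 / n1 + 1 / n2))
        t[np.isnan(t)] = 0.0
        return t

    t_obs = t_for(tuple(range(n1)))
    counts = np.zeros(X.shape[0])
    combos = list(itertools.combinations(range(n), n1))
    for combo in combos:
        counts += np.abs(t_for(combo)) >= np.abs(t_obs) - 1e-12
    return counts / len(combos)


class TestShrinkage:
    def test_identical_variances_are_a_fixed_point(self):
        s2 = np.full(200, 0.04)
        s2_post, d0, s0 = squeeze_variances(s2, d=10)
        np.testing.assert_allclose(s2_post, s2, rtol=1e-10)

    def test_moderated_variance_interpolates(self):
        rng = np.random.default_rng(0)
        s2 = rng.uniform(0.001, 0.2, size=50)
        s2_post, d0, s0 = squeeze_variances(s2, d=10)
        assert 0 < d0 < np.inf
        lo = np.minimum(s2, s0) - 1e-12
        hi = np.maximum(s2, s0) + 1e-12
        assert ((s2_post >= lo) & (s2_post <= hi)).all()

    def test_trigamma_inverse_inverts(self):
        from scipy.special import polygamma

        x = np.array([0.1, 0.5, 1.0, 5.0, 50.0])
        y = polygamma(1, x)
        np.testing.assert_allclose(trigamma_inverse(y), x, rtol=1e-6)

    def test_all_zero_variance_falls_back_with_warning(self):
        s2 = np.zeros(20)
        with pytest.warns(RuntimeWarning, match="unmoderated"):
            s2_post, d0, _ = squeeze_variances(s2, d=4)
        np.testing.assert_array_equal(s2_post, s2)


class TestProbeStats:
    def test_delta_beta_is_difference_of_group_means(self):
        betas = pd.DataFrame(
            {"c1": [0.9], "c2": [0.9], "k1": [0.1], "k2": [0.1]}, index=["p1"]
        )
        spec = ComparisonSpec(("c1", "c2"), ("k1", "k2"), "toy")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = probe_stats(betas, spec)
        assert table.loc["p1", "delta_beta"] == pytest.approx(0.8)
        assert table.loc["p1", "mean_case"] == pytest.approx(0.9)

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ComparisonSpec(("a", "b"), ("b", "c"))

    def test_single_sample_arm_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            ComparisonSpec(("a",), ("b", "c"))


class TestPermutationPvalues:
    def test_hand_enumerated_two_vs_two(self):
        betas = pd.DataFrame(
            {"c1": [0.9], "c2": [0.9], "k1": [0.1], "k2": [0.1]}, index=["p1"]
        )
        spec = ComparisonSpec(("c1", "c2"), ("k1", "k2"), "toy")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = permutation_pvalues(betas, spec)
        # of the 6 balanced assignments only the identity and its complement
        # reach |t_obs|
        assert p.loc["p1"] == pytest.approx(2 / 6)

    def test_degenerate_equal_groups_give_p_one(self):
        betas = pd.DataFrame(
            {"c1": [0.5, 0.2], "c2": [0.5, 0.2], "k1": [0.5, 0.2], "k2": [0.5, 0.2]},
            index=["p1", "p2"],
        )
        spec = ComparisonSpec(("c1", "c2"), ("k1", "k2"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = permutation_pvalues(betas, spec)
        assert (p == 1.0).all()

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0.1, 0.9, size=(40, 8))
        betas = pd.DataFrame(X, columns=[f"s{i}" for i in range(8)])
        spec = ComparisonSpec(("s0", "s1", "s2", "s3"), ("s4", "s5", "s6", "s7"))
        p = permutation_pvalues(betas, spec, mode="exhaustive")
        expected = brute_force_exhaustive_p(X, 4)
        np.testing.assert_allclose(p.to_numpy(), expected, atol=1e-12)

    def test_zero_permutations_rejected(self):
        betas = pd.DataFrame(np.full((3, 6), 0.5), columns=list("abcdef"))
        spec = ComparisonSpec(("a", "b", "c"), ("d", "e", "f"))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_pvalues(betas, spec, n_perm=0, mode="montecarlo")

    def test_small_monte_carlo_warns(self):
        rng = np.random.default_rng(1)
        betas = pd.DataFrame(
            rng.uniform(size=(5, 6)), columns=list("abcdef")
        )
        spec = ComparisonSpec(("a", "b", "c"), ("d", "e", "f"))
        with pytest.warns(RuntimeWarning, match="small"):
            permutation_pvalues(betas, spec, n_perm=50, mode="montecarlo", seed=0)

    def test_label_swap_preserves_p_and_negates_stats(self):
        rng = np.random.default_rng(3)
        betas = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(30, 8)), columns=[f"s{i}" for i in range(8)]
        )
        fwd = ComparisonSpec(("s0", "s1", "s2", "s3"), ("s4", "s5", "s6", "s7"))
        rev = ComparisonSpec(("s4", "s5", "s6", "s7"), ("s0", "s1", "s2", "s3"))
        t_fwd = probe_stats(betas, fwd)
        t_rev = probe_stats(betas, rev)
        np.testing.assert_allclose(t_rev["delta_beta"], -t_fwd["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(t_rev["t_mod"], -t_fwd["t_mod"], atol=1e-9)
        p_fwd = permutation_pvalues(betas, fwd)
        p_rev = permutation_pvalues(betas, rev)
        np.testing.assert_allclose(p_fwd, p_rev, atol=1e-12)


class TestCallDML:
    @pytest.fixture()
    def stats_and_p(self):
        table = pd.DataFrame(
            {
                "mean_case": [0.5, 0.6, 0.7],
                "mean_control": [0.41, 0.45, 0.55],
                "delta_beta": [0.09, 0.15, 0.15],
                "t_mod": [5.0, 2.0, 6.0],
            },
            index=["pA", "pB", "pC"],
        )
        pvals = pd.Series([0.001, 0.20, 0.01], index=table.index)
        return table, pvals

    def test_effect_size_gate(self, stats_and_p):
        table, pvals = stats_and_p
        called = call_dml(table, pvals)
        assert "pA" not in called.probe_ids  # |delta| = 0.09 < 0.10

    def test_pvalue_gate(self, stats_and_p):
        table, pvals = stats_and_p
        called = call_dml(table, pvals)
        assert "pB" not in called.probe_ids  # p = 0.20
        assert called.probe_ids == {"pC"}

    def test_invariant_to_probe_order(self, stats_and_p):
        table, pvals = stats_and_p
        shuffled = table.iloc[[2, 0, 1]]
        a = call_dml(table, pvals)
        b = call_dml(shuffled, pvals.loc[shuffled.index])
        pd.testing.assert_frame_equal(a.table, b.table)


class TestDetectorEstimator:
    def test_sklearn_api_round_trip(self):
        det = DMLDetector(alpha=0.01, n_perm=199)
        params = det.get_params()
        assert params["alpha"] == 0.01
        cloned = clone(det)
        assert cloned.get_params() == params

    def test_fit_transform_selects_planted_probe(self):
        rng = np.random.default_rng(5)
        n = 12
        X = rng.normal(0.5, 0.02, size=(n, 30)).clip(0, 1)
        X[:6, 0] += 0.2  # plant one strong DML in the cases
        y = np.array([1] * 6 + [0] * 6)
        det = DMLDetector(random_state=0).fit(X, y)
        assert det.support_[0]
        assert det.mode_used_ == "exhaustive"  # C(12,6) = 924 <= 2000
        kept = det.transform(X)
        assert kept.shape[1] == det.support_.sum()

    def test_recovery_on_simulated_cohort(self, small_dataset):
        data = small_dataset
        samples = data.samples
        betas = data.betas.loc[~data.manifest.set_index("probe_id")["snp_flag"].values]
        sub = samples[samples.age_group == "young"]
        spec = ComparisonSpec(
            tuple(sub.loc[sub.diagnosis == "autism", "sample_id"]),
            tuple(sub.loc[sub.diagnosis == "control", "sample_id"]),
            "young",
        )
        called = dml.run_comparison(betas, spec, seed=1)
        truth = data.truth.dml_probe_ids["young"] & set(betas.index)
        recovered = truth & called.probe_ids
        assert len(recovered) / len(truth) >= 0.9


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        betas = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5], "s3": [0.9, 0.9]})
        Z, order = cluster_samples(betas)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_one_dimensional_toy_heights(self):
        # complete linkage on {0, 1, 10}: merge (0,1) at height 1, then the
        # pair with 10 at height max(10, 9) = 10
        betas = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [10.0]})
        Z, order = cluster_samples(betas)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(10.0)

    def test_single_sample_trivial_tree(self):
        betas = pd.DataFrame({"only": [0.1, 0.2]})
        Z, order = cluster_samples(betas)
        assert Z.shape == (0, 4)
        assert order == ["only"]

    def test_two_clusters_separate_diagnoses_on_planted_dml(self, small_dataset):
        data = small_dataset
        sub = data.samples[data.samples.age_group == "middle"]
        ids = sorted(data.truth.dml_probe_ids["middle"])
        betas = data.betas.loc[ids, sub["sample_id"]]
        Z, order = cluster_samples(betas)
        assignments = dml.cut_clusters(Z, list(betas.columns), 2)
        diag = sub.set_index("sample_id")["diagnosis"]
        clusters_per_diag = {
            d: {assignments[s] for s in sub["sample_id"] if diag[s] == d}
            for d in ("autism", "control")
        }
        assert clusters_per_diag["autism"].isdisjoint(clusters_per_diag["control"])


class TestDistributionTests:
    def test_ks_identical_samples(self):
        d, _ = ks_two_sample([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert d == pytest.approx(0.0)

    def test_ks_disjoint_supports(self):
        d, _ = ks_two_sample([0.1, 0.2], [0.8, 0.9])
        assert d == pytest.approx(1.0)

    def test_ks_hand_computed_ecdf(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [2, 3, 4, 5])
        assert d == pytest.approx(0.25)

    def test_ks_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_t_equal_constant_samples(self):
        t, p = ttest_two_sample([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_t_identical_samples_p_one(self):
        _, p = ttest_two_sample([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_t_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1e-3, size=4)
        b = 1.0 + rng.normal(0.0, 1e-3, size=4)
        _, p = ttest_two_sample(a, b)
        assert p < 0.001
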