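"""Group statistics: effect sizes, correlations, cluster tests, comparability."""

import math
from itertools import product

import numpy as np
import pytest
import scipy.stats

from stnpower.stats import (
    bonferroni_confidence_level,
    bootstrap_spectrum_se,
    cluster_permutation_test,
    cohens_d_band,
    correlate_with_ci,
    dataset_comparability,
    frequency_correlation_profile,
    required_sample_size,
    significant_runs,
)


class TestCohensD:
    def test_identical_samples_give_zero_with_ci_containing_zero(self):
        x = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        with pytest.raises(ValueError, match="zero variance"):
            cohens_d_band(x, x, paired=True, n_boot=100)
        res = cohens_d_band(x, x, paired=False, n_boot=500, seed=1)
        assert res.d == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.significant

    def test_constructed_unit_effect(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(40)
        diff = rng.standard_normal(40)
        diff = (diff - diff.mean()) / diff.std(ddof=1) + 1.0  # mean 1, SD 1
        res = cohens_d_band(y + diff, y, paired=True, n_boot=200, seed=3)
        assert res.d == pytest.approx(1.0, abs=1e-9)

    def test_bonferroni_level_for_six_bands(self):
        level = bonferroni_confidence_level(6)
        assert level == pytest.approx(1.0 - 0.05 / 6.0, abs=1e-15)
        assert round(level, 3) == 0.992  # the conventionally printed value

    def test_strong_effect_flagged_significant_at_bonferroni_level(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.5, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        res = cohens_d_band(x, y, paired=True, conf_level=0.992, n_boot=2000, seed=5)
        assert res.significant


class TestCorrelation:
    def test_monotone_pair_gives_rho_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        res = correlate_with_ci(x, np.exp(x), n_boot=200, seed=0)
        assert res.coefficient == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_spearman(self):
        # d = (0, 1, 1, 0), rho = 1 - 6*2/(4*15) = 0.8
        res = correlate_with_ci(
            np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]), n_boot=100, seed=0
        )
        assert res.coefficient == pytest.approx(0.8)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 10, 50)
        y = rng.uniform(1, 10, 50)
        a = correlate_with_ci(x, y, n_boot=100, seed=7).coefficient
        b = correlate_with_ci(np.log(x), y, n_boot=100, seed=7).coefficient
        assert a == pytest.approx(b)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_with_ci(np.ones(10), np.arange(10.0), n_boot=10)

    def test_bootstrap_ci_brackets_coefficient(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        res = correlate_with_ci(x, y, n_boot=2000, seed=9)
        assert res.ci_low <= res.coefficient <= res.ci_high


class TestRequiredSampleSize:
    def test_fisher_z_oracle(self):
        """Independent closed-form evaluation, frozen from the formula."""
        for rho, power, alpha in [(0.26, 0.8, 0.05), (0.5, 0.8, 0.05)]:
            z_a = scipy.stats.norm.ppf(1 - alpha / 2)
            z_b = scipy.stats.norm.ppf(power)
            expected = math.ceil(((z_a + z_b) / math.atanh(rho)) ** 2 + 3)
            assert required_sample_size(rho, power, alpha) == expected
        # rho = 0.26 gives 114 from this formula; exact-power variants land
        # a couple of patients higher, hence the documented formula note
        assert required_sample_size(0.26) == 114

    def test_monotone_in_rho(self):
        sizes = [required_sample_size(r) for r in (0.1, 0.2, 0.3, 0.5, 0.8)]
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError):
            required_sample_size(rho)


def _exhaustive_paired_oracle(diff, alpha=0.05):
    """Brute-force sign-flip enumeration for the paired cluster test."""
    n, F = diff.shape
    flips = np.array(list(product((1.0, -1.0), repeat=n)))
    stats = flips @ diff / n
    obs = diff.mean(axis=0)
    B = stats.shape[0]
    bin_p = (np.abs(stats) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
    # per-permutation pseudo p by direct counting (O(B^2), fine at n = 3)
    pseudo = np.array(
        [
            [(np.abs(stats[:, j]) >= abs(stats[b, j]) - 1e-12).mean() for j in range(F)]
            for b in range(B)
        ]
    )
    def clusters(mask, vals):
        out, j = [], 0
        while j < F:
            if mask[j]:
                k = j
                while k + 1 < F and mask[k + 1]:
                    k += 1
                out.append((j, k, abs(vals[j : k + 1].sum())))
                j = k + 1
            else:
                j += 1
        return out
    null_max = []
    for b in range(B):
        cl = clusters(pseudo[b] < alpha, stats[b])
        null_max.append(max((c[2] for c in cl), default=0.0))
    null_max = np.array(null_max)
    obs_clusters = clusters(bin_p < alpha, obs)
    cluster_p = [(null_max >= c[2] - 1e-12).mean() for c in obs_clusters]
    return bin_p, obs_clusters, cluster_p


class TestClusterPermutation:
    def test_identical_conditions_produce_no_clusters(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((8, 30))
        res = cluster_permutation_test(a, a.copy(), paired=True, n_perm=500, seed=0)
        assert res.clusters == []
        assert np.all(res.statistic == 0)

    def test_three_subject_paired_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((3, 12))
        b = rng.standard_normal((3, 12)) + 0.8
        res = cluster_permutation_test(a, b, paired=True, n_perm=1000, seed=1)
        assert res.exhaustive and res.n_permutations == 8
        bin_p, obs_clusters, cluster_p = _exhaustive_paired_oracle(a - b)
        np.testing.assert_allclose(res.bin_p, bin_p, atol=1e-12)
        assert len(res.clusters) == len(obs_clusters)
        np.testing.assert_allclose(res.cluster_p, cluster_p, atol=1e-12)

    def test_planted_offset_recovers_cluster_extent(self):
        rng = np.random.default_rng(12)
        freqs = np.arange(2.0, 61.0)
        n = 20
        a = rng.standard_normal((n, freqs.size))
        b = rng.standard_normal((n, freqs.size))
        plant = (freqs >= 10) & (freqs <= 20)
        a[:, plant] += 3.0
        res = cluster_permutation_test(a, b, paired=True, n_perm=2000, seed=2,
                                       frequencies=freqs)
        sig = res.significant_clusters
        assert sig, "planted effect must produce a significant cluster"
        lo, hi = sig[0]
        assert lo <= 12 and hi >= 18  # extent covers 10-20 Hz within +/-2 bins

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            cluster_permutation_test(np.zeros((3, 5)), np.zeros((3, 6)))

    def test_unpaired_small_groups_run_exhaustively(self):
        rng = np.random.default_rng(13)
        a = rng.standard_normal((4, 6))
        b = rng.standard_normal((3, 6))
        res = cluster_permutation_test(a, b, paired=False, n_perm=100, seed=3)
        assert res.exhaustive and res.n_permutations == math.comb(7, 4)

    def test_doubling_permutations_changes_p_within_mc_error(self):
        rng = np.random.default_rng(14)
        a = rng.standard_normal((12, 20))
        b = rng.standard_normal((12, 20))
        a[:, 5:9] += 1.0
        r1 = cluster_permutation_test(a, b, paired=True, n_perm=2000, seed=4)
        r2 = cluster_permutation_test(a, b, paired=True, n_perm=4000, seed=5)
        for p1, p2 in zip(r1.cluster_p, r2.cluster_p):
            se = math.sqrt(p1 * (1 - p1) / 2000) if 0 < p1 < 1 else 0.03
            assert abs(p1 - p2) < 4 * se + 1e-3


class TestFrequencyProfile:
    def test_null_scores_give_near_nominal_rate(self):
        rng = np.random.default_rng(15)
        powers = rng.standard_normal((40, 200))
        scores = rng.standard_normal(40)
        prof = frequency_correlation_profile(powers, scores)
        rate = prof["significant"].mean()
        assert rate < 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / 200)

    def test_planted_link_found_in_band(self):
        rng = np.random.default_rng(16)
        scores = rng.standard_normal(60)
        freqs = np.arange(2.0, 45.0)
        powers = rng.standard_normal((60, freqs.size))
        plant = (freqs >= 14) & (freqs <= 18)
        powers[:, plant] += 1.5 * scores[:, None]
        prof = frequency_correlation_profile(powers, scores, frequencies=freqs)
        runs = significant_runs(prof)
        assert any(lo <= 14 and hi >= 18 for lo, hi in runs)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            frequency_correlation_profile(np.random.default_rng(0).random((10, 5)), np.ones(10))


class TestDatasetComparability:
    def test_tiny_groups_match_brute_force_rank_permutation(self):
        groups = {"a": [1.2, 3.4, 2.2], "b": [5.1, 4.4, 6.0, 5.5]}
        h, p, _ = dataset_comparability(groups, exact=True)
        # independent oracle: enumerate every assignment of pooled ranks
        from itertools import combinations

        pooled = np.array(groups["a"] + groups["b"])
        ranks = scipy.stats.rankdata(pooled)
        def hstat(r1, r2):
            n = len(r1) + len(r2)
            return (12 / (n * (n + 1))) * (
                sum(r1) ** 2 / len(r1) + sum(r2) ** 2 / len(r2)
            ) - 3 * (n + 1)
        obs = hstat(ranks[:3], ranks[3:])
        assert h == pytest.approx(obs, abs=1e-10)
        count = total = 0
        for comb in combinations(range(7), 3):
            r1 = ranks[list(comb)]
            r2 = ranks[[i for i in range(7) if i not in comb]]
            total += 1
            if hstat(r1, r2) >= obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            vals = rng.standard_normal(30)
            groups = {"a": vals[:10], "b": vals[10:20], "c": vals[20:]}
            _, p, _ = dataset_comparability(groups, exact=False)
            hits += p < 0.05
        assert hits / n_rep < 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_shifted_group_flagged_by_dunn(self):
        rng = np.random.default_rng(18)
        groups = {
            "a": rng.standard_normal(15),
            "b": rng.standard_normal(15),
            "c": rng.standard_normal(15) + 5.0,
        }
        h, p, posthoc = dataset_comparability(groups)
        assert p < 0.05
        sig = posthoc[posthoc["significant"]]
        flagged_pairs = {frozenset((r.group_a, r.group_b)) for r in sig.itertuples()}
        assert flagged_pairs == {frozenset(("a", "c")), frozenset(("b", "c"))}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dataset_comparability({"a": [1.0, 2.0], "b": []})


class TestBootstrapSpectrumSE:
    def test_identical_spectra_give_zero_se(self):
        arr = np.tile(np.linspace(1, 2, 30), (8, 1))
        np.testing.assert_allclose(bootstrap_spectrum_se(arr, seed=0), 0.0, atol=1e-12)

    def test_matches_analytic_standard_error(self):
        rng = np.random.default_rng(19)
        sigma, n = 2.0, 50
        arr = rng.normal(0, sigma, (n, 40))
        se = bootstrap_spectrum_se(arr, n_boot=2000, seed=1)
        assert se.mean() == pytest.approx(sigma / math.sqrt(n), rel=0.15)

    def test_invariant_to_bin_reordering(self):
        rng = np.random.default_rng(20)
        arr = rng.random((10, 25))
        perm = rng.permutation(25)
        se = bootstrap_spectrum_se(arr, n_boot=500, seed=2)
        se_perm = bootstrap_spectrum_se(arr[:, perm], n_boot=500, seed=2)
        np.testing.assert_allclose(se[perm], se_perm, atol=1e-12)

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_spectrum_se(np.ones((1, 10)))
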