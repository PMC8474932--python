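import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xci_scstruct.cdp import CDProfile, cdp_bin_edges, normalize_cdp, rebin_cdp
from xci_scstruct.structure import (LMDRanges, ThresholdSpec, call_bipartite,
                                    call_population, cdp_spearman, classifier_roc,
                                    delta_lmd, embedding_timepoint_auc, fpr_threshold,
                                    lmd, proportion_bipartite, recovered_fraction,
                                    statistics_table)

SCHEME = cdp_bin_edges()
RANGES = LMDRanges()


def make_profile(long=0.0, mid=0.0, elsewhere=0.0, cell="c", allele="hap1"):
    """Normalized profile with the given mass split over the LMD windows."""
    counts = np.zeros(143)
    mid_bins, long_bins = RANGES.mid_bins(SCHEME), RANGES.long_bins(SCHEME)
    other = np.setdiff1d(np.arange(143), np.concatenate([mid_bins, long_bins]))
    counts[long_bins] = long / len(long_bins)
    counts[mid_bins] = mid / len(mid_bins)
    counts[other] = elsewhere / len(other)
    return CDProfile(cell, "chrX", allele, counts, normalized=True, n_contacts=1000)


class TestLMD:
    def test_range_bins_are_exact_unions(self):
        assert list(RANGES.mid_bins(SCHEME)) == list(range(51, 80))
        assert list(RANGES.long_bins(SCHEME)) == list(range(101, 131))

    @pytest.mark.parametrize("long, mid, elsewhere, expected", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 1.0, 0.0, -1.0),
        (0.6, 0.3, 0.1, 0.3),
    ])
    def test_mass_split_examples(self, long, mid, elsewhere, expected):
        assert lmd(make_profile(long, mid, elsewhere)) == pytest.approx(expected)

    def test_zero_coverage_is_nan(self):
        p = CDProfile("c", "chrX", "hap1", np.zeros(143), n_contacts=0)
        assert math.isnan(lmd(p))

    def test_raw_profile_normalized_internally(self):
        counts = np.zeros(143)
        counts[110] = 500  # all mass long-range
        p = CDProfile("c", "chrX", "hap1", counts, n_contacts=500)
        assert lmd(p) == pytest.approx(1.0)


class TestDeltaLMD:
    def test_identical_profiles_give_zero(self):
        p = make_profile(0.5, 0.3, 0.2)
        assert delta_lmd(p, p) == pytest.approx(0.0)

    def test_opposite_point_masses(self):
        assert delta_lmd(make_profile(long=1.0), make_profile(mid=1.0)) == pytest.approx(2.0)

    def test_antisymmetry_under_allele_swap(self):
        a, b = make_profile(0.7, 0.1, 0.2), make_profile(0.2, 0.5, 0.3)
        assert delta_lmd(a, b) == pytest.approx(-delta_lmd(b, a))

    def test_missing_allele_is_nan(self):
        zero = CDProfile("c", "chrX", "hap2", np.zeros(143), n_contacts=0)
        assert math.isnan(delta_lmd(make_profile(1.0), zero))


class TestSpearman:
    def test_identity(self):
        a = np.arange(14.0)
        assert cdp_spearman(a, a) == pytest.approx(1.0)

    def test_reversal(self):
        a = np.arange(14.0)
        assert cdp_spearman(a, a[::-1]) == pytest.approx(-1.0)

    def test_against_rank_then_pearson_oracle(self):
        a = np.arange(1.0, 15.0)
        b = np.concatenate([np.arange(1.0, 14.0), [0.0]])
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert cdp_spearman(a, b) == pytest.approx(expected)

    def test_constant_vector_is_nan(self):
        assert math.isnan(cdp_spearman(np.ones(14), np.arange(14.0)))


class TestFPRThreshold:
    def test_nearest_rank_on_1_to_10(self):
        spec = fpr_threshold(np.arange(1, 11), fpr=0.10)
        assert spec.threshold == 9
        assert sum(spec.is_called(v) for v in range(1, 11)) == 1  # only 10

    def test_degenerate_all_zero_null(self):
        spec = fpr_threshold(np.zeros(50), fpr=0.10)
        assert spec.threshold == 0.0
        assert spec.is_called(0.01) and not spec.is_called(0.0)

    def test_median_at_half(self):
        null = np.arange(-50, 51)  # symmetric, |null| quantile
        spec = fpr_threshold(null, fpr=0.5)
        assert spec.threshold == np.sort(np.abs(null))[int(np.ceil(0.5 * len(null))) - 1]

    def test_spearman_direction_low_quantile(self):
        null = np.linspace(0.5, 1.0, 100)
        spec = fpr_threshold(null, fpr=0.10, direction="less", statistic="spearman_cdp")
        called = sum(spec.is_called(v) for v in null)
        assert called <= 10

    def test_calls_on_own_null_never_exceed_fpr(self):
        rng = np.random.default_rng(5)
        for n in (7, 50, 333):
            null = rng.normal(size=n)
            spec = fpr_threshold(null, fpr=0.10)
            assert sum(spec.is_called(v) for v in null) <= math.floor(0.10 * n)

    def test_empty_null_is_error(self):
        with pytest.raises(ValueError):
            fpr_threshold([], fpr=0.10)


class TestCallBipartite:
    SPEC = ThresholdSpec("delta_lmd", 0.2, 0.1, "abs_greater", 100)

    def test_statistic_equal_to_threshold_not_called(self):
        a, b = make_profile(0.55, 0.25, 0.2), make_profile(0.25, 0.15, 0.6)
        d = delta_lmd(a, b)
        spec = ThresholdSpec("delta_lmd", abs(d), 0.1, "abs_greater", 100)
        call = call_bipartite("c", a, b, spec_lmd=spec)
        assert not call.is_bipartite and call.xi_allele == "none"

    def test_higher_lmd_homolog_is_xi(self):
        call = call_bipartite("c", make_profile(long=0.9, elsewhere=0.1),
                              make_profile(mid=0.5, elsewhere=0.5), spec_lmd=self.SPEC)
        assert call.is_bipartite and call.xi_allele == "hap1"
        assert call.delta_lmd > 0

    def test_symmetry_under_relabeling(self):
        a, b = make_profile(long=0.9, elsewhere=0.1), make_profile(mid=0.5, elsewhere=0.5)
        fwd = call_bipartite("c", a, b, spec_lmd=self.SPEC)
        rev = call_bipartite("c", b, a, spec_lmd=self.SPEC)
        assert fwd.is_bipartite == rev.is_bipartite
        assert fwd.delta_lmd == pytest.approx(-rev.delta_lmd)
        assert {fwd.xi_allele, rev.xi_allele} == {"hap1", "hap2"}

    def test_spearman_mode_above_threshold_not_called(self):
        rho_spec = ThresholdSpec("spearman_cdp", 0.5, 0.1, "less", 100)
        a = make_profile(0.3, 0.3, 0.4)
        call = call_bipartite("c", a, a, spec_rho=rho_spec)
        assert call.rho == pytest.approx(1.0) and not call.is_bipartite


class TestROC:
    def test_perfect_separation(self):
        _, auc = classifier_roc([5.0, 6.0, 7.0], [0.1, 0.2])
        assert auc == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(7)
        pooled = rng.normal(size=4000)
        _, auc = classifier_roc(pooled[:2000], pooled[2000:])
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_point_each(self):
        _, auc = classifier_roc([2.0], [1.0])
        assert auc == 1.0

    def test_agrees_with_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        x, y = rng.normal(1.0, 1.0, 300), rng.normal(0.0, 1.0, 400)
        _, auc = classifier_roc(x, y)
        expected = roc_auc_score(np.r_[np.ones(300), np.zeros(400)],
                                 np.abs(np.r_[x, y]))
        assert auc == pytest.approx(expected, abs=1e-9)


class TestEmbeddingAUC:
    def test_collapsed_clusters_are_perfect(self):
        emb = np.array([[0, 0]] * 5 + [[10, 10]] * 5, dtype=float)
        labels = ["a"] * 5 + ["b"] * 5
        assert embedding_timepoint_auc(emb, labels) == pytest.approx(1.0)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(9)
        emb = rng.normal(size=(200, 3))
        labels = rng.integers(0, 4, 200)
        assert embedding_timepoint_auc(emb, labels) == pytest.approx(0.5, abs=0.05)

    def test_two_pairs_on_a_line(self):
        emb = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert embedding_timepoint_auc(emb, ["a", "a", "b", "b"]) == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        emb = rng.normal(size=(60, 2)) + np.repeat([[0, 0], [4, 4], [8, 0]], 20, axis=0)
        labels = np.repeat(["a", "b", "c"], 20)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = embedding_timepoint_auc(emb, labels)
        b = embedding_timepoint_auc(emb @ rot.T, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_singleton_label_excluded_with_warning(self):
        emb = np.array([[0.0], [1.0], [5.0], [6.0], [99.0]])
        labels = ["a", "a", "b", "b", "lonely"]
        with pytest.warns(UserWarning, match="lonely"):
            auc = embedding_timepoint_auc(emb, labels)
        assert auc == pytest.approx(1.0)


class TestProportions:
    def test_basic_percentages(self):
        calls = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(10)],
            "time_point": ["d0"] * 10,
            "is_bipartite": [True] * 8 + [False] * 2,
            "xi_allele": ["hap1"] * 6 + ["hap2"] * 2 + ["none"] * 2,
        })
        out = proportion_bipartite(calls)
        assert out.loc[0, "pct_bipartite"] == 80.0
        assert out.loc[0, "pct_xi_hap1"] == 60.0
        assert out.loc[0, "pct_xi_hap2"] == 20.0

    def test_no_calls_zero_percent(self):
        calls = pd.DataFrame({"cell_id": ["a", "b"], "time_point": ["d0", "d0"],
                              "is_bipartite": [False, False], "xi_allele": ["none"] * 2})
        assert proportion_bipartite(calls).loc[0, "pct_bipartite"] == 0.0

    def test_recovered_fraction_corrects_known_fpr(self):
        est, lo, hi = recovered_fraction(19, 100, fpr=0.10)
        assert est == pytest.approx((0.19 - 0.1) / 0.9)
        assert lo < est < hi


class TestConcordance:
    def test_spearman_and_lmd_modes_agree_beyond_chance(self, null_cdp_table):
        """On strong-effect bipartite cells plus nulls, the two classifiers'
        calls agree more often than independent chance would allow."""
        from xci_scstruct.cdp import compute_cdp_table
        from xci_scstruct.contacts import informative_contacts
        from xci_scstruct.simulate import ContactGeneratorSpec, simulate_population

        spec = ContactGeneratorSpec(n_min=500, n_max=2000, mitotic_fraction=0.0,
                                    mid_depletion=0.5, long_boost=4.0, seed=23)
        table, truth = simulate_population(spec, 60, bipartite_fraction=0.5)
        cdp_tab = compute_cdp_table(informative_contacts(table))
        null = statistics_table(null_cdp_table, "chr1")
        spec_lmd = fpr_threshold(null["delta_lmd"], fpr=0.10)
        spec_rho = fpr_threshold(null["rho"], fpr=0.10, direction="less",
                                 statistic="spearman_cdp")
        lmd_calls = call_population(cdp_tab, spec_lmd=spec_lmd)
        rho_calls = call_population(cdp_tab, spec_rho=spec_rho)
        merged = lmd_calls.merge(rho_calls, on="cell_id", suffixes=("_lmd", "_rho"))
        agree = (merged["is_bipartite_lmd"] == merged["is_bipartite_rho"]).mean()
        p_l = merged["is_bipartite_lmd"].mean()
        p_r = merged["is_bipartite_rho"].mean()
        chance = p_l * p_r + (1 - p_l) * (1 - p_r)
        assert agree > chance


class TestNullCalibration:
    def test_fpr_calibration_on_held_out_null(self, null_cdp_table):
        """Threshold from chr1 |dLMD| of half the null cells gives ~10% calls
        on the other half's chrX (exact binomial 99% band)."""
        s1 = statistics_table(null_cdp_table, "chr1")
        sX = statistics_table(null_cdp_table, "chrX")
        train = s1.iloc[:150]
        test = sX[sX["cell_id"].isin(set(s1["cell_id"].iloc[150:]))]
        spec = fpr_threshold(train["delta_lmd"], fpr=0.10)
        k = int((test["delta_lmd"].abs() > spec.threshold).sum())
        n = len(test)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.10)
        assert lo <= k <= hi

    def test_population_call_symmetry(self, null_cdp_table):
        """On null cells, calls split roughly evenly between the two homologs."""
        s1 = statistics_table(null_cdp_table, "chr1")
        spec = fpr_threshold(s1["delta_lmd"], fpr=0.10)
        calls = call_population(null_cdp_table, spec_lmd=spec, chrom="chrX")
        called = calls[calls["is_bipartite"]]
        if len(called) >= 10:
            frac_h1 = (called["xi_allele"] == "hap1").mean()
            assert 0.1 < frac_h1 < 0.9
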