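import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xci_scstruct.simulate import CountGeneratorSpec, simulate_allelic_counts
from xci_scstruct.skew import (AllelicCountMatrix, allelic_log2_ratio, call_xci,
                               feature_cell_filters, silencing_timecourse, skew_calls,
                               xa_ratio)
from xci_scstruct.structure import ThresholdSpec, fpr_threshold


def build_matrix(h1: np.ndarray, h2: np.ndarray, chroms, cells=None) -> AllelicCountMatrix:
    genes = [f"g{i}" for i in range(h1.shape[0])]
    cells = cells or [f"c{j}" for j in range(h1.shape[1])]
    return AllelicCountMatrix(
        {"hap1": pd.DataFrame(h1, index=genes, columns=cells),
         "hap2": pd.DataFrame(h2, index=genes, columns=cells)},
        pd.DataFrame({"chrom": chroms}, index=genes),
        pd.DataFrame({"time_point": "d0"}, index=pd.Index(cells)))


@pytest.fixture(scope="module")
def rna_timecourse():
    spec = CountGeneratorSpec(seed=31)
    return simulate_allelic_counts(
        spec, 100, {"d0": 0.0, "d3": 0.3, "d7": 0.8, "d11": 0.9, "NPC": 1.0})


class TestLog2Ratio:
    @pytest.mark.parametrize("h1, h2, expected", [
        (50, 50, 0.0),
        (80, 20, np.log2(81 / 21)),       # ~1.9475
        (0, 40, np.log2(1 / 41)),         # ~-5.358
    ])
    def test_examples(self, h1, h2, expected):
        assert allelic_log2_ratio(h1, h2) == pytest.approx(expected)

    def test_antisymmetry(self):
        assert allelic_log2_ratio(7, 123) == pytest.approx(-allelic_log2_ratio(123, 7))

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            allelic_log2_ratio(-1, 5)


class TestFilters:
    def test_gene_seen_in_nine_cells_dropped(self):
        h1 = np.zeros((2, 20), int)
        h1[0, :9] = 1    # gene 0: coverage in 9 cells on its best allele
        h1[1, :15] = 1   # gene 1: coverage in 15 cells
        m = build_matrix(h1, np.zeros((2, 20), int), ["chr1", "chr1"])
        out = feature_cell_filters(m, chroms=())
        assert list(out.features) == ["g1"]

    def test_cell_with_nine_umis_on_one_allele_dropped(self):
        h1 = np.full((4, 3), 20)
        h2 = np.full((4, 3), 20)
        h2[2:, 1] = [5, 4]  # cell c1: chrX hap2 total 9
        m = build_matrix(h1, h2, ["chr1", "chr1", "chrX", "chrX"])
        out = feature_cell_filters(m, min_cells_per_feature=3)
        assert list(out.cells) == ["c0", "c2"]

    def test_combined_mode_keeps_fully_silenced_cell(self):
        h1 = np.full((4, 2), 20)
        h2 = np.full((4, 2), 20)
        h2[2:, 0] = 0  # cell c0: chrX hap2 fully silenced
        m = build_matrix(h1, h2, ["chr1", "chr1", "chrX", "chrX"])
        assert list(feature_cell_filters(m, min_cells_per_feature=2).cells) == ["c1"]
        assert list(feature_cell_filters(m, min_cells_per_feature=2,
                                         mode="combined").cells) == ["c0", "c1"]

    def test_all_pass_fixture_unchanged(self):
        h = np.full((4, 12), 30)
        m = build_matrix(h, h, ["chr1", "chr1", "chrX", "chrX"])
        out = feature_cell_filters(m)
        assert list(out.features) == list(m.features)
        assert list(out.cells) == list(m.cells)


class TestCallXCI:
    SPEC = ThresholdSpec("tae_log2", 1.2, 0.1, "abs_greater", 100)

    def test_balanced_ratio_biallelic(self):
        call = call_xci("c", 50, 50, self.SPEC)
        assert call.xci_status == "biallelic" and call.xa_allele == "none"

    def test_left_skew_means_hap1_silenced(self):
        call = call_xci("c", 5, 50, self.SPEC)  # ratio ~ -3.1
        assert call.log2_ratio < -self.SPEC.threshold
        assert call.xci_status == "hap1_silenced" and call.xa_allele == "hap2"

    def test_right_skew_means_hap2_silenced(self):
        call = call_xci("c", 50, 5, self.SPEC)
        assert call.xci_status == "hap2_silenced" and call.xa_allele == "hap1"

    def test_ratio_exactly_at_threshold_is_biallelic(self):
        # choose totals giving |ratio| == threshold exactly
        spec = ThresholdSpec("tae_log2", allelic_log2_ratio(80, 20), 0.1,
                             "abs_greater", 100)
        assert call_xci("c", 80, 20, spec).xci_status == "biallelic"

    def test_missing_totals_no_call(self):
        assert call_xci("c", float("nan"), 5, self.SPEC).xci_status == "no_call"


class TestXARatio:
    def test_identical_means_give_one(self):
        h = np.full((6, 12), 10)
        m = build_matrix(h, h, ["chr1"] * 3 + ["chrX"] * 3)
        np.testing.assert_allclose(xa_ratio(m), 1.0)

    def test_halving_x_halves_ratio(self):
        h1 = np.full((6, 12), 10)
        h2 = h1.copy()
        h2[3:] = 0  # chrX halved when alleles summed: X mean 10 vs A mean 20
        m = build_matrix(h1, h2, ["chr1"] * 3 + ["chrX"] * 3)
        np.testing.assert_allclose(xa_ratio(m), 0.5)

    def test_two_active_x_doubles_dosage_vs_male(self):
        """Female cells with both X alleles active show ~2x the X:A ratio of
        male cells carrying a single X."""
        f_spec = CountGeneratorSpec(seed=41, sex="female")
        m_spec = CountGeneratorSpec(seed=42, sex="male")
        fem, _ = simulate_allelic_counts(f_spec, 150, {"d0": 0.0})
        mal, _ = simulate_allelic_counts(m_spec, 150, {"d0": 0.0})
        ratio = xa_ratio(fem).mean() / xa_ratio(mal).mean()
        assert ratio == pytest.approx(2.0, rel=0.15)


class TestSkewCalls:
    def test_threshold_calibrates_fpr_on_biallelic_cells(self, rna_timecourse):
        matrix, truth = rna_timecourse
        d0 = matrix.subset(cells=truth.loc[truth.time_point == "d0", "cell_id"])
        calls, spec = skew_calls(feature_cell_filters(d0, mode="combined"))
        rate = calls["xci_status"].isin(["hap1_silenced", "hap2_silenced"]).mean()
        n = len(calls)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.10) / n
        assert lo <= rate <= hi

    def test_silencing_called_monotone_in_completeness(self):
        """Stronger residual expression (higher completeness) weakens calls."""
        rates = []
        for comp in (0.0, 0.3, 0.8):
            spec = CountGeneratorSpec(seed=43, completeness=comp)
            matrix, _ = simulate_allelic_counts(spec, 120, {"d7": 1.0, "null": 0.0})
            keep = matrix.cell_meta.index[matrix.cell_meta["time_point"] == "d7"]
            null = matrix.cell_meta.index[matrix.cell_meta["time_point"] == "null"]
            null_tot = matrix.subset(cells=null).chrom_allele_totals("chr1")
            tspec = fpr_threshold([allelic_log2_ratio(a, b) for a, b in
                                   zip(null_tot["hap1"], null_tot["hap2"])], 0.10)
            tot = matrix.subset(cells=keep).chrom_allele_totals("chrX")
            called = np.mean([call_xci(c, tot.at[c, "hap1"], tot.at[c, "hap2"],
                                       tspec).xci_status != "biallelic" for c in keep])
            rates.append(called)
        assert rates[0] >= rates[1] >= rates[2]

    def test_timecourse_table_and_percentages(self, rna_timecourse):
        matrix, truth = rna_timecourse
        calls, _ = skew_calls(feature_cell_filters(matrix, mode="combined"))
        table = silencing_timecourse({"rna": calls})
        assert set(table["time_point"]) == {"d0", "d3", "d7", "d11", "NPC"}
        pct = table.set_index("time_point")["pct_rna"]
        assert pct["NPC"] > pct["d7"] > pct["d0"]

    def test_male_cells_have_zero_hap2_chrx(self):
        spec = CountGeneratorSpec(seed=44, sex="male")
        matrix, _ = simulate_allelic_counts(spec, 30, {"d0": 0.0})
        assert matrix.chrom_allele_totals("chrX")["hap2"].sum() == 0

    def test_antisymmetry_allele_swap_flips_call(self, rna_timecourse):
        matrix, _ = rna_timecourse
        filt = feature_cell_filters(matrix, mode="combined")
        swapped = AllelicCountMatrix(
            {"hap1": filt.counts["hap2"], "hap2": filt.counts["hap1"]},
            filt.feature_meta, filt.cell_meta)
        a, _ = skew_calls(filt)
        b, _ = skew_calls(swapped)
        np.testing.assert_allclose(a["log2_ratio"], -b["log2_ratio"])
        flips = {"hap1_silenced": "hap2_silenced", "hap2_silenced": "hap1_silenced",
                 "biallelic": "biallelic", "no_call": "no_call"}
        assert list(a["xci_status"].map(flips)) == list(b["xci_status"])


def test_atac_prefilter_drops_shallow_cells():
    from xci_scstruct.skew import atac_cell_prefilter
    h1 = np.zeros((3, 2), int)
    h1[:, 0] = 200   # cell c0: 600 total over both alleles
    h2 = h1.copy()
    m = build_matrix(h1, h2, ["chr1", "chr1", "chrX"])
    out = atac_cell_prefilter(m, min_umis=500)
    assert list(out.cells) == ["c0"]


class TestMTXRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = build_matrix(rng.poisson(2, (5, 4)), rng.poisson(2, (5, 4)),
                         ["chr1"] * 3 + ["chrX"] * 2)
        m.write_mtx(tmp_path / "counts")
        back = AllelicCountMatrix.read_mtx(tmp_path / "counts")
        for a in ("hap1", "hap2"):
            pd.testing.assert_frame_equal(m.counts[a], back.counts[a],
                                          check_dtype=False)
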