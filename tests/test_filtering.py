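"""Site/genotype filters, heterozygote resolution, pruning and masks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wpoly.filtering import (
    CoverageTable,
    FilterConfig,
    build_sex_mask,
    filter_sites,
    haploidize_sex_linked,
    merge_intervals,
    prune_linked_snps,
    resolve_sex_linked_het,
    sex_coverage_log2,
)
from wpoly.io import ABSENT, MISSING, SiteTable
from wpoly.simulate import simulate_coverage

from conftest import table_from_haplotypes


def annotated_table(n_sites=6, n_samples=10, **overrides):
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 2, size=(n_sites, n_samples)).astype(np.int8)
    t = table_from_haplotypes(mat)
    t.qual = np.full(n_sites, 50.0)
    t.site_dp = np.full(n_sites, float(n_samples * 2))
    t.mq = np.full(n_sites, 60.0)
    t.rpbz = np.zeros(n_sites)
    for k, v in overrides.items():
        getattr(t, k)[:] = v
    return t


@pytest.mark.parametrize(
    "field,value,rule",
    [
        ("qual", 19.0, "qual"),          # QUAL < 20
        ("mq", 29.0, "mq"),              # MQ < 30
        ("rpbz", 3.5, "rpbz"),           # |RPBZ| > 3
        ("rpbz", -3.5, "rpbz"),
        ("site_dp", 5.0, "dp_low"),      # DP below sample count
        ("site_dp", 100.0, "dp_high"),   # DP > 2x chromosomal mean
    ],
)
def test_site_level_thresholds(field, value, rule):
    t = annotated_table()
    getattr(t, field)[2] = value
    out, counts = filter_sites(t, FilterConfig(), chrom_mean_dp=20.0)
    assert counts[rule] == 1
    assert out.n_sites == t.n_sites - 1
    assert 3 not in out.pos  # site at pos 3 (index 2) removed


def test_missing_annotations_never_fail():
    """Absent QC annotations must pass filters, not count as zero."""
    mat = np.zeros((4, 10), dtype=np.int8)
    mat[:, 0] = 1
    t = table_from_haplotypes(mat)  # no annotations at all
    out, counts = filter_sites(t, FilterConfig(), chrom_mean_dp=None)
    assert out.n_sites == 4
    assert all(v == 0 for v in counts.values())


def test_missingness_rule():
    mat = np.zeros((2, 10), dtype=np.int8)
    mat[:, :5] = 1
    mat[0, :3] = MISSING  # 30% missing at site 0
    t = table_from_haplotypes(mat)
    out, counts = filter_sites(t, FilterConfig(), chrom_mean_dp=None)
    assert counts["missingness"] == 1
    assert out.n_sites == 1


def test_low_depth_genotypes_blanked():
    mat = np.zeros((1, 10), dtype=np.int8)
    mat[:, :5] = 1
    t = table_from_haplotypes(mat)  # haploid samples
    ad = np.zeros((1, 10, 2), dtype=np.int32)
    ad[:, :, 0] = 5
    ad[0, 3] = (1, 0)  # depth 1 < haploid minimum of 2
    t.allele_depths = ad
    out, counts = filter_sites(t, FilterConfig(), chrom_mean_dp=None)
    assert counts["low_depth_genotypes"] == 1
    assert out.alleles[0, 3, 0] == MISSING


def test_filter_idempotence(base_cohort):
    t = base_cohort.site_tables["autosome"]
    cfg = FilterConfig()
    once, _ = filter_sites(t, cfg, chrom_mean_dp=None)
    twice, counts = filter_sites(once, cfg, chrom_mean_dp=None)
    assert twice.n_sites == once.n_sites
    assert all(v == 0 for v in counts.values())


class TestHetResolution:
    def test_strongly_imbalanced_goes_to_major(self):
        # two-sided exact binomial: 2*P(X<=1 | n=31, 0.5) ~ 2.98e-8 < 1e-5
        p = stats.binomtest(1, 31, 0.5).pvalue
        assert p == pytest.approx(2.98e-8, rel=0.01)
        assert resolve_sex_linked_het((0, 1), (30, 1), 1e-5) == 0
        assert resolve_sex_linked_het((0, 1), (1, 30), 1e-5) == 1

    def test_balanced_het_is_missing(self):
        assert resolve_sex_linked_het((0, 1), (5, 5), 1e-5) is None

    def test_homozygote_passes_through(self):
        assert resolve_sex_linked_het((0, 0), (10, 0), 1e-5) == 0
        assert resolve_sex_linked_het((1, 1), (0, 10), 1e-5) == 1

    def test_no_depth_information_is_missing(self):
        assert resolve_sex_linked_het((0, 1), None, 1e-5) is None

    def test_table_haploidization(self):
        alleles = np.array(
            [[[0, 1], [0, 0], [1, 1]],
             [[1, 0], [0, 1], [0, 0]]], dtype=np.int8)
        ad = np.array(
            [[[30, 1], [9, 0], [0, 9]],
             [[5, 5], [1, 30], [9, 0]]], dtype=np.int32)
        t = SiteTable(
            chrom=np.array(["chrW", "chrW"], dtype=object),
            pos=np.array([1, 2]),
            ref=np.array(["A", "A"], dtype=object),
            alt=np.array(["T", "T"], dtype=object),
            alleles=alleles, samples=["a", "b", "c"], chrom_class="W",
            allele_depths=ad,
        )
        out = haploidize_sex_linked(t, ["a", "b", "c"])
        assert tuple(out.alleles[0, 0]) == (0, ABSENT)       # resolved to major
        assert tuple(out.alleles[0, 1]) == (0, ABSENT)       # hom -> haploid
        assert tuple(out.alleles[1, 0]) == (MISSING, ABSENT)  # balanced het
        assert tuple(out.alleles[1, 1]) == (1, ABSENT)


class TestPruning:
    def base(self, positions, mafs):
        n = len(positions)
        # 10 haploid samples; alt count = maf*10
        mat = np.zeros((n, 10), dtype=np.int8)
        for i, m in enumerate(mafs):
            mat[i, : int(round(m * 10))] = 1
        return table_from_haplotypes(mat, positions=positions)

    def test_keep_highest_maf_in_chain(self):
        t = self.base([100, 103], [0.1, 0.3])
        out = prune_linked_snps(t, 5)
        assert list(out.pos) == [103]

    def test_distant_snps_both_kept(self):
        t = self.base([100, 106], [0.1, 0.3])
        out = prune_linked_snps(t, 5)
        assert list(out.pos) == [100, 106]

    def test_maf_tie_keeps_lower_position(self):
        t = self.base([100, 103], [0.2, 0.2])
        out = prune_linked_snps(t, 5)
        assert list(out.pos) == [100]

    def test_transitive_chain_keeps_single_snp(self):
        t = self.base([100, 103, 106], [0.1, 0.2, 0.4])
        out = prune_linked_snps(t, 5)
        assert list(out.pos) == [106]


class TestMergeIntervals:
    def test_gap_below_threshold_merges(self):
        assert merge_intervals([(100, 600), (1000, 1500)], 500) == [(100, 1500)]

    def test_gap_above_threshold_kept(self):
        assert merge_intervals([(0, 100), (700, 800)], 500) == [(0, 100), (700, 800)]

    def test_overlapping_union(self):
        assert merge_intervals([(0, 100), (50, 150), (140, 200)]) == [(0, 200)]

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([(-5, 10)])


class TestCoverageMasks:
    @pytest.fixture()
    def cov_fixture(self, base_cohort):
        rep = [(0, 20_000), (60_000, 80_000)]
        mis = [(20_000, 40_000)]
        cov = simulate_coverage(base_cohort, rep, mis, mean_depth=10.0,
                                depth_sd_frac=0.02, seed=5)
        return CoverageTable(cov), base_cohort.metadata, rep, mis

    def test_w_mask_recovers_exactly_the_repetitive_windows(self, cov_fixture):
        cov, meta, rep, _ = cov_fixture
        mask = build_sex_mask(cov, meta, "W")
        assert [(s, e) for s, e in zip(mask.intervals["start"], mask.intervals["end"])] == rep
        assert mask.total_bp == 40_000

    def test_z_mask_recovers_exactly_the_misassembled_windows(self, cov_fixture):
        cov, meta, _, mis = cov_fixture
        mask = build_sex_mask(cov, meta, "Z")
        assert [(s, e) for s, e in zip(mask.intervals["start"], mask.intervals["end"])] == mis

    def test_mt_mask_rule(self):
        from wpoly.simulate import simulate_mt_coverage

        cov_df = simulate_mt_coverage(["a", "b", "c"], n_windows=12,
                                      outlier_windows={2: 0.2, 7: 3.0}, seed=2)
        auto = pd.DataFrame(
            {"chrom": "chr1", "start": 0, "end": 100,
             "sample": ["a", "b", "c"], "mean_depth": 10.0}
        )
        cov = CoverageTable(pd.concat([cov_df, auto], ignore_index=True))
        mask = build_sex_mask(cov, pd.DataFrame(
            {"sample": list("abc"), "species": "canorus", "morph": "gray",
             "sex": "F", "population": "hu"}), "mt")
        assert set(mask.intervals["start"]) == {2 * 25, 7 * 25}

    def test_unknown_class_rejected(self, cov_fixture):
        cov, meta, _, _ = cov_fixture
        with pytest.raises(ValueError):
            build_sex_mask(cov, meta, "autosome")


class TestLog2Scan:
    def make_cov(self, mf, mm):
        rows = []
        for i, d in enumerate(mf):
            rows.append(("chrZ", 0, 1000, f"f{i}", d))
        for i, d in enumerate(mm):
            rows.append(("chrZ", 0, 1000, f"m{i}", d))
        cov = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "mean_depth"])
        meta = pd.DataFrame({
            "sample": [f"f{i}" for i in range(len(mf))] + [f"m{i}" for i in range(len(mm))],
            "species": "canorus", "morph": "gray",
            "sex": ["F"] * len(mf) + ["M"] * len(mm),
            "population": "hu",
        })
        return cov, meta

    def test_equal_means_give_zero(self):
        cov, meta = self.make_cov([10, 10], [10, 10])
        out = sex_coverage_log2(cov, meta, scale_to_smallest=False)
        assert out["log2_fm"].iloc[0] == pytest.approx(0.0)

    def test_female_specific_window(self):
        cov, meta = self.make_cov([10, 10], [0, 0])
        out = sex_coverage_log2(cov, meta, scale_to_smallest=False)
        assert out["log2_fm"].iloc[0] == pytest.approx(np.log2(10.01 / 0.01), abs=1e-9)
        assert out["log2_fm"].iloc[0] == pytest.approx(9.97, abs=0.01)

    def test_antisymmetry_under_sex_swap(self):
        cov, meta = self.make_cov([10, 2], [5, 1])
        fwd = sex_coverage_log2(cov, meta, scale_to_smallest=False)
        meta_swapped = meta.assign(sex=meta["sex"].map({"F": "M", "M": "F"}))
        rev = sex_coverage_log2(cov, meta_swapped, scale_to_smallest=False)
        assert fwd["log2_fm"].iloc[0] == pytest.approx(-rev["log2_fm"].iloc[0])

    def test_single_sex_rejected(self):
        cov, meta = self.make_cov([10, 10], [])
        with pytest.raises(ValueError):
            sex_coverage_log2(cov, meta)
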