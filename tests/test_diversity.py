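"""Diversity statistics against brute-force pairwise-counting oracles."""

import numpy as np
import pandas as pd
import pytest

from wpoly.diversity import (
    WindowedDiversity,
    shuffle_groups_scan,
    subsample_robustness,
    tajimas_d,
    window_diversity,
)

from conftest import table_from_haplotypes


# ---------------------------------------------------------------------------
# brute-force oracles: count differences over explicit sequence pairs
# ---------------------------------------------------------------------------

def brute_pi(seqs, L):
    n = seqs.shape[1]
    tot, pairs = 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += int((seqs[:, i] != seqs[:, j]).sum())
            pairs += 1
    return tot / pairs / L


def brute_dxy(x, y, L):
    tot, pairs = 0, 0
    for i in range(x.shape[1]):
        for j in range(y.shape[1]):
            tot += int((x[:, i] != y[:, j]).sum())
            pairs += 1
    return tot / pairs / L


def brute_hudson_fst(x, y):
    """1 - Hw/Hb with per-site pair counting (unbiased within-pop term)."""
    num_sum = den_sum = 0.0
    for s in range(x.shape[0]):
        hw = 0.0
        for seqs in (x[s], y[s]):
            n = len(seqs)
            diffs = sum(
                seqs[i] != seqs[j] for i in range(n) for j in range(i + 1, n)
            )
            hw += diffs / (n * (n - 1) / 2)
        hw /= 2.0
        hb = np.mean([xi != yj for xi in x[s] for yj in y[s]])
        num_sum += hb - hw
        den_sum += hb
    return num_sum / den_sum


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_oracle_equivalence_small_matrices(seed):
    """pi / D_XY / F_ST match explicit pairwise counting to 1e-12."""
    rng = np.random.default_rng(seed)
    L = 1000
    n_sites = 120
    x = rng.integers(0, 2, size=(n_sites, 5)).astype(np.int8)
    y = (rng.random((n_sites, 5)) < 0.7).astype(np.int8)
    mat = np.concatenate([x, y], axis=1)
    t = table_from_haplotypes(mat)
    groups = {"X": [f"s{i}" for i in range(5)], "Y": [f"s{i}" for i in range(5, 10)]}
    out = window_diversity(t, groups, window_bp=L, min_called_frac=0.0,
                           exclude_singletons=False)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["pi_X"] == pytest.approx(brute_pi(x, L), abs=1e-12)
    assert row["pi_Y"] == pytest.approx(brute_pi(y, L), abs=1e-12)
    assert row["dxy_X_Y"] == pytest.approx(brute_dxy(x, y, L), abs=1e-12)
    assert row["fst_X_Y"] == pytest.approx(brute_hudson_fst(x, y), abs=1e-12)


def test_hudson_fst_hand_example():
    """p1=0.8 (n1=10), p2=0.2 (n2=10) at one site -> F_ST ~ 0.477."""
    x = np.zeros((1, 10), dtype=np.int8)
    x[0, :8] = 1
    y = np.zeros((1, 10), dtype=np.int8)
    y[0, :2] = 1
    t = table_from_haplotypes(np.concatenate([x, y], axis=1))
    groups = {"A": [f"s{i}" for i in range(10)],
              "B": [f"s{i}" for i in range(10, 20)]}
    out = window_diversity(t, groups, window_bp=10, min_called_frac=0.0,
                           exclude_singletons=False)
    num = (0.8 - 0.2) ** 2 - 0.8 * 0.2 / 9 - 0.2 * 0.8 / 9
    den = 0.8 * 0.8 + 0.2 * 0.2
    assert out["fst_A_B"].iloc[0] == pytest.approx(num / den)
    assert out["fst_A_B"].iloc[0] == pytest.approx(0.477, abs=5e-4)


def test_fixed_difference_window():
    """One fixed difference in L=10 callable: dxy=0.1, fst=1, pi=0."""
    mat = np.array([[0, 0, 1, 1]], dtype=np.int8)
    t = table_from_haplotypes(mat)
    groups = {"X": ["s0", "s1"], "Y": ["s2", "s3"]}
    out = window_diversity(t, groups, window_bp=10, min_called_frac=0.0,
                           exclude_singletons=False)
    row = out.iloc[0]
    assert row["pi_X"] == 0.0 and row["pi_Y"] == 0.0
    assert row["dxy_X_Y"] == pytest.approx(0.1)
    assert row["fst_X_Y"] == pytest.approx(1.0)


def test_identical_groups_fst_near_zero():
    rng = np.random.default_rng(4)
    mat = rng.integers(0, 2, size=(400, 12)).astype(np.int8)
    t = table_from_haplotypes(mat)
    groups = {"X": [f"s{i}" for i in range(6)], "Y": [f"s{i}" for i in range(6, 12)]}
    out = window_diversity(t, groups, window_bp=1000, min_called_frac=0.0,
                           exclude_singletons=False)
    row = out.iloc[0]
    # random halves of one pool: dxy ~ (pi_X + pi_Y)/2, F_ST ~ 0
    assert row["dxy_X_Y"] == pytest.approx((row["pi_X"] + row["pi_Y"]) / 2, rel=0.05)
    assert abs(row["fst_X_Y"]) < 0.05


def test_singleton_exclusion_and_min_called():
    mat = np.zeros((3, 6), dtype=np.int8)
    mat[0, 0] = 1            # pooled singleton
    mat[1, :3] = 1           # common variant
    mat[2, :2] = 1
    t = table_from_haplotypes(mat)
    groups = {"X": [f"s{i}" for i in range(3)], "Y": [f"s{i}" for i in range(3, 6)]}
    with_s = window_diversity(t, groups, 100, 0.0, exclude_singletons=False)
    without = window_diversity(t, groups, 100, 0.0, exclude_singletons=True)
    assert with_s["n_snps"].iloc[0] == 3
    assert without["n_snps"].iloc[0] == 2
    # min_called_frac drops windows with a short callable denominator
    dropped = window_diversity(t, groups, 100, 0.5, exclude_singletons=False,
                               callable_bp=0.2)
    assert len(dropped) == 0


class TestTajimasD:
    def test_single_singleton_n4(self):
        """n=4 sequences, one singleton site: D ~ -0.612 (direct evaluation)."""
        mat = np.zeros((1, 4), dtype=np.int8)
        mat[0, 0] = 1
        t = table_from_haplotypes(mat)
        out = tajimas_d(t, [f"s{i}" for i in range(4)], window_bp=100)
        assert out["tajimas_d"].iloc[0] == pytest.approx(-0.612, abs=1e-3)

    def test_zero_numerator(self):
        """8 singletons + 3 doubletons at n=4 give pi_sum = S/a1 exactly."""
        mat = np.zeros((11, 4), dtype=np.int8)
        for i in range(8):
            mat[i, i % 4] = 1
        for i in range(8, 11):
            mat[i, :2] = 1
        t = table_from_haplotypes(mat)
        out = tajimas_d(t, [f"s{i}" for i in range(4)], window_bp=100)
        assert out["tajimas_d"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_is_missing(self):
        mat = np.zeros((1, 4), dtype=np.int8)
        mat[0] = 1  # fixed in the sample after polarization -> dropped by sim,
        t = table_from_haplotypes(mat)
        out = tajimas_d(t.take_sites([]), [f"s{i}" for i in range(4)], 100)
        assert len(out) == 0 or np.isnan(out["tajimas_d"]).all()

    def test_balancing_vs_expansion_signatures(self):
        """Two deep haplogroups pooled: D > 0; expanded population: D < 0."""
        from wpoly.simulate import SimulationConfig, simulate_cohort

        deep = simulate_cohort(SimulationConfig(
            n_per_group=5, n_males_per_species=1, ne_auto=2e4, ne_w=1e4,
            t_species=0.0, t_plumage=1e5,  # haplogroups isolated 10*ne_w
            n_windows=60, window_len_bp=20_000, seed=31, chromosomes=("W",),
        ))
        meta = deep.metadata
        can_f = meta[(meta["species"] == "canorus") & (meta["sex"] == "F")]
        d_deep = tajimas_d(deep.site_tables["W"], list(can_f["sample"]), 20_000)
        assert d_deep["tajimas_d"].mean() > 0.5

        grown = simulate_cohort(SimulationConfig(
            n_per_group=5, n_males_per_species=1, ne_auto=2e4, ne_w=2e4,
            t_species=0.0, t_plumage=0.0,
            t_resize=4000.0, resize_factor=0.02,  # 50x expansion 4k gens ago
            n_windows=60, window_len_bp=20_000, seed=37, chromosomes=("W",),
        ))
        meta = grown.metadata
        can_f = meta[(meta["species"] == "canorus") & (meta["sex"] == "F")]
        d_exp = tajimas_d(grown.site_tables["W"], list(can_f["sample"]), 20_000)
        assert d_exp["tajimas_d"].mean() < -0.5


class TestShuffleAndSubsample:
    def test_shuffle_is_seeded_and_centered(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 2, size=(300, 12)).astype(np.int8)
        t = table_from_haplotypes(mat)
        groups = {"X": [f"s{i}" for i in range(6)],
                  "Y": [f"s{i}" for i in range(6, 12)]}
        a = shuffle_groups_scan(t, groups, 1000, iters=5, seed=1,
                                min_called_frac=0.0, exclude_singletons=False)
        b = shuffle_groups_scan(t, groups, 1000, iters=5, seed=1,
                                min_called_frac=0.0, exclude_singletons=False)
        pd.testing.assert_frame_equal(a, b)
        assert abs(a["fst_X_Y"].mean()) < 0.05

    def test_observed_w_fst_beats_shuffled(self, base_cohort, female_groups):
        w = base_cohort.site_tables["W"]
        groups = {
            "gray": female_groups["can_gray"] + female_groups["opt_gray"],
            "rufous": female_groups["can_rufous"] + female_groups["opt_rufous"],
        }
        obs = window_diversity(w, groups, 20_000, 0.0)
        null = shuffle_groups_scan(w, groups, 20_000, iters=10, seed=3,
                                   min_called_frac=0.0)
        assert obs["fst_gray_rufous"].mean() > null["fst_gray_rufous"].max()

    def test_subsample_full_group_has_zero_variance(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 2, size=(200, 10)).astype(np.int8)
        t = table_from_haplotypes(mat)
        groups = {"X": [f"s{i}" for i in range(5)],
                  "Y": [f"s{i}" for i in range(5, 10)]}
        out = subsample_robustness(t, groups, n_sub=5, iters=4,
                                   window_sizes=(1000,), seed=0,
                                   min_called_frac=0.0, exclude_singletons=False)
        assert (out["sd"] == 0).all()

    def test_subsample_supports_uneven_groups_and_multiple_windows(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, size=(200, 24)).astype(np.int8)
        t = table_from_haplotypes(mat)
        groups = {"X": [f"s{i}" for i in range(12)],
                  "Y": [f"s{i}" for i in range(12, 24)]}
        out = subsample_robustness(
            t, groups, n_sub={"X": 7, "Y": 5}, iters=3,
            window_sizes=(50, 100, 200), seed=5,
            min_called_frac=0.0, exclude_singletons=False,
        )
        assert set(out["window_bp"]) == {50, 100, 200}
        again = subsample_robustness(
            t, groups, n_sub={"X": 7, "Y": 5}, iters=3,
            window_sizes=(50, 100, 200), seed=5,
            min_called_frac=0.0, exclude_singletons=False,
        )
        pd.testing.assert_frame_equal(out, again)

    def test_oversubsampling_rejected(self):
        mat = np.zeros((10, 4), dtype=np.int8)
        t = table_from_haplotypes(mat)
        groups = {"X": ["s0", "s1"], "Y": ["s2", "s3"]}
        with pytest.raises(ValueError):
            subsample_robustness(t, groups, n_sub=3, iters=1)


def test_da_identity_on_random_split(null_cohort):
    """Random halves of one population: D_XY - (pi_X+pi_Y)/2 ~ 0."""
    t = null_cohort.site_tables["autosome"]
    meta = null_cohort.metadata
    females = list(meta.loc[meta["sex"] == "F", "sample"])
    groups = {"X": females[:10], "Y": females[10:20]}
    res = WindowedDiversity(t, groups, window_bp=20_000,
                            min_called_frac=0.0).fit()
    da = res.windows["dxy_X_Y"] - (res.windows["pi_X"] + res.windows["pi_Y"]) / 2
    se = da.std(ddof=1) / np.sqrt(len(da))
    assert abs(da.mean()) < 3 * se + 1e-6


def test_results_object_summary(base_cohort, female_groups):
    res = WindowedDiversity(base_cohort.site_tables["W"], female_groups,
                            window_bp=20_000, min_called_frac=0.0).fit()
    text = res.summary()
    assert "windows" in text and "fst" in text.lower()
    assert len(res.genome_means()) > 0
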