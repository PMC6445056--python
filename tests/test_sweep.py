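import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    dxy_literal_brute,
    dxy_per_site_brute,
    fst_hudson_brute,
    fst_wright_brute,
    hp_brute,
)
from tailsweep import (
    WindowSpec,
    assign_major_minor,
    lsbl,
    read_vcf,
    scan_genome,
    standardize_zhp,
    top_windows,
    window_dxy,
    window_fst,
    window_hp,
)

freqs = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40)


class TestWindowFst:
    def test_fixed_difference_is_one(self):
        assert window_fst([1.0], [0.0]) == pytest.approx(1.0)

    def test_identical_populations_zero(self):
        f = np.array([0.1, 0.5, 0.9])
        assert window_fst(f, f) == pytest.approx(0.0)

    def test_monomorphic_everywhere_is_nan(self):
        assert np.isnan(window_fst([1.0, 0.0], [1.0, 0.0]))

    @pytest.mark.parametrize("estimator", ["wright", "hudson"])
    def test_matches_brute_force(self, estimator):
        rng = np.random.default_rng(42)
        for _ in range(20):
            fa = rng.uniform(0, 1, 50)
            fb = rng.uniform(0, 1, 50)
            na = rng.integers(10, 60, 50)
            nb = rng.integers(10, 60, 50)
            got = window_fst(fa, fb, na, nb, estimator=estimator)
            want = (
                fst_wright_brute(fa, fb)
                if estimator == "wright"
                else fst_hudson_brute(fa, fb, na, nb)
            )
            assert got == pytest.approx(want, abs=1e-12)

    @given(freqs, freqs)
    @settings(max_examples=60, deadline=None)
    def test_wright_symmetric_and_bounded(self, fa, fb):
        n = min(len(fa), len(fb))
        fa, fb = np.array(fa[:n]), np.array(fb[:n])
        v = window_fst(fa, fb)
        assert window_fst(fb, fa) == pytest.approx(v, nan_ok=True, abs=1e-12)
        if not np.isnan(v):
            assert -1e-12 <= v <= 1 + 1e-12


class TestLsbl:
    @pytest.mark.parametrize(
        "fi, expected_m",
        [((1.0, 1.0, 0.0), 1.0), ((0.3, 0.3, 0.3), 0.15), ((0.6, 0.8, 0.2), 0.6)],
    )
    def test_arithmetic(self, fi, expected_m):
        m, t, e = lsbl(*fi)
        assert m == pytest.approx(expected_m)
        assert m + t + e == pytest.approx(sum(fi) / 2)

    def test_permutation_values(self):
        m, t, e = lsbl(0.6, 0.8, 0.2)
        assert (m, t, e) == pytest.approx((0.6, 0.0, 0.2))

    def test_nan_propagates(self):
        assert all(np.isnan(v) for v in lsbl(float("nan"), 0.1, 0.2))

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    @settings(max_examples=60, deadline=None)
    def test_additivity(self, a, b, c):
        m, t, e = lsbl(a, b, c)
        assert m + t + e == pytest.approx((a + b + c) / 2, abs=1e-12)


class TestWindowDxy:
    def test_fixed_opposite_alleles(self):
        assert window_dxy([1.0], [0.0]) == pytest.approx(1.0)

    def test_half_half(self):
        assert window_dxy([0.5], [0.5]) == pytest.approx(0.5)

    def test_literal_hand_value(self):
        # x=(0.9,0.6), y=(0.2,0.5): (1.5·1.3 + 0.7·0.5) = 2.30
        assert window_dxy([0.9, 0.6], [0.2, 0.5], mode="literal") == pytest.approx(2.30)

    @pytest.mark.parametrize("mode", ["per_site", "literal"])
    def test_matches_brute_force_and_symmetry(self, mode):
        rng = np.random.default_rng(3)
        fx = rng.uniform(0, 1, 60)
        fy = rng.uniform(0, 1, 60)
        brute = dxy_per_site_brute(fx, fy) if mode == "per_site" else dxy_literal_brute(fx, fy)
        assert window_dxy(fx, fy, mode) == pytest.approx(brute, abs=1e-12)
        assert window_dxy(fy, fx, mode) == pytest.approx(window_dxy(fx, fy, mode), abs=1e-12)

    @given(freqs, freqs)
    @settings(max_examples=60, deadline=None)
    def test_per_site_bounded(self, fx, fy):
        n = min(len(fx), len(fy))
        v = window_dxy(np.array(fx[:n]), np.array(fy[:n]))
        assert -1e-12 <= v <= 1 + 1e-12


class TestWindowHp:
    def test_maximal_heterozygosity(self):
        assert window_hp([0.5]) == pytest.approx(0.5)

    def test_all_fixed_zero(self):
        assert window_hp([1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_pooled_form_hand_value(self):
        # sites (0.9, 0.6): Σmaj=1.5, Σmin=0.5 → 2·1.5·0.5/4 = 0.375
        assert window_hp([0.9, 0.6]) == pytest.approx(0.375)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.5, 1, 80)
        assert window_hp(f) == pytest.approx(hp_brute(f), abs=1e-12)

    @given(freqs)
    @settings(max_examples=60, deadline=None)
    def test_bounded_half(self, f):
        v = window_hp(np.array(f))
        assert -1e-12 <= v <= 0.5 + 1e-12


class TestStandardizeZhp:
    def test_unit_example(self):
        np.testing.assert_allclose(standardize_zhp([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_constant_warns_and_nans(self):
        with pytest.warns(UserWarning):
            out = standardize_zhp([0.3, 0.3, 0.3])
        assert np.isnan(out).all()

    def test_standardization_identity(self):
        rng = np.random.default_rng(8)
        hp = rng.uniform(0, 0.5, 200)
        hp[[3, 50]] = np.nan
        z = standardize_zhp(hp)
        ok = ~np.isnan(z)
        assert np.nanmean(z[ok]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z[ok], ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(z[3]) and np.isnan(z[50])


class TestWindowing:
    def test_tiling_contract(self):
        spec = WindowSpec(30_000, 15_000)
        assert spec.tile(60_000) == [
            (0, 30_000),
            (15_000, 45_000),
            (30_000, 60_000),
            (45_000, 60_000),
        ]

    def test_step_greater_than_window_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(10_000, 20_000)


class TestTopWindows:
    def test_quantile_count(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        stats = pd.DataFrame({"LSBL_M": rng.normal(size=1000)})
        assert len(top_windows(stats)) >= 5

    def test_ties_all_included(self):
        import pandas as pd

        stats = pd.DataFrame({"LSBL_M": [0.2] * 50})
        assert len(top_windows(stats)) == 50

    def test_distinct_values(self):
        import pandas as pd

        stats = pd.DataFrame({"LSBL_M": np.arange(1, 201, dtype=float)})
        got = top_windows(stats)
        assert got["LSBL_M"].tolist() == [200.0]

    def test_empty_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            top_windows(pd.DataFrame({"LSBL_M": []}))


class TestScanGenome:
    def test_planted_sweep_tops_lsbl(self, small_cohort):
        table = assign_major_minor(
            read_vcf(str(small_cohort.vcf_path), small_cohort.manifest)
        )
        stats = scan_genome(table, small_cohort.manifest)
        s, e = small_cohort.truth.sweep_interval
        best = stats.loc[stats["LSBL_M"].idxmax()]
        assert best["start"] < e and best["end"] > s

    def test_signal_attenuates_with_distance(self, small_cohort):
        table = assign_major_minor(
            read_vcf(str(small_cohort.vcf_path), small_cohort.manifest)
        )
        stats = scan_genome(table, small_cohort.manifest)
        s, e = small_cohort.truth.sweep_interval
        overlap = (stats["start"] < e) & (stats["end"] > s)
        far = (stats["end"] <= s - 200_000) | (stats["start"] >= e + 200_000)
        assert stats.loc[far, "LSBL_M"].mean() < stats.loc[overlap, "LSBL_M"].mean()

    def test_sparse_windows_are_nan(self, small_cohort):
        table = assign_major_minor(
            read_vcf(str(small_cohort.vcf_path), small_cohort.manifest)
        )
        stats = scan_genome(
            table, small_cohort.manifest, WindowSpec(30_000, 15_000, min_sites=10_000)
        )
        assert stats["LSBL_M"].isna().all()
        assert (stats["n_sites"] < 10_000).all()

    def test_no_sweep_max_consistent_with_permutation_null(self, tmp_path):
        """Without a planted sweep the observed maximum window LSBL_M should
        be a typical draw from the permutation distribution of maxima
        obtained by shuffling sites across windows."""
        from tailsweep import CohortSimConfig, simulate_cohort

        p_values = []
        for seed in range(20):
            cohort = simulate_cohort(
                CohortSimConfig(
                    n_per_pop=12,
                    chrom_length=1_000_000,
                    n_sites=2_000,
                    drift_F=0.01,
                    sweep_interval=None,
                    seed=100 + seed,
                ),
                tmp_path / f"c{seed}",
            )
            table = assign_major_minor(
                read_vcf(str(cohort.vcf_path), cohort.manifest)
            )
            stats = scan_genome(table, cohort.manifest)
            observed = stats["LSBL_M"].max()
            p_values.append(_permutation_p_of_max(table, cohort.manifest, observed, seed))
        # under the null, p ~ Uniform; more than 3/20 below 0.05 would be
        # evidence that real maxima exceed shuffled maxima systematically
        assert sum(p < 0.05 for p in p_values) <= 3


def _permutation_p_of_max(table, manifest, observed_max, seed, n_perm=99):
    """Permutation distribution of the maximum window LSBL_M obtained by
    shuffling site order (cumulative-sum window evaluation, independent of
    the scan code path)."""
    rng = np.random.default_rng(seed)
    spec = WindowSpec()
    pop_of = {"M": manifest.roles["selected"], "T": manifest.roles["sister"],
              "E": manifest.roles["outgroup"]}
    chrom = table.chroms[0]
    mask = table.chrom_mask(chrom)
    pos = table.sites.loc[mask, "pos"].to_numpy() - 1
    f = {L: table.f_major[pop_of[L]][mask] for L in "MTE"}
    windows = spec.tile(int(pos.max()) + 1)
    bounds = np.searchsorted(pos, np.array(windows))

    def max_lsbl(order):
        ht = {}
        hs = {}
        for a, b in (("M", "T"), ("M", "E"), ("T", "E")):
            fa, fb = f[a][order], f[b][order]
            pbar = (fa + fb) / 2
            ht[a + b] = np.concatenate([[0.0], np.cumsum(2 * pbar * (1 - pbar))])
            hs[a + b] = np.concatenate(
                [[0.0], np.cumsum(fa * (1 - fa) + fb * (1 - fb))]
            )
        best = -np.inf
        for lo, hi in bounds:
            if hi - lo < spec.min_sites:
                continue
            fi = {}
            for key in ht:
                den = ht[key][hi] - ht[key][lo]
                fi[key] = (den - (hs[key][hi] - hs[key][lo])) / den if den else np.nan
            val = (fi["MT"] + fi["ME"] - fi["TE"]) / 2
            if not np.isnan(val):
                best = max(best, val)
        return best

    null = [max_lsbl(rng.permutation(len(pos))) for _ in range(n_perm)]
    return (1 + sum(m >= observed_max for m in null)) / (1 + n_perm)
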