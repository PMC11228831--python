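"""SFS, theta, pi, Tajima's D, windows, Weir-Cockerham FST, heterozygosity, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invkaryo import popgen, simdata
from invkaryo.genio import MISSING
from invkaryo.popgen import SFS

from conftest import make_matrix
from _oracles import (
    pooled_anova_f_oracle,
    tajimas_d_oracle,
    watterson_oracle,
    wc_fst_oracle,
    welch_oracle,
)


class TestSFS:
    def test_monomorphic_input_all_zero(self):
        G = make_matrix(np.zeros((5, 6), dtype=np.int8))
        sfs = popgen.sfs_from_genotypes(G)
        assert sfs.S == 0

    def test_single_singleton_folded(self):
        d = np.zeros((10, 1), dtype=np.int8)
        d[0, 0] = 1
        sfs = popgen.sfs_from_genotypes(make_matrix(d), folded=True)
        assert sfs.counts[1] == 1.0
        assert sfs.S == 1.0

    def test_projection_matches_hypergeometric_enumeration(self):
        """A site with k=2 of m=6 projected to n=4 contributes the exact
        hypergeometric expectation to each class."""
        from math import comb

        contrib = popgen.project_counts(2, 6, 4)
        for i in range(1, 4):
            expected = comb(2, i) * comb(4, 4 - i) / comb(6, 4)
            assert contrib[i] == pytest.approx(expected, abs=1e-12)

    def test_missing_data_projected_to_common_size(self):
        d = np.array([[1, 1], [0, 1], [0, MISSING], [0, 0], [0, 0]],
                     dtype=np.int8)
        sfs = popgen.sfs_from_genotypes(make_matrix(d), min_fraction=0.8)
        assert sfs.n_chromosomes == 8
        # site with m=8 contributes 1; the m=10 singleton survives projection
        # to n=8 with probability 1 - C(9,8)/C(10,8) = 0.8
        assert sfs.S == pytest.approx(1.8, abs=1e-9)
        assert sfs.counts[1] == pytest.approx(0.8, abs=1e-9)

    def test_all_sites_below_floor_raises(self):
        d = np.full((5, 3), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            popgen.sfs_from_genotypes(make_matrix(d))


class TestThetaPiD:
    def test_watterson_zero_sites(self):
        assert popgen.watterson_theta(0, 10) == 0.0

    def test_watterson_matches_harmonic_oracle(self):
        assert popgen.watterson_theta(10, 10) == pytest.approx(
            watterson_oracle(10, 10), rel=1e-12
        )

    def test_watterson_invalid_n(self):
        with pytest.raises(ValueError):
            popgen.watterson_theta(5, 1)

    def test_tajima_undefined_cases(self):
        assert np.isnan(popgen.tajimas_d(SFS(10, np.zeros(11))))
        c = np.zeros(4)
        c[1] = 3
        assert np.isnan(popgen.tajimas_d(SFS(3, c)))

    def test_tajima_matches_independent_constants_oracle(self):
        counts = np.zeros(11)
        counts[[1, 2, 3, 5, 9]] = [6, 3, 2, 1, 1]
        ours = popgen.tajimas_d(SFS(10, counts))
        assert ours == pytest.approx(tajimas_d_oracle(counts.tolist(), 10),
                                     abs=1e-10)

    def test_all_singletons_negative(self):
        counts = np.zeros(11)
        counts[1] = 20
        assert popgen.tajimas_d(SFS(10, counts)) < 0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        n=st.integers(min_value=4, max_value=40),
        data=st.data(),
    )
    def test_numerator_identity(self, n, data):
        """D * denominator == pi - S/a1 for any spectrum (1e-9)."""
        counts = np.zeros(n + 1)
        for i in range(1, n):
            counts[i] = data.draw(st.integers(min_value=0, max_value=30))
        if counts.sum() == 0:
            counts[1] = 1
        sfs = SFS(n, counts)
        c = popgen.tajima_constants(n)
        S = sfs.S
        den = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
        lhs = popgen.tajimas_d(sfs) * den
        rhs = popgen.pi_from_sfs(sfs) - popgen.watterson_theta(S, n)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_neutral_pi_minus_theta_is_mean_zero(self):
        """E[pi - theta_W] = 0 exactly under neutrality (both are unbiased
        estimators of theta), unlike the normalized D whose neutral mean is
        slightly negative; mean over replicates within 3 MC SE of 0."""
        rng = np.random.default_rng(37)
        n, theta, reps = 50, 50.0, 1500
        diffs = []
        for _ in range(reps):
            hap = simdata.simulate_neutral_block(n, theta, rng)
            counts = np.bincount(hap.sum(axis=0), minlength=n + 1).astype(float)
            counts[0] = counts[n] = 0.0
            sfs = SFS(n, counts)
            diffs.append(popgen.pi_from_sfs(sfs)
                         - popgen.watterson_theta(sfs.S, n))
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(reps)
        assert abs(diffs.mean()) < 3 * se

    def test_windowed_theta_recovers_generating_theta(self):
        """Mean Watterson theta over replicate neutral blocks is within 3 MC
        SE of the generating theta."""
        rng = np.random.default_rng(31)
        theta, n, reps = 10.0, 30, 400
        est = []
        for _ in range(reps):
            hap = simdata.simulate_neutral_block(n, theta, rng)
            est.append(popgen.watterson_theta(hap.shape[1], n))
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - theta) < 3 * se


class TestWindows:
    def test_tiling_on_100kb_chromosome(self):
        G = make_matrix(np.zeros((4, 2), dtype=np.int8), positions=[10, 20])
        wins = popgen.sliding_window_stats(G, 100_000)
        assert [w.start for w in wins] == [1, 10_001, 20_001, 30_001,
                                           40_001, 50_001]
        assert all(w.end - w.start == 50_000 for w in wins)

    def test_window_smaller_than_step_raises(self):
        G = make_matrix(np.zeros((4, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            popgen.sliding_window_stats(G, 100_000, window=5_000, step=10_000)

    def test_empty_window_fails_filter(self):
        G = make_matrix(np.ones((4, 1), dtype=np.int8), positions=[95_000])
        wins = popgen.sliding_window_stats(G, 100_000)
        assert wins[0].S == 0.0
        assert not wins[0].passes_filter
        assert np.isnan(wins[0].tajima_d)

    def test_region_mask_keep_and_exclude_partition(self):
        G = make_matrix(np.ones((4, 1), dtype=np.int8), positions=[5])
        region = (30_000, 60_000)
        all_w = popgen.sliding_window_stats(G, 100_000)
        kept = popgen.sliding_window_stats(G, 100_000, region=region,
                                           region_mode="keep")
        dropped = popgen.sliding_window_stats(G, 100_000, region=region,
                                              region_mode="exclude")
        assert len(kept) + len(dropped) == len(all_w)
        assert all(w.start <= region[1] and w.end - 1 >= region[0]
                   for w in kept)

    def test_diversity_elevated_inside_diverged_inversion(self, cohort1):
        """Pooled pi inside the inversion exceeds outside pi: the two diverged
        haplotype classes add between-class differences."""
        G = cohort1.genotypes
        lo, hi = cohort1.truth_region
        wins = popgen.sliding_window_stats(G, int(G.positions[-1]),
                                           window=500_000, step=500_000,
                                           min_S=1)
        inside = [w.pi for w in wins if lo <= w.start and w.end - 1 <= hi]
        outside = [w.pi for w in wins if w.end - 1 < lo or w.start > hi]
        assert np.mean(inside) > np.mean(outside)


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        d = np.zeros((40, 1), dtype=np.int8)
        d[20:, 0] = 2
        G = make_matrix(d)
        g1 = [f"s{i}" for i in range(20)]
        g2 = [f"s{i}" for i in range(20, 40)]
        recs = popgen.weir_cockerham_fst(G, g1, g2)
        assert recs[0].fst == pytest.approx(1.0)

    def test_identical_columns_nonpositive_and_match_oracle(self):
        rng = np.random.default_rng(12)
        col = rng.integers(0, 3, size=20).astype(np.int8)
        d = np.concatenate([col, col]).reshape(-1, 1)
        G = make_matrix(d)
        g1 = [f"s{i}" for i in range(20)]
        g2 = [f"s{i}" for i in range(20, 40)]
        recs = popgen.weir_cockerham_fst(G, g1, g2)
        expected = wc_fst_oracle(col.tolist(), col.tolist())
        assert recs[0].fst == pytest.approx(expected, abs=1e-12)
        assert recs[0].fst <= 0.0

    def test_every_site_matches_component_oracle(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, size=(30, 25)).astype(np.int8)
        G = make_matrix(d)
        g1 = [f"s{i}" for i in range(14)]
        g2 = [f"s{i}" for i in range(14, 30)]
        recs = popgen.weir_cockerham_fst(G, g1, g2)
        for r in recs:
            expected = wc_fst_oracle(
                d[:14, r.site_index].tolist(), d[14:, r.site_index].tolist()
            )
            assert r.fst == pytest.approx(expected, abs=1e-12)

    def test_group_swap_and_allele_flip_invariance(self):
        rng = np.random.default_rng(14)
        d = rng.integers(0, 3, size=(24, 10)).astype(np.int8)
        G = make_matrix(d)
        g1 = [f"s{i}" for i in range(12)]
        g2 = [f"s{i}" for i in range(12, 24)]
        base = [r.fst for r in popgen.weir_cockerham_fst(G, g1, g2)]
        swapped = [r.fst for r in popgen.weir_cockerham_fst(G, g2, g1)]
        assert base == pytest.approx(swapped, abs=1e-12)
        flipped = [
            r.fst for r in popgen.weir_cockerham_fst(
                make_matrix((2 - d).astype(np.int8)), g1, g2
            )
        ]
        assert base == pytest.approx(flipped, abs=1e-12)

    def test_overlapping_groups_raise(self):
        G = make_matrix(np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            popgen.weir_cockerham_fst(G, ["s0", "s1"], ["s1", "s2"])


class TestHeterozygosity:
    def test_all_het_is_one_all_hom_is_zero(self):
        d = np.array([[1, 1, 1], [0, 2, 0]], dtype=np.int8)
        het = popgen.per_sample_heterozygosity(make_matrix(d))
        assert het[0] == 1.0
        assert het[1] == 0.0

    def test_all_missing_sample_is_nan(self):
        d = np.array([[1, 1], [MISSING, MISSING], [0, 1]], dtype=np.int8)
        het = popgen.per_sample_heterozygosity(make_matrix(d))
        assert np.isnan(het[1])

    def test_heterokaryotypes_exceed_homokaryotypes(self, cohort1):
        """Simulated HETs carry one haplotype from each diverged class, so
        their inversion-region heterozygosity is highest."""
        G = cohort1.genotypes
        lo, hi = cohort1.truth_region
        het = popgen.per_sample_heterozygosity(G, G.region_sites(lo, hi))
        by = {}
        for i, s in enumerate(G.sample_ids):
            by.setdefault(cohort1.truth_karyotypes[s], []).append(het[i])
        assert np.mean(by["HET"]) > np.mean(by["ANC_HOM"])
        assert np.mean(by["HET"]) > np.mean(by["INV_HOM"])


class TestSignificance:
    def test_welch_identical_samples(self):
        res = popgen.welch_t_test([1, 2, 3], [1, 2, 3])
        assert (res.statistic, res.p_two_tailed) == (0.0, 1.0) or (
            res.statistic == pytest.approx(0.0) and res.p_two_tailed
            == pytest.approx(1.0)
        )

    def test_welch_matches_direct_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = popgen.welch_t_test(x, y)
        t, df, p = welch_oracle(x, y)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df[0] == pytest.approx(df, abs=1e-10)
        assert res.p_two_tailed == pytest.approx(p, abs=1e-10)

    def test_welch_degenerate_variance(self):
        res = popgen.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_two_tailed == 1.0
        with pytest.raises(ValueError, match="degenerate"):
            popgen.welch_t_test([2.0, 2.0], [3.0, 3.0])

    def test_anova_identical_groups(self):
        res = popgen.anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        assert (res.statistic, res.p_two_tailed) == (0.0, 1.0)

    def test_anova_two_groups_matches_pooled_f_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.5, 3.5, 6.0, 7.0, 8.0]
        res = popgen.anova_oneway([x, y])
        assert res.statistic == pytest.approx(pooled_anova_f_oracle([x, y]),
                                              rel=1e-10)
        assert res.df == (1.0, 7.0)

    def test_fst_increases_with_divergence_time(self):
        """Mean inversion-region FST between homokaryotype groups is strictly
        monotone in the class divergence time."""
        means = []
        for t_div in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for seed in (61, 62):
                cohort = simdata.simulate_inversion_cohort(
                    simdata.CohortSimParams(
                        seed=seed, t_div_ci=t_div,
                        p_inverted_per_pop=(0.5, 0.5),
                        pop_labels=("a", "b"), pop_latitudes=(33.0, 45.0),
                        n_samples_per_pop=40,
                    )
                )
                g1 = [s for s, k in cohort.truth_karyotypes.items()
                      if k == "ANC_HOM"]
                g2 = [s for s, k in cohort.truth_karyotypes.items()
                      if k == "INV_HOM"]
                ci = np.nonzero(simdata.realized_ci_site_mask(cohort))[0]
                recs = popgen.weir_cockerham_fst(
                    cohort.genotypes.take_sites(ci), g1, g2
                )
                vals.append(np.mean([r.fst for r in recs]))
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))
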