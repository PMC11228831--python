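"""Synthetic-data generator: coalescent expectations, truth labels, determinism."""

import hashlib

import numpy as np
import pytest

from invkaryo import popgen, simdata
from invkaryo.genio import write_vcf


def _harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestNeutralBlock:
    def test_zero_rate_limit_gives_no_sites(self):
        """As theta -> 0 the Poisson mutation count vanishes."""
        rng = np.random.default_rng(0)
        hap = simdata.simulate_neutral_block(10, 1e-12, rng)
        assert hap.shape == (10, 0)

    @pytest.mark.parametrize("n,theta,reps", [(2, 1.0, 2000), (10, 2.0, 2000)])
    def test_watterson_expectation(self, n, theta, reps):
        """Mean S equals theta * a1 within 3 Monte-Carlo SE."""
        rng = np.random.default_rng(17)
        S = np.array([
            simdata.simulate_neutral_block(n, theta, rng).shape[1]
            for _ in range(reps)
        ])
        expected = theta * _harmonic(n)
        se = S.std(ddof=1) / np.sqrt(reps)
        assert abs(S.mean() - expected) < 3 * se

    def test_matches_msprime_oracle(self):
        """Mean S agrees with the independent msprime engine at matched theta."""
        import msprime

        theta, n, reps = 5.0, 10, 400
        rng = np.random.default_rng(23)
        own = np.array([
            simdata.simulate_neutral_block(n, theta, rng).shape[1]
            for _ in range(reps)
        ])
        other = []
        for i in range(reps):
            ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                                      random_seed=1000 + i)
            mts = msprime.sim_mutations(ts, rate=theta / 2.0,
                                        discrete_genome=False,
                                        random_seed=50_000 + i)
            other.append(mts.num_sites)
        other = np.array(other)
        se = np.sqrt(own.var(ddof=1) / reps + other.var(ddof=1) / reps)
        assert abs(own.mean() - other.mean()) < 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simdata.simulate_neutral_block(1, 1.0, 0)
        with pytest.raises(ValueError):
            simdata.simulate_neutral_block(5, 0.0, 0)

    def test_unfolded_sfs_matches_one_over_i(self):
        """Pooled unfolded SFS class proportions fit the 1/i neutral law.

        Small theta keeps each genealogy's site count low, so pooled class
        counts are effectively independent and the chi-square GOF applies
        (at large theta the shared-tree correlation overdisperses the counts
        and the test statistic no longer follows its null distribution).
        """
        from scipy.stats import chisquare

        n, theta = 20, 0.5
        rng = np.random.default_rng(29)
        counts = np.zeros(n - 1)
        pooled = 0
        while pooled < 10_000:
            hap = simdata.simulate_neutral_block(n, theta, rng)
            k = hap.sum(axis=0)
            counts += np.bincount(k, minlength=n + 1)[1:n]
            pooled = counts.sum()
        expected = (1.0 / np.arange(1, n))
        expected = expected / expected.sum() * counts.sum()
        stat, p = chisquare(counts, expected)
        assert p > 0.01


class TestInversionCohort:
    def test_all_inverted_when_p_one(self):
        params = simdata.CohortSimParams(
            seed=2, p_inverted_per_pop=(1.0,) * 5, n_samples_per_pop=4
        )
        cohort = simdata.simulate_inversion_cohort(params)
        assert set(cohort.truth_karyotypes.values()) == {"INV_HOM"}

    def test_interval_outside_chromosome_raises(self):
        with pytest.raises(ValueError):
            simdata.simulate_inversion_cohort(
                simdata.CohortSimParams(ci_end=40_000_000)
            )
        with pytest.raises(ValueError):
            simdata.simulate_inversion_cohort(
                simdata.CohortSimParams(p_inverted_per_pop=(1.2,) * 5)
            )

    def test_determinism_byte_identical(self, tmp_path):
        """Identical seed gives byte-identical VCF output; a different seed differs."""
        params = simdata.CohortSimParams(seed=7, n_samples_per_pop=4)
        digests = []
        for tag in ("a", "b"):
            cohort = simdata.simulate_inversion_cohort(params)
            path = tmp_path / f"{tag}.vcf"
            write_vcf(cohort.genotypes, path)
            digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert digests[0] == digests[1]
        other = simdata.simulate_inversion_cohort(
            simdata.CohortSimParams(seed=8, n_samples_per_pop=4)
        )
        path = tmp_path / "c.vcf"
        write_vcf(other.genotypes, path)
        assert hashlib.sha256(path.read_bytes()).hexdigest() != digests[0]

    def test_realized_frequency_within_binomial_ci(self, cohort1):
        """Per-population inverted-haplotype frequency lies in the 99% binomial CI."""
        from scipy.stats import binom

        params = simdata.CohortSimParams(seed=1)
        score = {"ANC_HOM": 0, "HET": 1, "INV_HOM": 2}
        for pop, p in zip(params.pop_labels, params.p_inverted_per_pop):
            k = sum(
                score[cohort1.truth_karyotypes[s]]
                for s, q in cohort1.genotypes.population_of.items()
                if q == pop
            )
            n = 2 * params.n_samples_per_pop
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= k <= hi, f"{pop}: {k} outside [{lo}, {hi}]"

    def test_null_divergence_fst_near_zero(self):
        """t_div_ci = 0 -> mean per-SNP FST between classes ~ 0 (|mean| < 0.02)."""
        params = simdata.CohortSimParams(
            seed=42, t_div_ci=0.0, p_inverted_per_pop=(0.5, 0.5),
            pop_labels=("a", "b"), pop_latitudes=(33.0, 45.0),
            n_samples_per_pop=110,
        )
        cohort = simdata.simulate_inversion_cohort(params)
        g1 = [s for s, k in cohort.truth_karyotypes.items() if k == "ANC_HOM"]
        g2 = [s for s, k in cohort.truth_karyotypes.items() if k == "INV_HOM"]
        assert min(len(g1), len(g2)) >= 50
        ci = np.nonzero(simdata.realized_ci_site_mask(cohort))[0]
        recs = popgen.weir_cockerham_fst(
            cohort.genotypes.take_sites(ci), g1, g2
        )
        assert abs(np.mean([r.fst for r in recs])) < 0.02


class TestOrthologFamilies:
    def test_inversion_pair_identical_at_zero_divergence(self):
        params = simdata.OrthologSimParams(
            n_families=3, seq_length=2000, seed=11,
            species_tree_ages={**simdata.DEFAULT_TREE_AGES, "t_inv": 0.0},
        )
        fams = simdata.simulate_ortholog_families(params)
        for fam in fams:
            assert fam.sequences["trout_anc"] == fam.sequences["trout_inv"]

    def test_pairwise_divergence_expectation(self, families200):
        """Mean anc<->inv p-distance ~ 2 * rate * t_inv within 3 SE."""
        p = []
        for fam in families200:
            a = np.frombuffer(fam.sequences["trout_anc"].encode(), dtype="S1")
            b = np.frombuffer(fam.sequences["trout_inv"].encode(), dtype="S1")
            p.append(float((a != b).mean()))
        p = np.array(p)
        # JC69: E[p] = 3/4 (1 - exp(-4/3 * 2 mu t)); ~ 2 mu t at small distance
        expected = 0.75 * (1 - np.exp(-4.0 / 3.0 * 2 * 1e-3 * 1.0))
        se = p.std(ddof=1) / np.sqrt(len(p))
        assert abs(p.mean() - expected) < 3 * se

    def test_non_nested_ages_raise(self):
        with pytest.raises(ValueError, match="nested"):
            simdata.simulate_ortholog_families(
                simdata.OrthologSimParams(
                    n_families=1,
                    species_tree_ages={**simdata.DEFAULT_TREE_AGES, "wgd": 120.0},
                )
            )

    def test_family_has_required_taxa_and_equal_lengths(self, families200):
        fam = families200[0]
        assert set(fam.sequences) == set(simdata.FAMILY_TAXA)
        assert len({len(s) for s in fam.sequences.values()}) == 1


class TestAnnotation:
    def test_multiplier_one_means_no_planted_truth(self):
        params = simdata.AnnotationSimParams(
            n_genes=500, n_terms=8, seed=13,
            enriched_terms={"T000": 1.0},
        )
        _, _, truth = simdata.simulate_annotation(params)
        assert truth == []

    def test_byte_identical_on_rerun(self, tmp_path):
        params = simdata.AnnotationSimParams(n_genes=400, n_terms=6, seed=9)
        digests = []
        for tag in ("a", "b"):
            table, _, _ = simdata.simulate_annotation(params)
            path = tmp_path / f"{tag}.tsv"
            table.to_csv(path, sep="\t", index=False)
            digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert digests[0] == digests[1]

    def test_probability_clipping_warns(self):
        params = simdata.AnnotationSimParams(
            n_genes=200, n_terms=4, baseline_term_prob=0.3, seed=1,
            enriched_terms={"T000": 8.0},
        )
        with pytest.warns(UserWarning, match="clipped"):
            simdata.simulate_annotation(params)

    def test_ci_genes_lie_inside_interval(self):
        params = simdata.AnnotationSimParams(n_genes=300, n_terms=5, seed=21)
        table, ci_genes, _ = simdata.simulate_annotation(params)
        sub = table[table["gene_id"].isin(ci_genes)]
        assert (sub["start"] >= params.ci_start).all()
        assert (sub["end"] <= params.ci_end + 1000).all()
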