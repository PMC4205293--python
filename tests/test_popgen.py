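import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_dataset
from oracles import rst_bruteforce, wc_fstats_bruteforce
from refugia.genotypes import GenotypeDataset
from refugia.popgen import (
    allelic_richness,
    expected_heterozygosity,
    fstats_wc,
    mean_expected_heterozygosity,
    observed_heterozygosity,
    pairwise_fst_matrix,
    permutation_pvalue,
    population_inbreeding,
    rst_slatkin,
    summary_table,
)


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([np.array([4])], 0.0),  # monomorphic
            ([np.array([1, 1])], 1.0),  # one diploid het: (2/1)*(1-0.5)
            ([np.array([2, 2])], 2 / 3),  # (4/3)*(1-0.5)
        ],
    )
    def test_unbiased_gene_diversity_worked_values(self, counts, expected):
        _, mean = expected_heterozygosity(counts)
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_plain_estimator_option(self):
        _, mean = expected_heterozygosity([np.array([2, 2])], unbiased=False)
        assert mean == pytest.approx(0.5)

    def test_tiny_locus_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            per_locus, _ = expected_heterozygosity([np.array([1]), np.array([3, 3])])
        assert len(per_locus) == 1

    def test_unbiasedness_over_replicate_samples(self, rng):
        # samples from a known pool recover the pool's gene diversity
        pool = np.array([0.5, 0.3, 0.2])
        target = 1 - (pool**2).sum()
        estimates = []
        for _ in range(400):
            counts = rng.multinomial(12, pool)
            _, he = expected_heterozygosity([counts])
            estimates.append(he)
        assert np.mean(estimates) == pytest.approx(target, abs=0.01)

    def test_observed_heterozygosity_counts(self):
        hom = np.array([[[7, 7]], [[8, 8]]])
        het = np.array([[[7, 8]], [[8, 9]]])
        assert observed_heterozygosity(hom) == 0.0
        assert observed_heterozygosity(het) == 1.0
        mixed = np.array([[[7, 8]], [[7, 9]], [[8, 9]], [[7, 7]]])
        assert observed_heterozygosity(mixed) == pytest.approx(0.75)


class TestAllelicRichness:
    @pytest.mark.parametrize(
        "counts, g, expected",
        [
            ([np.array([6])], 2, 1.0),  # monomorphic
            ([np.array([2, 2])], 2, 5 / 3),  # 2*(1 - C(2,2)/C(4,2))
            ([np.array([3, 1])], 2, 1.5),  # 1 + (1 - C(3,2)/C(4,2))
        ],
    )
    def test_combinatorial_worked_values(self, counts, g, expected):
        _, ar = allelic_richness(counts, g=g)
        assert ar == pytest.approx(expected, abs=1e-12)

    def test_reference_exceeding_sample_rejected(self):
        with pytest.raises(ValueError, match="gene copies"):
            allelic_richness([np.array([2, 1])], g=4)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_reference_size(self, seed):
        rng = np.random.default_rng(seed)
        counts = [rng.integers(1, 8, size=rng.integers(1, 5))]
        values = [allelic_richness(counts, g=g)[1] for g in range(1, int(counts[0].sum()) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        # never exceeds the observed allele count
        assert values[-1] <= len(counts[0]) + 1e-12


class TestFstats:
    def test_complete_differentiation(self):
        al = np.zeros((8, 1, 2), dtype=int)
        al[:4] = 10
        al[4:] = 20
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 4))
        _, fst, fit = fstats_wc(ds)
        assert fst == pytest.approx(1.0)
        assert fit == pytest.approx(1.0)

    def test_panmictic_null_centred_on_zero(self, rng):
        # populations drawn from one Hardy-Weinberg pool
        vals = []
        for _ in range(40):
            al = rng.integers(9, 13, size=(48, 2, 2))
            ds = GenotypeDataset(alleles=al, pops=np.repeat(np.arange(4), 12))
            vals.append(fstats_wc(ds)[1])
        assert abs(np.mean(vals)) < 0.015

    def test_matches_bruteforce_anova_on_worked_fixture(self, worked_dataset):
        ours = fstats_wc(worked_dataset)
        oracle = wc_fstats_bruteforce(worked_dataset)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_anova_on_random_data(self, seed):
        ds = random_dataset(np.random.default_rng(seed), n_pops=5, n_per_pop=7)
        np.testing.assert_allclose(fstats_wc(ds), wc_fstats_bruteforce(ds), atol=1e-9)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14])
    def test_fixation_index_identity(self, seed):
        # (1-FIT) = (1-FIS)(1-FST) for the variance-component ratios
        ds = random_dataset(np.random.default_rng(seed))
        fis, fst, fit = fstats_wc(ds)
        assert (1 - fit) == pytest.approx((1 - fis) * (1 - fst), abs=1e-12)

    def test_monomorphic_reported_as_missing(self):
        al = np.full((6, 2, 2), 9, dtype=int)
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 3))
        assert all(np.isnan(v) for v in fstats_wc(ds))

    def test_single_population_rejected(self, worked_dataset):
        with pytest.raises(ValueError):
            fstats_wc(worked_dataset.subset_populations([0]))


class TestRst:
    def test_identical_populations_near_zero(self, rng):
        al = rng.integers(10, 16, size=(60, 2, 2))
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1, 2], 20))
        assert abs(rst_slatkin(ds)) < 0.05

    def test_fixed_size_difference_is_one(self):
        al = np.zeros((8, 1, 2), dtype=int)
        al[:4] = 10
        al[4:] = 20
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 4))
        assert rst_slatkin(ds) == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, worked_dataset):
        assert rst_slatkin(worked_dataset) == pytest.approx(
            rst_bruteforce(worked_dataset), abs=1e-9
        )

    def test_monomorphic_missing(self):
        al = np.full((4, 1, 2), 7, dtype=int)
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 2))
        assert np.isnan(rst_slatkin(ds))


class TestPermutation:
    def test_seed_determinism_and_lower_bound(self, worked_dataset):
        p1 = permutation_pvalue("fst", worked_dataset, n_perm=99, seed=5)
        p2 = permutation_pvalue("fst", worked_dataset, n_perm=99, seed=5)
        assert p1 == p2
        assert p1 >= 1 / 100

    def test_unknown_statistic_rejected(self, worked_dataset):
        with pytest.raises(ValueError):
            permutation_pvalue("gst", worked_dataset, n_perm=99)

    def test_too_few_permutations_rejected(self, worked_dataset):
        with pytest.raises(ValueError):
            permutation_pvalue("fst", worked_dataset, n_perm=10)

    def test_null_pvalues_are_not_extreme(self, rng):
        # panmictic data: p roughly uniform, so the mean sits near 0.5
        ps = []
        for i in range(15):
            al = rng.integers(9, 13, size=(24, 2, 2))
            ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1, 2], 8))
            ps.append(permutation_pvalue("fst", ds, n_perm=99, seed=i))
        assert 0.25 < np.mean(ps) < 0.75

    def test_fis_permutation_destroys_inbreeding_signal(self, rng):
        # all-homozygote data: observed FIS is extreme, p small
        states = rng.integers(8, 12, size=(30, 2))
        al = np.stack([states, states], axis=2)
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 15))
        assert permutation_pvalue("fis", ds, n_perm=99, seed=0) <= 0.05

    def test_size_permutation_pvalue_valid(self, worked_dataset):
        p = permutation_pvalue("fst_eq_rst", worked_dataset, n_perm=99, seed=2)
        assert 0 < p <= 1


class TestPairwiseFst:
    def test_matrix_symmetric_zero_diagonal(self, worked_dataset):
        mat = pairwise_fst_matrix(worked_dataset).to_numpy()
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 0)

    def test_linearize_algebra(self):
        al = np.zeros((8, 1, 2), dtype=int)
        al[:4] = 10
        al[4:] = 20
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 4))
        lin = pairwise_fst_matrix(ds, linearize=True).to_numpy()
        assert np.isinf(lin[0, 1])  # FST = 1 sentinel

    def test_identical_populations_near_zero(self, rng):
        al = np.tile(rng.integers(10, 14, size=(10, 2, 2)), (2, 1, 1))
        ds = GenotypeDataset(alleles=al, pops=np.repeat([0, 1], 10))
        mat = pairwise_fst_matrix(ds).to_numpy()
        assert abs(mat[0, 1]) < 0.05


class TestSummaries:
    def test_inbreeding_coefficient_detects_homozygote_excess(self, rng):
        states = rng.integers(8, 14, size=(40, 3))
        al = np.stack([states, states], axis=2)  # fully homozygous
        ds = GenotypeDataset(alleles=al, pops=np.zeros(40, dtype=int))
        assert population_inbreeding(ds, 0) == pytest.approx(1.0)

    def test_summary_table_shape_and_bounds(self, worked_dataset):
        table, overall = summary_table(worked_dataset)
        assert list(table.index[:3]) == worked_dataset.pop_names
        assert {"Mean", "SD"} <= set(table.index)
        pops = table.loc[worked_dataset.pop_names]
        assert ((pops["Ho"] >= 0) & (pops["Ho"] <= 1)).all()
        assert ((pops["He"] >= 0) & (pops["He"] <= 1)).all()
        assert (pops["Ar"] <= pops["A"] + 1e-9).all()
        assert set(overall) == {"FIS", "FST", "FIT", "RST"}

    def test_mean_he_matches_manual_average(self, worked_dataset):
        table, _ = summary_table(worked_dataset)
        manual = table.loc[worked_dataset.pop_names, "He"].mean()
        assert mean_expected_heterozygosity(worked_dataset) == pytest.approx(manual)
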