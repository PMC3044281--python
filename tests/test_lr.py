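"""Saturated interaction logit, LRT, stepwise search, shrunken statistic."""

import numpy as np
import pytest

from epinull import (
    GenotypeDataset,
    NullSimConfig,
    PenetranceModel,
    corrected_statistic,
    fit_full_interaction,
    lrt,
    simulate_epistasis_dataset,
    simulate_null_dataset,
    single_locus_chi2,
    stepwise_search,
)
from epinull.nulls import chi2_pvalue

# threshold-type epistasis: strong joint effect with visible marginals, the
# regime forward selection is designed for (pure XOR defeats any greedy
# marginal-first search)
THRESHOLD_PENETRANCE = np.array(
    [[0.05, 0.05, 0.05], [0.05, 0.65, 0.65], [0.05, 0.65, 0.65]]
)


def g2_oracle(dataset, snp_indices):
    """Direct cell-wise G2 of the 3^d x 2 table, written independently."""
    d = len(snp_indices)
    cells = np.zeros(dataset.n_samples, dtype=int)
    for j in snp_indices:
        cells = cells * 3 + dataset.genotypes[:, j]
    g2 = 0.0
    n = dataset.n_samples
    n1, n0 = dataset.n_cases, dataset.n_controls
    for c in range(3**d):
        for cls, ntot in ((1, n1), (0, n0)):
            obs = ((cells == c) & (dataset.phenotype == cls)).sum()
            exp = (cells == c).sum() * ntot / n
            if obs > 0:
                g2 += 2 * obs * np.log(obs / exp)
    return g2


class TestSaturatedFit:
    @pytest.mark.parametrize("d,df", [(2, 8), (3, 26), (4, 80)])
    def test_parameter_and_df_counts(self, d, df):
        ds = simulate_null_dataset(NullSimConfig(n_samples=500, n_snps=4, seed=d))
        fit = fit_full_interaction(ds, tuple(range(d)))
        assert fit.n_params == 3**d
        assert lrt(fit, ds).df == df

    def test_single_cell_degeneracy(self):
        """Constant genotypes: full model collapses onto the null model."""
        ds = GenotypeDataset(
            np.zeros((40, 2), dtype=np.int8), np.array([1, 0] * 20)
        )
        res = lrt(fit_full_interaction(ds, (0, 1)), ds)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.pvalue == pytest.approx(1.0)

    def test_statistic_equals_g2_oracle(self, small_null_dataset):
        for snps in [(0,), (1, 3), (0, 2, 5)]:
            got = lrt(fit_full_interaction(small_null_dataset, snps),
                      small_null_dataset).statistic
            assert got == pytest.approx(g2_oracle(small_null_dataset, snps))

    def test_invariant_to_genotype_relabeling(self, small_null_dataset):
        """The saturated model only sees cell identities, not codes."""
        base = lrt(
            fit_full_interaction(small_null_dataset, (0, 1)), small_null_dataset
        ).statistic
        geno = small_null_dataset.genotypes.copy()
        geno[:, 0] = 2 - geno[:, 0]  # swap homozygote labels
        relabeled = GenotypeDataset(geno, small_null_dataset.phenotype)
        assert lrt(
            fit_full_interaction(relabeled, (0, 1)), relabeled
        ).statistic == pytest.approx(base)

    def test_null_mean_matches_theoretical_df(self):
        """Two fixed SNPs: the LRT statistic has null mean ~8."""
        stats = []
        for seed in range(300):
            ds = simulate_null_dataset(
                NullSimConfig(n_samples=500, n_snps=2, seed=seed)
            )
            stats.append(lrt(fit_full_interaction(ds, (0, 1)), ds).statistic)
        assert abs(np.mean(stats) - 8.0) < 3 * np.sqrt(16 / 300)


class TestStepwise:
    def test_exhaustion_returns_all_candidates(self, small_null_dataset):
        sel = stepwise_search(small_null_dataset, [5, 1, 3], order=3)
        assert set(sel) == {1, 3, 5}

    def test_result_is_subset_of_candidates(self, small_null_dataset):
        sel = stepwise_search(small_null_dataset, [0, 2, 3, 5], order=2)
        assert len(sel) == 2 and set(sel) <= {0, 2, 3, 5}

    def test_planted_interaction_selected(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            ds = simulate_epistasis_dataset(
                NullSimConfig(n_samples=1200, n_snps=8, seed=100 + seed),
                PenetranceModel((2, 5), THRESHOLD_PENETRANCE),
            )
            sel = stepwise_search(ds, range(8), order=2)
            hits += set(sel) == {2, 5}
        assert hits >= 0.95 * reps


class TestCorrectedStatistic:
    def test_arithmetic_contract(self, small_null_dataset):
        r = lrt(
            fit_full_interaction(small_null_dataset, (0, 1)), small_null_dataset
        ).statistic
        k0 = single_locus_chi2(small_null_dataset, 0)
        k1 = single_locus_chi2(small_null_dataset, 1)
        got = corrected_statistic(small_null_dataset, 0, 1)
        assert got == pytest.approx(r - k0 - k1)

    def test_zero_marginal_association_leaves_r(self):
        """Monomorphic SNPs carry no single-locus term."""
        geno = np.zeros((60, 2), dtype=np.int8)
        geno[:30, 0] = 1  # variation independent of phenotype pattern below
        phen = np.array([1, 0] * 30)
        ds = GenotypeDataset(geno, phen)
        r = lrt(fit_full_interaction(ds, (0, 1)), ds).statistic
        assert single_locus_chi2(ds, 1) == 0.0
        assert corrected_statistic(ds, 0, 1) == pytest.approx(
            r - single_locus_chi2(ds, 0)
        )

    def test_same_snp_rejected(self, small_null_dataset):
        with pytest.raises(ValueError):
            corrected_statistic(small_null_dataset, 1, 1)

    def test_conservative_against_unshrunken_reference(self):
        """Referring R' to the chi-square null of R rejects less often than
        nominal: the shrunken statistic is conservative."""
        rej = 0
        reps = 2000
        for seed in range(reps):
            ds = simulate_null_dataset(
                NullSimConfig(n_samples=300, n_snps=2, seed=5000 + seed)
            )
            rprime = corrected_statistic(ds, 0, 1)
            rej += chi2_pvalue(max(rprime, 0.0), 8) <= 0.05
        assert rej / reps < 0.05
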