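"""MDR tabulation, risk collapse, chi-square, and cross-validated search."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from epinull import (
    GenotypeDataset,
    GenotypeTable,
    MDRModel,
    NullSimConfig,
    PenetranceModel,
    chi2_2x2,
    collapse,
    cv_search,
    fit_without_search,
    search_orders,
    select_champion,
    simulate_epistasis_dataset,
    simulate_null_dataset,
    table1,
    table1_dataset,
    tabulate,
)
from epinull.mdr import DegenerateTableError

XOR_PENETRANCE = np.array(
    [[0.05, 0.75, 0.05], [0.75, 0.05, 0.75], [0.05, 0.75, 0.05]]
)


class TestTabulate:
    def test_worked_example_counts(self):
        ds = table1_dataset()
        t = tabulate(ds, (0, 1))
        fix = table1()
        np.testing.assert_array_equal(t.case_counts.reshape(3, 3), fix.case)
        np.testing.assert_array_equal(t.control_counts.reshape(3, 3), fix.control)
        assert t.case_counts[:3].sum() == 316  # first-SNP homozygous row

    def test_degenerate_single_cell(self):
        ds = GenotypeDataset(
            np.zeros((10, 1), dtype=np.int8), np.array([1] * 5 + [0] * 5)
        )
        t = tabulate(ds, (0,))
        assert t.case_counts[0] == 5 and t.control_counts[0] == 5
        assert t.case_counts[1:].sum() == 0

    def test_conservation(self, small_null_dataset):
        t = tabulate(small_null_dataset, (0, 3))
        assert (t.case_counts + t.control_counts).sum() == 200

    def test_duplicate_indices_rejected(self, small_null_dataset):
        with pytest.raises(ValueError, match="duplicate"):
            tabulate(small_null_dataset, (1, 1))


class TestCollapse:
    def test_worked_example_collapse(self):
        coll = collapse(tabulate(table1_dataset(), (0, 1)), threshold=1.0)
        np.testing.assert_array_equal(
            coll.table2x2, [[399, 443], [601, 557]]
        )

    def test_all_high_degenerate_labeling(self):
        t = GenotypeTable((0,), np.array([5, 5, 5]), np.array([1, 1, 1]))
        coll = collapse(t, threshold=1.0)
        assert coll.cell_labels.all()
        np.testing.assert_array_equal(coll.table2x2, [[0, 0], [15, 3]])

    def test_empty_cell_is_low_risk(self):
        t = GenotypeTable((0,), np.array([0, 9, 0]), np.array([0, 3, 6]))
        coll = collapse(t, threshold=1.0)
        assert not coll.cell_labels[0]  # (0, 0) cell
        assert not coll.cell_labels[2]  # cases absent
        assert coll.cell_labels[1]

    def test_grand_total_preserved(self, small_null_dataset):
        coll = collapse(tabulate(small_null_dataset, (1, 2)))
        assert coll.table2x2.sum() == small_null_dataset.n_samples


class TestChi2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[399, 443], [601, 557]], 3.971135),
            ([[10, 10], [20, 20]], 0.0),
            ([[0, 10], [10, 0]], 20.0),
        ],
    )
    def test_pearson_values(self, table, expected):
        assert chi2_2x2(table) == pytest.approx(expected, abs=1e-4)

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chi2_2x2([[0, 0], [10, 20]])

    def test_agrees_with_scipy_and_g2(self):
        """Pearson (no correction) matches scipy exactly; on null-structured
        tables with healthy expected counts it tracks the likelihood-ratio
        G2 within 5% (the two tests are interchangeable there)."""
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(200):
            p, q = rng.uniform(0.3, 0.7, size=2)
            probs = np.outer([p, 1 - p], [q, 1 - q]).ravel()
            o = rng.multinomial(400, probs).reshape(2, 2)
            if (np.outer(o.sum(1), o.sum(0)) / o.sum() < 5).any():
                continue
            pearson = chi2_2x2(o)
            assert pearson == pytest.approx(
                chi2_contingency(o, correction=False)[0], rel=1e-10
            )
            g2 = chi2_contingency(o, correction=False, lambda_="log-likelihood")[0]
            if pearson > 0.5:
                assert pearson == pytest.approx(g2, rel=0.05)
                checked += 1
        assert checked > 20


class TestFitWithoutSearch:
    def test_worked_example_statistic(self):
        model = fit_without_search(table1_dataset(), (0, 1))
        assert model.chi2 == pytest.approx(3.971, abs=1e-3)

    def test_dominant_coded_phenotype_maximal(self):
        """A SNP that recodes the phenotype achieves the maximal 2x2
        chi-square for its class sizes (= n)."""
        phen = np.array([1, 0] * 50)
        geno = np.column_stack([2 * phen, np.zeros(100, dtype=int)]).astype(np.int8)
        model = fit_without_search(GenotypeDataset(geno, phen), (0,))
        assert model.chi2 == pytest.approx(100.0)


class TestCvSearch:
    def test_single_candidate_degeneracy(self, small_null_dataset):
        """With L = k there is one subset: consistency is n_folds and the
        statistic equals the no-search fit."""
        ds = small_null_dataset
        model = cv_search(ds, 2, n_folds=5, seed=0, candidates=[1, 4])
        assert model.cv_consistency == 5
        assert model.snp_indices == (1, 4)
        assert model.chi2 == pytest.approx(
            fit_without_search(ds, (1, 4), on_degenerate="zero").chi2
        )

    def test_planted_epistasis_recovered(self):
        """A strong two-SNP interaction must win the exhaustive search."""
        hits = 0
        reps = 20
        for seed in range(reps):
            ds = simulate_epistasis_dataset(
                NullSimConfig(n_samples=1200, n_snps=10, seed=seed),
                PenetranceModel((3, 6), XOR_PENETRANCE),
            )
            model = cv_search(ds, 2, seed=seed)
            hits += model.snp_indices == (3, 6)
        assert hits >= 0.95 * reps

    def test_deterministic_given_seed(self, small_null_dataset):
        a = cv_search(small_null_dataset, 2, seed=9)
        b = cv_search(small_null_dataset, 2, seed=9)
        assert a == b

    def test_search_guard(self, small_null_dataset):
        with pytest.raises(ValueError, match="order"):
            cv_search(small_null_dataset, 0)


class TestSearchOrders:
    def test_single_order_reduces_to_cv_search(self, small_null_dataset):
        models, champ = search_orders(small_null_dataset, [2], seed=1)
        assert champ == models[0] == cv_search(small_null_dataset, 2, seed=1)

    def test_champion_rule_on_published_shaped_models(self):
        """Consistency first, accuracy second: a 10/10 four-way model with
        higher CV accuracy beats a 10/10 single-SNP model."""
        models = [
            MDRModel((0,), 27.1, cv_accuracy=0.7246, cv_consistency=10),
            MDRModel((0, 1), 38.3, cv_accuracy=0.7086, cv_consistency=6),
            MDRModel((0, 1, 2), 55.4, cv_accuracy=0.7833, cv_consistency=3),
            MDRModel((0, 1, 2, 3), 85.2, cv_accuracy=0.7615, cv_consistency=10),
        ]
        assert select_champion(models).snp_indices == (0, 1, 2, 3)

    def test_champion_snps_within_dataset(self, small_null_dataset):
        _, champ = search_orders(small_null_dataset, [1, 2], seed=2)
        assert set(champ.snp_indices) <= set(range(small_null_dataset.n_snps))
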