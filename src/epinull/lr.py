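"""Saturated genotype-interaction logistic regression and likelihood-ratio tests.

The full d-way interaction model is the saturated model on the 3^d joint
genotype cells: the fitted case probability of a cell is its observed case
fraction.  Its deviance equals that of a dummy-coded logistic regression with
all interaction terms, but the closed form has no convergence pathologies
when cells are empty or contain one class only (where iteratively reweighted
fitting diverges).  The likelihood-ratio statistic against the intercept-only
model is the G2 of the 3^d x 2 contingency table and is referred to
chi-square with 3^d - 1 degrees of freedom.

Also provided: greedy forward stepwise subset search on the full-interaction
deviance, and the marginally-shrunken pair statistic
``R'(l, m) = R(l, m) - (k_l + k_m)`` with ``k`` the single-locus Pearson
chi-squares, whose reference to the unshrunken chi-square null is
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .dataset import GenotypeDataset
from .mdr import _cell_index

__all__ = [
    "InteractionFit",
    "LrtResult",
    "SaturatedInteractionLogit",
    "fit_full_interaction",
    "null_deviance",
    "lrt",
    "stepwise_search",
    "single_locus_chi2",
    "corrected_statistic",
]


@dataclass
class InteractionFit:
    snp_indices: tuple[int, ...]
    deviance: float
    n_params: int
    converged: bool = True


@dataclass
class LrtResult:
    statistic: float
    df: int
    pvalue: float


def _binomial_cell_deviance(case: np.ndarray, control: np.ndarray) -> float:
    """-2 log-likelihood of the saturated per-cell case probabilities."""
    total = case + control
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(case, np.where(total > 0, case / np.maximum(total, 1), 1))
        ll = ll + xlogy(
            control, np.where(total > 0, control / np.maximum(total, 1), 1)
        )
    return float(-2.0 * ll.sum())


def _deviance_from_cells(cells: np.ndarray, y: np.ndarray, n_cells: int) -> float:
    case = np.bincount(cells[y == 1], minlength=n_cells).astype(float)
    control = np.bincount(cells[y == 0], minlength=n_cells).astype(float)
    return _binomial_cell_deviance(case, control)


def fit_full_interaction(dataset: GenotypeDataset, snp_indices) -> InteractionFit:
    """Saturated d-way interaction model; deviance from per-cell case fractions."""
    snp_indices = tuple(int(i) for i in snp_indices)
    if len(set(snp_indices)) != len(snp_indices):
        raise ValueError("duplicate SNP indices")
    if min(snp_indices) < 0 or max(snp_indices) >= dataset.n_snps:
        raise ValueError("SNP index out of range")
    d = len(snp_indices)
    cells = _cell_index(dataset.genotypes, snp_indices)
    dev = _deviance_from_cells(cells, dataset.phenotype, 3**d)
    return InteractionFit(snp_indices, dev, 3**d)


def null_deviance(dataset: GenotypeDataset) -> float:
    """Deviance of the intercept-only (constant case probability) model."""
    n1 = dataset.n_cases
    n0 = dataset.n_controls
    n = n1 + n0
    return float(-2.0 * (xlogy(n1, n1 / n) + xlogy(n0, n0 / n)))


def lrt(full: InteractionFit, dataset: GenotypeDataset) -> LrtResult:
    """Full-vs-null likelihood ratio test with df = 3^d - 1."""
    stat = null_deviance(dataset) - full.deviance
    if stat < -1e-8:
        raise ArithmeticError("negative likelihood-ratio statistic")
    stat = max(stat, 0.0)
    df = full.n_params - 1
    return LrtResult(stat, df, float(chi2_dist.sf(stat, df)))


def stepwise_search(dataset: GenotypeDataset, candidates, order: int):
    """Greedy forward selection on the full-interaction deviance.

    Starting empty, each step adds the candidate whose inclusion yields the
    lowest saturated-model deviance on the enlarged subset (ties to the
    lowest SNP index), stopping at ``order`` SNPs.
    """
    candidates = sorted(int(c) for c in candidates)
    if len(candidates) < order:
        raise ValueError("fewer candidates than the requested order")
    chosen: list[int] = []
    for _ in range(order):
        best_c, best_dev = None, np.inf
        for c in candidates:
            if c in chosen:
                continue
            trial = chosen + [c]
            cells = _cell_index(dataset.genotypes, trial)
            dev = _deviance_from_cells(
                cells, dataset.phenotype, 3 ** len(trial)
            )
            if dev < best_dev:
                best_c, best_dev = c, dev
        chosen.append(best_c)
    return tuple(chosen)


def single_locus_chi2(dataset: GenotypeDataset, snp: int) -> float:
    """Pearson chi-square of the 2x3 phenotype-by-genotype table.

    Genotype categories absent from the data are dropped from the table, so
    a monomorphic SNP scores 0.
    """
    cells = dataset.genotypes[:, snp].astype(np.int64)
    case = np.bincount(cells[dataset.phenotype == 1], minlength=3).astype(float)
    control = np.bincount(cells[dataset.phenotype == 0], minlength=3).astype(float)
    keep = (case + control) > 0
    o = np.stack([case[keep], control[keep]])
    if o.shape[1] < 2:
        return 0.0
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    return float(((o - e) ** 2 / e).sum())


def corrected_statistic(dataset: GenotypeDataset, l: int, m: int) -> float:
    """Marginally-shrunken pair statistic R(l, m) - (k_l + k_m)."""
    if l == m:
        raise ValueError("the two SNPs must differ")
    full = fit_full_interaction(dataset, (l, m))
    r = lrt(full, dataset).statistic
    return r - single_locus_chi2(dataset, l) - single_locus_chi2(dataset, m)


class SaturatedInteractionLogit(BaseEstimator):
    """Saturated d-way interaction logit as an sklearn-style estimator.

    ``fit`` exposes ``deviance_``, ``null_deviance_``, ``lrt_statistic_``,
    ``lrt_df_``, ``lrt_pvalue_``; ``predict_proba`` returns the fitted
    per-cell case probabilities (0.5 for cells unseen at fit time).
    """

    def __init__(self, snp_indices=(0,)):
        self.snp_indices = snp_indices

    def fit(self, X, y):
        ds = GenotypeDataset(np.asarray(X), np.asarray(y))
        fitres = fit_full_interaction(ds, self.snp_indices)
        res = lrt(fitres, ds)
        self.deviance_ = fitres.deviance
        self.null_deviance_ = null_deviance(ds)
        self.lrt_statistic_ = res.statistic
        self.lrt_df_ = res.df
        self.lrt_pvalue_ = res.pvalue
        d = len(tuple(self.snp_indices))
        cells = _cell_index(ds.genotypes, tuple(self.snp_indices))
        case = np.bincount(cells[ds.phenotype == 1], minlength=3**d)
        tot = np.bincount(cells, minlength=3**d)
        with np.errstate(invalid="ignore"):
            self.cell_probs_ = np.where(tot > 0, case / np.maximum(tot, 1), 0.5)
        return self

    def predict_proba(self, X):
        cells = _cell_index(np.asarray(X, dtype=np.int8), tuple(self.snp_indices))
        p1 = self.cell_probs_[cells]
        return np.column_stack([1 - p1, p1])
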