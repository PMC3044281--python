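"""Multifactor dimensionality reduction (MDR).

MDR tabulates the joint genotypes of a k-SNP subset into 3^k cells, labels
each cell high- or low-risk by comparing its case:control ratio with a
threshold (by default the overall case:control ratio of the fitting data),
collapses to a 2x2 high/low x case/control table, and scores the subset with
the Pearson chi-square of that table.  Exhaustive model search evaluates
every k-subset under stratified 10-fold cross-validation; a subset's
cross-validation consistency is the number of folds in which it is the fold's
best model.

Conventions (configurable): ratio ties are labeled high-risk; cells with no
training samples are labeled low-risk; the reported chi-square of a selected
model is computed on the full fitting data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .dataset import GenotypeDataset

__all__ = [
    "GenotypeTable",
    "RiskCollapse",
    "MDRModel",
    "MDRClassifier",
    "MDRSearch",
    "DegenerateTableError",
    "tabulate",
    "collapse",
    "chi2_2x2",
    "fit_without_search",
    "cv_search",
    "search_orders",
    "select_champion",
]

_MAX_ORDER = 8
_MAX_SUBSETS = 500_000


class DegenerateTableError(ValueError):
    """A 2x2 table with an empty row or column has no defined chi-square."""


@dataclass
class GenotypeTable:
    """Case/control counts over the 3^k joint-genotype cells of a SNP subset.

    Cells are indexed lexicographically by the genotype tuple (first SNP most
    significant).
    """

    snp_indices: tuple[int, ...]
    case_counts: np.ndarray
    control_counts: np.ndarray

    @property
    def order(self) -> int:
        return len(self.snp_indices)


@dataclass
class RiskCollapse:
    """Learned high/low labeling of cells and the collapsed 2x2 table.

    ``table2x2`` rows are (low, high), columns (case, control); the grand
    total always equals the number of tabulated samples.
    """

    threshold: float
    cell_labels: np.ndarray  # bool, True = high-risk
    table2x2: np.ndarray  # shape (2, 2)


@dataclass
class MDRModel:
    """A scored SNP subset: CV summary plus the full-data chi-square."""

    snp_indices: tuple[int, ...]
    chi2: float
    cv_accuracy: float | None = None
    cv_consistency: int | None = None
    n_folds: int | None = None


def _cell_index(genotypes: np.ndarray, snp_indices) -> np.ndarray:
    cells = genotypes[:, snp_indices[0]].astype(np.int32)
    for j in snp_indices[1:]:
        cells = cells * 3 + genotypes[:, j]
    return cells


def tabulate(dataset: GenotypeDataset, snp_indices) -> GenotypeTable:
    """Count cases and controls in every joint-genotype cell of the subset."""
    snp_indices = tuple(int(i) for i in snp_indices)
    k = len(snp_indices)
    if len(set(snp_indices)) != k:
        raise ValueError("duplicate SNP indices")
    if k < 1 or k > _MAX_ORDER:
        raise ValueError(f"order must be between 1 and {_MAX_ORDER}")
    if min(snp_indices) < 0 or max(snp_indices) >= dataset.n_snps:
        raise ValueError("SNP index out of range")
    cells = _cell_index(dataset.genotypes, snp_indices)
    n_cells = 3**k
    case = np.bincount(cells[dataset.phenotype == 1], minlength=n_cells)
    control = np.bincount(cells[dataset.phenotype == 0], minlength=n_cells)
    return GenotypeTable(snp_indices, case, control)


def collapse(table: GenotypeTable, threshold: float | None = None) -> RiskCollapse:
    """Label each cell high- or low-risk and pool into a 2x2 table.

    A cell is high-risk iff ``cases >= threshold * controls`` (ratio ties go
    high; a cell with cases but no controls is high).  Empty cells are
    low-risk.  ``threshold=None`` uses the table's case:control ratio, which
    is 1 for balanced designs.
    """
    ca, co = table.case_counts, table.control_counts
    if threshold is None:
        threshold = ca.sum() / co.sum()
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    high = (ca >= threshold * co) & ((ca + co) > 0)
    table2x2 = np.array(
        [
            [ca[~high].sum(), co[~high].sum()],
            [ca[high].sum(), co[high].sum()],
        ],
        dtype=np.int64,
    )
    return RiskCollapse(float(threshold), high, table2x2)


def chi2_2x2(table2x2) -> float:
    """Pearson chi-square of a 2x2 table, no continuity correction.

    Raises :class:`DegenerateTableError` when a row or column margin is zero;
    the caller decides how to treat such collapses.
    """
    o = np.asarray(table2x2, dtype=float).reshape(2, 2)
    rows, cols, n = o.sum(axis=1), o.sum(axis=0), o.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("degenerate table")
    e = np.outer(rows, cols) / n
    return float(((o - e) ** 2 / e).sum())


def fit_without_search(
    dataset: GenotypeDataset,
    snp_indices,
    threshold: float | None = None,
    on_degenerate: str = "raise",
) -> MDRModel:
    """Tabulate, collapse, and score a fixed SNP subset on the full data.

    ``on_degenerate='zero'`` reports statistic 0 when the collapse puts every
    sample in one risk group (no association is then expressible).
    """
    coll = collapse(tabulate(dataset, snp_indices), threshold)
    try:
        stat = chi2_2x2(coll.table2x2)
    except DegenerateTableError:
        if on_degenerate == "zero":
            stat = 0.0
        else:
            raise
    return MDRModel(tuple(int(i) for i in snp_indices), stat)


def _counts_by_class(cells, rows, n_cells):
    """Per-candidate cell counts for the given sample rows.

    ``cells`` is (n, P); returns (P, n_cells).
    """
    P = cells.shape[1]
    idx = cells[rows].astype(np.int64) + np.arange(P, dtype=np.int64) * n_cells
    return (
        np.bincount(idx.ravel(), minlength=P * n_cells)
        .reshape(P, n_cells)
        .astype(np.float64)
    )


def cv_search(
    dataset: GenotypeDataset,
    order: int,
    n_folds: int = 10,
    threshold: float | None = None,
    seed: int = 0,
    candidates=None,
) -> MDRModel:
    """Exhaustive cross-validated search over all k-subsets of the candidates.

    Within each stratified fold the collapse is learned on the training
    samples (threshold defaulting to the training case:control ratio) and the
    fold winner is the subset with the lowest balanced training
    classification error (ties to the lexicographically first subset).  A
    held-out sample is called a case iff its cell is high-risk in the
    training collapse; cells unseen in training predict low-risk.  The
    returned model maximizes cross-validation consistency, breaking ties by
    the lowest average held-out balanced prediction error and then by subset
    order; its chi-square is recomputed on the full data.
    """
    if candidates is None:
        candidates = np.arange(dataset.n_snps)
    candidates = np.sort(np.asarray(candidates, dtype=np.int64))
    k = int(order)
    if k < 1 or k > _MAX_ORDER:
        raise ValueError(f"order must be between 1 and {_MAX_ORDER}")
    if len(candidates) < k:
        raise ValueError("fewer candidate SNPs than the requested order")
    n_subsets = math.comb(len(candidates), k)
    if n_subsets > _MAX_SUBSETS:
        raise ValueError(f"{n_subsets} candidate subsets exceed the search guard")
    if n_folds < 2:
        raise ValueError("need at least two folds")

    combos = np.array(list(combinations(candidates, k)), dtype=np.int64)
    P = len(combos)
    n_cells = 3**k
    cells = dataset.genotypes[:, combos[:, 0]].astype(np.int16)
    for j in range(1, k):
        cells = cells * 3 + dataset.genotypes[:, combos[:, j]]

    y = dataset.phenotype
    case_rows = np.flatnonzero(y == 1)
    ctrl_rows = np.flatnonzero(y == 0)
    full_case = _counts_by_class(cells, case_rows, n_cells)
    full_ctrl = _counts_by_class(cells, ctrl_rows, n_cells)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    wins = np.zeros(P, dtype=np.int64)
    balacc = np.zeros((P, n_folds))
    for f, (_, test_idx) in enumerate(skf.split(cells, y)):
        te_case = _counts_by_class(cells, test_idx[y[test_idx] == 1], n_cells)
        te_ctrl = _counts_by_class(cells, test_idx[y[test_idx] == 0], n_cells)
        tr_case = full_case - te_case
        tr_ctrl = full_ctrl - te_ctrl
        n_tr_case = len(case_rows) - (y[test_idx] == 1).sum()
        n_tr_ctrl = len(ctrl_rows) - (y[test_idx] == 0).sum()
        T = n_tr_case / n_tr_ctrl if threshold is None else threshold
        high = (tr_case >= T * tr_ctrl) & ((tr_case + tr_ctrl) > 0)
        train_err = 0.5 * (
            (tr_case * ~high).sum(axis=1) / n_tr_case
            + (tr_ctrl * high).sum(axis=1) / n_tr_ctrl
        )
        wins[int(np.argmin(train_err))] += 1
        sens = (te_case * high).sum(axis=1) / max((y[test_idx] == 1).sum(), 1)
        spec = (te_ctrl * ~high).sum(axis=1) / max((y[test_idx] == 0).sum(), 1)
        balacc[:, f] = 0.5 * (sens + spec)

    mean_balacc = balacc.mean(axis=1)
    # max consistency, then max held-out accuracy, then lexicographic subset
    best = np.lexsort((np.arange(P), -mean_balacc, -wins))[0]
    snps = tuple(int(i) for i in combos[best])
    full = fit_without_search(dataset, snps, threshold, on_degenerate="zero")
    return MDRModel(
        snps,
        full.chi2,
        cv_accuracy=float(mean_balacc[best]),
        cv_consistency=int(wins[best]),
        n_folds=n_folds,
    )


def select_champion(models: list[MDRModel]) -> MDRModel:
    """Across-order champion: max consistency, ties by max CV accuracy."""
    return max(
        models,
        key=lambda m: (m.cv_consistency, m.cv_accuracy, -len(m.snp_indices)),
    )


def search_orders(
    dataset: GenotypeDataset,
    orders,
    n_folds: int = 10,
    threshold: float | None = None,
    seed: int = 0,
    candidates=None,
) -> tuple[list[MDRModel], MDRModel]:
    """Best model per order plus the across-order champion."""
    models = [
        cv_search(dataset, k, n_folds, threshold, seed, candidates)
        for k in orders
    ]
    return models, select_champion(models)


class MDRClassifier(BaseEstimator, ClassifierMixin):
    """The MDR collapse of a fixed SNP subset as an sklearn classifier.

    ``predict`` labels a sample 1 (case) iff its joint-genotype cell was
    high-risk in the fitted collapse; cells unseen at fit time predict 0.
    """

    def __init__(self, snp_indices=(0,), threshold: float | None = None):
        self.snp_indices = snp_indices
        self.threshold = threshold

    def fit(self, X, y):
        ds = GenotypeDataset(np.asarray(X), np.asarray(y))
        table = tabulate(ds, self.snp_indices)
        coll = collapse(table, self.threshold)
        self.collapse_ = coll
        self.table_ = table
        try:
            self.chi2_ = chi2_2x2(coll.table2x2)
        except DegenerateTableError:
            self.chi2_ = 0.0
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "collapse_")
        cells = _cell_index(np.asarray(X, dtype=np.int8), tuple(self.snp_indices))
        return self.collapse_.cell_labels[cells].astype(int)


class MDRSearch(BaseEstimator, ClassifierMixin):
    """Cross-validated exhaustive MDR model search as an sklearn estimator.

    Fitted attributes mirror :func:`cv_search`: ``best_indices_``,
    ``cv_accuracy_``, ``cv_consistency_``, ``chi2_``.
    """

    def __init__(
        self,
        order: int = 2,
        n_folds: int = 10,
        threshold: float | None = None,
        random_state: int = 0,
    ):
        self.order = order
        self.n_folds = n_folds
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        ds = GenotypeDataset(np.asarray(X), np.asarray(y))
        model = cv_search(
            ds, self.order, self.n_folds, self.threshold, self.random_state
        )
        self.best_indices_ = model.snp_indices
        self.cv_accuracy_ = model.cv_accuracy
        self.cv_consistency_ = model.cv_consistency
        self.chi2_ = model.chi2
        self._final = MDRClassifier(model.snp_indices, self.threshold).fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "best_indices_")
        return self._final.predict(X)
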