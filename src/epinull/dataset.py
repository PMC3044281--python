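"""Case-control genotype datasets, flat-file I/O, and sample partitioning.

A dataset is an ``n x L`` matrix of genotypes coded as minor-allele counts
(0/1/2) together with a binary phenotype (1 = case, 0 = control).  All
downstream stages (screening, modeling, testing) operate on this container;
genotypes are treated categorically throughout, so the 0/1/2 coding is purely
a labeling convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "SplitPlan",
    "read_dataset",
    "write_dataset",
    "make_split",
]

CLASS_COLUMN = "Class"


class DatasetError(ValueError):
    """Raised when a genotype dataset violates its invariants."""


@dataclass
class GenotypeDataset:
    """n samples x L SNPs of categorical genotypes plus a binary phenotype.

    Parameters
    ----------
    genotypes : ndarray of shape (n, L)
        Minor-allele counts; every entry must be 0, 1, or 2.
    phenotype : ndarray of shape (n,)
        Disease status; 1 = case, 0 = control.  Both classes must be present.
    snp_names : list of str
        Unique identifiers aligned with the genotype columns.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetError("genotypes must be a 2-d samples x SNPs matrix")
        if self.snp_names is None:
            self.snp_names = [f"SNP{i}" for i in range(self.genotypes.shape[1])]
        self.snp_names = [str(s) for s in self.snp_names]
        self.validate()

    def validate(self) -> None:
        n, L = self.genotypes.shape
        if L == 0:
            raise DatasetError("dataset has no SNPs")
        if self.phenotype.shape != (n,):
            raise DatasetError("phenotype length does not match sample count")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise DatasetError("genotype values must be 0, 1 or 2")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise DatasetError("phenotype values must be 0 or 1")
        if len(np.unique(self.phenotype)) < 2:
            raise DatasetError("single phenotype class")
        if len(set(self.snp_names)) != L:
            raise DatasetError("duplicate SNP names")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def subset(self, rows: np.ndarray) -> "GenotypeDataset":
        """Dataset restricted to the given sample indices."""
        rows = np.asarray(rows)
        return GenotypeDataset(
            self.genotypes[rows], self.phenotype[rows], list(self.snp_names)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_names == other.snp_names
        )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint sample-index sets partitioning a dataset into near-equal parts."""

    parts: tuple[np.ndarray, ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(p) for p in self.parts)


def read_dataset(path, format: str = "mdr_flat") -> GenotypeDataset:
    """Load a tab-delimited genotype flat file.

    The file must have a header of SNP names with a final column named
    ``Class`` holding the binary phenotype.  Anything other than 0/1/2
    genotypes and a 0/1 two-class phenotype is rejected, naming the first
    offending line.
    """
    if format != "mdr_flat":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise DatasetError(f"malformed flat file: {exc}") from exc
    if df.shape[1] < 2 or df.columns[-1] != CLASS_COLUMN:
        raise DatasetError(f"last column must be named {CLASS_COLUMN!r}")
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0])
        raise DatasetError(f"missing value on line {row + 2}")
    try:
        values = df.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise DatasetError(f"non-integer entry in flat file: {exc}") from exc
    geno, phen = values[:, :-1], values[:, -1]
    bad = ~np.isin(geno, (0, 1, 2)).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DatasetError(f"invalid genotype value on line {row + 2}")
    bad = ~np.isin(phen, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DatasetError(f"non-binary class label on line {row + 2}")
    return GenotypeDataset(geno, phen, list(df.columns[:-1]))


def write_dataset(dataset: GenotypeDataset, path) -> None:
    """Write the tab-delimited flat file; inverse of :func:`read_dataset`."""
    dataset.validate()
    df = pd.DataFrame(dataset.genotypes, columns=dataset.snp_names)
    df[CLASS_COLUMN] = dataset.phenotype
    df.to_csv(path, sep="\t", index=False)


def make_split(
    dataset: GenotypeDataset,
    n_parts: int = 3,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Partition samples into ``n_parts`` nearly equal disjoint subsets.

    Stratified mode (the default) shuffles each phenotype class separately and
    deals samples round-robin, cases first with controls continuing the deal,
    so that part sizes differ by at most one overall and every part keeps
    samples of both classes.
    """
    n = dataset.n_samples
    if n < n_parts:
        raise DatasetError("fewer samples than requested parts")
    rng = np.random.default_rng(seed)
    if stratified:
        counts = [dataset.n_cases, dataset.n_controls]
        if min(counts) < n_parts:
            raise DatasetError("too few samples per class for stratified split")
        order = np.concatenate(
            [
                rng.permutation(np.flatnonzero(dataset.phenotype == cls))
                for cls in (1, 0)
            ]
        )
    else:
        order = rng.permutation(n)
    parts = tuple(np.sort(order[j::n_parts]) for j in range(n_parts))
    return SplitPlan(parts)
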