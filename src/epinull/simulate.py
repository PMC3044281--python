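"""Simulation of case-control genotype data.

Null datasets draw each SNP's minor allele frequency uniformly from
``[maf_low, maf_high]``, generate genotypes under Hardy-Weinberg equilibrium,
and assign a balanced phenotype that is independent of every genotype.  These
are the study conditions for every null-calibration experiment in the
package.  A penetrance-table generator provides positive controls (planted
epistasis) for the screening and modeling stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import GenotypeDataset

__all__ = [
    "NullSimConfig",
    "PenetranceModel",
    "simulate_null_dataset",
    "simulate_epistasis_dataset",
    "permute_phenotype",
]


@dataclass(frozen=True)
class NullSimConfig:
    """Conditions for one null dataset: HWE genotypes, independent phenotype."""

    n_samples: int = 2000
    n_snps: int = 20
    maf_low: float = 0.05
    maf_high: float = 0.5
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        n_cases = round(self.n_samples * self.case_fraction)
        if n_cases < 1 or self.n_samples - n_cases < 1:
            raise ValueError("case_fraction leaves an empty class")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")


@dataclass(frozen=True)
class PenetranceModel:
    """Disease probability for each joint genotype of a k-SNP target set."""

    snp_indices: tuple[int, ...]
    penetrance: np.ndarray  # shape (3,)*k

    def __post_init__(self) -> None:
        pen = np.asarray(self.penetrance, dtype=float)
        object.__setattr__(self, "penetrance", pen)
        if pen.shape != (3,) * len(self.snp_indices):
            raise ValueError("penetrance table must be 3 per involved SNP")
        if ((pen < 0) | (pen > 1)).any():
            raise ValueError("penetrance entries must lie in [0, 1]")


def _hwe_genotypes(n: int, config: NullSimConfig, rng: np.random.Generator):
    q = rng.uniform(config.maf_low, config.maf_high, config.n_snps)
    p0 = (1.0 - q) ** 2
    p01 = p0 + 2.0 * q * (1.0 - q)
    u = rng.random((n, config.n_snps))
    return ((u > p0).astype(np.int8) + (u > p01)).astype(np.int8), q


def simulate_null_dataset(config: NullSimConfig) -> GenotypeDataset:
    """HWE genotypes with a phenotype assigned independently of all SNPs.

    Exactly ``round(n * case_fraction)`` samples are cases, placed by a
    uniformly random labeling; deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    geno, _ = _hwe_genotypes(config.n_samples, config, rng)
    n_cases = round(config.n_samples * config.case_fraction)
    phen = np.zeros(config.n_samples, dtype=np.int8)
    phen[rng.permutation(config.n_samples)[:n_cases]] = 1
    return GenotypeDataset(geno, phen)


def simulate_epistasis_dataset(
    config: NullSimConfig, model: PenetranceModel
) -> GenotypeDataset:
    """HWE genotypes with disease status drawn from a penetrance table.

    Each sample's case probability is the penetrance entry of its joint
    genotype at the target SNPs, so case/control counts are binomial rather
    than fixed.
    """
    if max(model.snp_indices) >= config.n_snps or min(model.snp_indices) < 0:
        raise ValueError("penetrance target SNPs out of range")
    if not model.penetrance.any():
        warnings.warn("penetrance table is identically zero; no cases expected")
    rng = np.random.default_rng(config.seed)
    geno, _ = _hwe_genotypes(config.n_samples, config, rng)
    cells = tuple(geno[:, j] for j in model.snp_indices)
    prob = model.penetrance[cells]
    phen = (rng.random(config.n_samples) < prob).astype(np.int8)
    return GenotypeDataset(geno, phen)


def permute_phenotype(dataset: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Dataset with the phenotype uniformly permuted; genotypes are shared.

    The genotype matrix of the returned dataset is the same array object as
    the input's (no copy), since permutation testing re-runs the pipeline many
    times on large matrices.
    """
    rng = np.random.default_rng(seed)
    out = GenotypeDataset.__new__(GenotypeDataset)
    out.genotypes = dataset.genotypes
    out.phenotype = rng.permutation(dataset.phenotype)
    out.snp_names = dataset.snp_names
    return out
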