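"""The null-distribution engine.

Runs a configured screen -> model pipeline over many independently simulated
null datasets, collects the final test statistic of each, and fits a
(generally non-integer) chi-square degree of freedom to the empirical null.
The non-integer df is handled through the gamma(shape=df/2, scale=2)
representation; the default estimator is the method of moments (the mean of a
chi-square variate equals its df), with a gamma MLE at fixed scale 2 as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from . import lr as lr_mod
from . import mdr as mdr_mod
from . import screen as screen_mod
from .dataset import GenotypeDataset
from .simulate import NullSimConfig, simulate_null_dataset

__all__ = [
    "ScreenConfig",
    "ModelConfig",
    "PipelineConfig",
    "EmpiricalNull",
    "run_pipeline",
    "simulate_null_distribution",
    "fit_chi2_df",
    "chi2_pvalue",
]

_SEED_BOUND = 2**31 - 1


@dataclass(frozen=True)
class ScreenConfig:
    """Stage-1 screening: reduce all SNPs to the top ``d``."""

    method: str = "relieff"  # "relieff" | "turf"
    d: int = 20
    k_neighbors: int = 10
    removal_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("relieff", "turf"):
            raise ValueError(f"unknown screening method {self.method!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Stage-2 modeling and the statistic it reports.

    ``mdr_no_search`` / ``lr_fixed`` fit the top ``order`` SNPs directly;
    ``mdr_search`` / ``lr_stepwise`` search the candidate set first.  MDR
    kinds report the collapsed 2x2 Pearson chi-square, LR kinds the
    full-vs-null likelihood-ratio statistic.
    """

    kind: str = "mdr_search"
    order: int = 2
    n_folds: int = 10
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mdr_no_search", "mdr_search", "lr_fixed", "lr_stepwise"):
            raise ValueError(f"unknown modeling kind {self.kind!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """A full scenario: simulation conditions, optional screening, modeling."""

    sim: NullSimConfig
    modeling: ModelConfig
    screening: ScreenConfig | None = None

    def __post_init__(self) -> None:
        L = self.sim.n_snps
        if self.screening is not None:
            if self.screening.d > L:
                raise ValueError("screening target exceeds the SNP count")
            if self.modeling.order > self.screening.d:
                raise ValueError("modeling order exceeds the screened subset")
        elif self.modeling.order > L:
            raise ValueError("modeling order exceeds the SNP count")


@dataclass
class EmpiricalNull:
    """Simulated null statistics with a fitted chi-square df."""

    statistics: np.ndarray
    fitted_df: float
    n_datasets: int
    seeds: list[int] = field(default_factory=list)


def run_pipeline(
    dataset: GenotypeDataset,
    screening: ScreenConfig | None,
    modeling: ModelConfig,
    seed: int = 0,
) -> tuple[float, tuple[int, ...]]:
    """Screen, model, and return (statistic, selected SNP subset).

    The statistic is always computed on all samples of ``dataset``; for MDR a
    collapse that pools every sample into one risk group scores 0.
    """
    if screening is not None:
        if screening.method == "relieff":
            res = screen_mod.relieff(dataset, k_neighbors=screening.k_neighbors)
        else:
            res = screen_mod.turf(
                dataset,
                screening.d,
                removal_fraction=screening.removal_fraction,
                k_neighbors=screening.k_neighbors,
            )
        candidates = np.sort(screen_mod.select_top(res, screening.d))
        top_ranked = res.ranking[: modeling.order]
    else:
        candidates = np.arange(dataset.n_snps)
        top_ranked = candidates[: modeling.order]

    k = modeling.order
    if modeling.kind == "mdr_no_search":
        snps = tuple(int(i) for i in sorted(top_ranked))
        model = mdr_mod.fit_without_search(
            dataset, snps, modeling.threshold, on_degenerate="zero"
        )
        return model.chi2, model.snp_indices
    if modeling.kind == "mdr_search":
        model = mdr_mod.cv_search(
            dataset,
            k,
            n_folds=modeling.n_folds,
            threshold=modeling.threshold,
            seed=seed,
            candidates=candidates,
        )
        return model.chi2, model.snp_indices
    if modeling.kind == "lr_fixed":
        snps = tuple(int(i) for i in sorted(top_ranked))
    else:  # lr_stepwise
        snps = lr_mod.stepwise_search(dataset, candidates, k)
    stat = lr_mod.lrt(lr_mod.fit_full_interaction(dataset, snps), dataset).statistic
    return stat, snps


def simulate_null_distribution(
    config: PipelineConfig, n_datasets: int, seed: int = 0
) -> EmpiricalNull:
    """Run the configured pipeline on ``n_datasets`` fresh null datasets.

    Per-replicate child seeds are drawn from a master generator and recorded,
    so any single replicate can be reproduced in isolation.
    """
    master = np.random.default_rng(seed)
    child_seeds = [int(s) for s in master.integers(0, _SEED_BOUND, size=n_datasets)]
    stats = np.empty(n_datasets)
    for b, child in enumerate(child_seeds):
        try:
            sim = NullSimConfig(
                n_samples=config.sim.n_samples,
                n_snps=config.sim.n_snps,
                maf_low=config.sim.maf_low,
                maf_high=config.sim.maf_high,
                case_fraction=config.sim.case_fraction,
                seed=child,
            )
            ds = simulate_null_dataset(sim)
            stats[b], _ = run_pipeline(
                ds, config.screening, config.modeling, seed=child
            )
        except Exception as exc:  # noqa: BLE001 - annotate the replicate
            raise RuntimeError(f"pipeline failed on replicate {b}") from exc
    return EmpiricalNull(stats, fit_chi2_df(stats), n_datasets, child_seeds)


def fit_chi2_df(statistics, method: str = "moments") -> float:
    """Fit the degree of freedom of a chi-square reference distribution.

    ``moments`` (default) returns the sample mean, since E[chi2_df] = df.
    ``mle`` maximizes the gamma likelihood with the scale fixed at 2 and
    requires strictly positive statistics.
    """
    x = np.asarray(statistics, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two statistics")
    if not np.isfinite(x).all() or (x < 0).any():
        raise ValueError("statistics must be finite and non-negative")
    if method == "moments":
        return float(x.mean())
    if method == "mle":
        if (x == 0).any():
            raise ValueError("MLE fit requires strictly positive statistics")
        shape, _, _ = gamma_dist.fit(x, floc=0, fscale=2)
        return float(2.0 * shape)
    raise ValueError(f"unknown method {method!r}")


def chi2_pvalue(statistic: float, df: float) -> float:
    """Upper-tail probability of chi-square with (possibly non-integer) df."""
    if df <= 0:
        raise ValueError("df must be positive")
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    return float(gamma_dist.sf(statistic, df / 2.0, scale=2.0))
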