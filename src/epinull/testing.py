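"""Calibrated significance assessment for screened-and-searched models.

Screening and model search shift the null distribution of the final test
statistic far to the right of its naive theoretical reference, so referring
the statistic of a selected model to chi-square with its nominal df grossly
inflates the type-I error.  Two procedures restore calibration:

* **Whole-pipeline permutation test** — the entire screen -> model pipeline
  is re-run on each phenotype-permuted dataset, so the permuted statistics
  carry exactly the selection effects of the observed one.
* **Independent-split testing** — the samples are partitioned into three
  nearly equal parts used for screening, modeling, and testing respectively;
  the testing-stage statistic then retains its unselected null (the
  analytic chi-square for the likelihood-ratio test, the plain no-search
  collapse null for MDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lr as lr_mod
from . import mdr as mdr_mod
from .dataset import GenotypeDataset, SplitPlan, make_split
from .nulls import (
    ModelConfig,
    ScreenConfig,
    chi2_pvalue,
    fit_chi2_df,
    run_pipeline,
)
from .simulate import NullSimConfig, permute_phenotype, simulate_null_dataset

__all__ = [
    "PermutationResult",
    "SplitTestConfig",
    "SplitTestResult",
    "permutation_test",
    "split_test",
    "bonferroni",
]

_SEED_BOUND = 2**31 - 1


@dataclass
class PermutationResult:
    t_obs: float
    permuted_stats: np.ndarray
    pvalue: float
    B: int
    seed: int
    observed_snps: tuple[int, ...] = ()


@dataclass(frozen=True)
class SplitTestConfig:
    """Testing-stage options for independent-split testing.

    For MDR models the collapse statistic on the testing subset follows the
    no-search collapse null, not chi-square with an integer df; its reference
    df is either supplied (``mdr_reference_df``) or fitted on the fly from
    ``n_reference`` freshly simulated null datasets matched to the testing
    subset's size and order.
    """

    mdr_reference_df: float | None = None
    n_reference: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5


@dataclass
class ModelTestRecord:
    order: int
    snp_indices: tuple[int, ...]
    statistic: float
    reference_df: float
    pvalue_raw: float
    pvalue_corrected: float


@dataclass
class SplitTestResult:
    split: SplitPlan
    A1: np.ndarray
    A2: np.ndarray
    A3: np.ndarray
    models: list[ModelTestRecord] = field(default_factory=list)
    correction_factor: int = 1


def permutation_test(
    dataset: GenotypeDataset,
    screening: ScreenConfig | None,
    modeling: ModelConfig,
    B: int = 500,
    seed: int = 0,
    convention: str = "plug-in",
) -> PermutationResult:
    """Whole-pipeline permutation test.

    The observed statistic t_obs comes from running screening and modeling on
    the original data; each of the B permutations re-runs the *entire*
    pipeline (screening included) on the phenotype-permuted dataset.  The
    default p-value is ``#{T_b >= t_obs} / B`` ("plug-in"), which can be 0;
    ``convention="add-one"`` uses ``(count + 1) / (B + 1)`` instead.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if convention not in ("plug-in", "add-one"):
        raise ValueError(f"unknown p-value convention {convention!r}")
    master = np.random.default_rng(seed)
    child = [int(s) for s in master.integers(0, _SEED_BOUND, size=B + 1)]
    t_obs, snps = run_pipeline(dataset, screening, modeling, seed=child[0])
    perm_stats = np.empty(B)
    for b in range(B):
        try:
            permuted = permute_phenotype(dataset, seed=child[b + 1])
            perm_stats[b], _ = run_pipeline(
                permuted, screening, modeling, seed=child[b + 1]
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed on permutation {b + 1}") from exc
    count = int((perm_stats >= t_obs).sum())
    if convention == "plug-in":
        pvalue = count / B
    else:
        pvalue = (count + 1) / (B + 1)
    return PermutationResult(float(t_obs), perm_stats, pvalue, B, seed, snps)


def _mdr_reference_df(
    n_samples: int,
    case_fraction: float,
    order: int,
    cfg: SplitTestConfig,
    seed: int,
) -> float:
    """No-search collapse null df matched to the testing subset."""
    rng = np.random.default_rng(seed)
    stats = np.empty(cfg.n_reference)
    for i in range(cfg.n_reference):
        ds = simulate_null_dataset(
            NullSimConfig(
                n_samples=n_samples,
                n_snps=order,
                maf_low=cfg.maf_low,
                maf_high=cfg.maf_high,
                case_fraction=case_fraction,
                seed=int(rng.integers(0, _SEED_BOUND)),
            )
        )
        stats[i] = mdr_mod.fit_without_search(
            ds, tuple(range(order)), on_degenerate="zero"
        ).chi2
    return fit_chi2_df(stats)


def split_test(
    dataset: GenotypeDataset,
    screen_cfg: ScreenConfig,
    model_cfg: ModelConfig,
    test_cfg: SplitTestConfig | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    orders=None,
) -> SplitTestResult:
    """Screen on part 1, model on part 2, test on part 3.

    ``orders`` defaults to ``[model_cfg.order]``; one model is selected and
    tested per order, and the Bonferroni factor is the number of models
    tested.  For MDR the contingency table is re-tabulated and re-collapsed
    on the testing subset at the selected SNPs (the collapse is *not*
    transported from the modeling subset: relearning it is what keeps the
    testing statistic on its no-search null).  For LR the full-vs-null
    likelihood-ratio test with its analytic df is used.
    """
    if test_cfg is None:
        test_cfg = SplitTestConfig()
    if orders is None:
        orders = [model_cfg.order]
    plan = make_split(dataset, n_parts=3, stratified=True, seed=seed)
    d1, d2, d3 = (dataset.subset(p) for p in plan.parts)

    # stage 1: screening on D1
    if screen_cfg.method == "relieff":
        from .screen import relieff, select_top

        res = relieff(d1, k_neighbors=screen_cfg.k_neighbors)
        a1 = np.sort(select_top(res, screen_cfg.d))
    else:
        from .screen import turf

        a1 = np.sort(
            turf(
                d1,
                screen_cfg.d,
                removal_fraction=screen_cfg.removal_fraction,
                k_neighbors=screen_cfg.k_neighbors,
            ).selected
        )

    # stage 2: modeling on D2 restricted to A1
    is_mdr = model_cfg.kind.startswith("mdr")
    selected: list[tuple[int, ...]] = []
    for k in orders:
        if is_mdr:
            model = mdr_mod.cv_search(
                d2,
                k,
                n_folds=model_cfg.n_folds,
                threshold=model_cfg.threshold,
                seed=seed,
                candidates=a1,
            )
            selected.append(model.snp_indices)
        else:
            selected.append(lr_mod.stepwise_search(d2, a1, k))

    # stage 3: testing on D3
    m = len(selected)
    records: list[ModelTestRecord] = []
    sig_snps: set[int] = set()
    ref_rng = np.random.default_rng(seed)
    for k, snps in zip(orders, selected):
        if is_mdr:
            stat = mdr_mod.fit_without_search(
                d3, snps, model_cfg.threshold, on_degenerate="zero"
            ).chi2
            if test_cfg.mdr_reference_df is not None:
                ref_df = float(test_cfg.mdr_reference_df)
            else:
                ref_df = _mdr_reference_df(
                    d3.n_samples,
                    d3.n_cases / d3.n_samples,
                    k,
                    test_cfg,
                    int(ref_rng.integers(0, _SEED_BOUND)),
                )
        else:
            res = lr_mod.lrt(lr_mod.fit_full_interaction(d3, snps), d3)
            stat, ref_df = res.statistic, float(res.df)
        raw = chi2_pvalue(stat, ref_df)
        corrected = min(1.0, m * raw)
        records.append(
            ModelTestRecord(k, snps, float(stat), ref_df, raw, corrected)
        )
        if corrected <= alpha:
            sig_snps.update(snps)

    a2 = np.array(sorted({s for snps in selected for s in snps}), dtype=np.int64)
    a3 = np.array(sorted(sig_snps), dtype=np.int64)
    return SplitTestResult(plan, a1, a2, a3, records, m)


def bonferroni(raw_pvalues, m: int) -> np.ndarray:
    """Family-wise error control: each p becomes min(1, m * p)."""
    p = np.asarray(raw_pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError("correction factor smaller than the number of tests")
    return np.minimum(1.0, m * p)
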