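"""Per-SNP importance screening: ReliefF and Tuning ReliefF (TURF).

ReliefF scores each SNP by contrasting its genotype agreement between a
sample and its nearest neighbours of the same class (hits) versus the other
class (misses) under the categorical mismatch distance (0 if genotypes are
equal, 1 otherwise, summed over SNPs).  A SNP whose genotype tracks the
phenotype accumulates positive weight; an irrelevant SNP drifts around zero.
TURF iterates ReliefF, discarding the worst-scoring fraction each round, which
sharpens the ranking when many SNPs are noise.

Both are exposed as sklearn-style selectors (``fit`` / ``transform``) and as
thin functions operating on :class:`~epinull.dataset.GenotypeDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import GenotypeDataset

__all__ = [
    "ScreeningResult",
    "ReliefF",
    "TURF",
    "relieff",
    "turf",
    "select_top",
]


@dataclass
class ScreeningResult:
    """Weights, the induced ranking, and the currently selected subset.

    ``ranking`` sorts SNP indices by non-increasing weight with ties broken by
    ascending index; ``selected`` is a prefix of the ranking.
    """

    weights: np.ndarray
    ranking: np.ndarray
    selected: np.ndarray


def _rank_weights(weights: np.ndarray) -> np.ndarray:
    # stable sort of -weights => ties resolved by ascending SNP index
    return np.argsort(-weights, kind="stable")


def _relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int,
    probes: np.ndarray | None,
) -> np.ndarray:
    """Average hit/miss mismatch contrast over the probe samples.

    Distances are computed via one-hot inner products (matches = number of
    agreeing SNPs).  Neighbour ties are broken by ascending sample index
    (stable sort); the probe itself is excluded from its hits.
    """
    n, L = X.shape
    for cls in (0, 1):
        if (y == cls).sum() < k_neighbors + 1:
            raise ValueError("class too small for k_neighbors")
    if probes is None:
        probes = np.arange(n)
    onehot = np.concatenate(
        [(X == g) for g in (0, 1, 2)], axis=1
    ).astype(np.float32)
    # mismatch distance = L - #matching SNPs
    dist = (L - onehot[probes] @ onehot.T).astype(np.float64)  # (m, n)
    m = len(probes)
    # unique sort keys: integer distances plus a fractional index tie-break,
    # so argpartition reproduces "nearest, ties to the lower sample index"
    dist += np.arange(n) / (n + 1.0)
    same = y[probes, None] == y[None, :]
    dist_hit = np.where(same, dist, np.inf)
    dist_hit[np.arange(m), probes] = np.inf  # exclude self
    dist_miss = np.where(same, np.inf, dist)
    hits = np.argpartition(dist_hit, k_neighbors - 1, axis=1)[:, :k_neighbors]
    misses = np.argpartition(dist_miss, k_neighbors - 1, axis=1)[:, :k_neighbors]
    Xp = X[probes][:, None, :]
    hit_diff = (X[hits] != Xp).mean(axis=1)  # (m, L)
    miss_diff = (X[misses] != Xp).mean(axis=1)
    return (miss_diff - hit_diff).mean(axis=0)


class ReliefF(BaseEstimator, TransformerMixin):
    """ReliefF feature weighting as an sklearn selector.

    Parameters
    ----------
    n_neighbors : int
        Nearest hits and misses per probe (default 10).
    n_features_to_select : int or None
        If set, ``transform`` keeps the top-weighted features.
    n_probes : int or None
        Number of randomly sampled probe instances; ``None`` probes every
        sample (deterministic).
    random_state : int or None
        Seed for probe subsampling.
    """

    def __init__(
        self,
        n_neighbors: int = 10,
        n_features_to_select: int | None = None,
        n_probes: int | None = None,
        random_state: int | None = None,
    ):
        self.n_neighbors = n_neighbors
        self.n_features_to_select = n_features_to_select
        self.n_probes = n_probes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.int8)
        y = np.asarray(y)
        probes = None
        if self.n_probes is not None and self.n_probes < X.shape[0]:
            rng = np.random.default_rng(self.random_state)
            probes = np.sort(
                rng.choice(X.shape[0], size=self.n_probes, replace=False)
            )
        self.feature_importances_ = _relieff_weights(
            X, y, self.n_neighbors, probes
        )
        self.ranking_ = _rank_weights(self.feature_importances_)
        d = self.n_features_to_select or X.shape[1]
        self.top_indices_ = self.ranking_[:d]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "top_indices_")
        return np.asarray(X)[:, self.top_indices_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "top_indices_")
        if indices:
            return self.top_indices_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.top_indices_] = True
        return mask


class TURF(BaseEstimator, TransformerMixin):
    """Tuning ReliefF: iterated ReliefF with worst-fraction removal.

    Each round re-runs ReliefF on the surviving features and removes the
    lowest-weighted ``removal_fraction`` of them (at least one, never dropping
    below ``n_features_to_select``) until the target size is reached.  Removed
    features keep ``-inf`` weight; survivors carry their final-round weights.
    """

    def __init__(
        self,
        n_features_to_select: int = 20,
        removal_fraction: float = 0.1,
        n_neighbors: int = 10,
    ):
        self.n_features_to_select = n_features_to_select
        self.removal_fraction = removal_fraction
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        if not 0 < self.removal_fraction < 1:
            raise ValueError("removal_fraction must be in (0, 1)")
        X = np.asarray(X, dtype=np.int8)
        y = np.asarray(y)
        L = X.shape[1]
        target = self.n_features_to_select
        if target >= L:
            warnings.warn("target size >= number of features; keeping all")
            target = L
        alive = np.arange(L)
        weights = np.full(L, -np.inf)
        removed_order: list[np.ndarray] = []
        w_alive = _relieff_weights(X, y, self.n_neighbors, None)
        while len(alive) > target:
            n_remove = max(1, int(self.removal_fraction * len(alive)))
            n_remove = min(n_remove, len(alive) - target)
            order = _rank_weights(w_alive)
            drop_local = order[len(alive) - n_remove :]
            removed_order.append(alive[drop_local])
            keep_local = np.sort(order[: len(alive) - n_remove])
            alive = alive[keep_local]
            w_alive = _relieff_weights(X[:, alive], y, self.n_neighbors, None)
        weights[alive] = w_alive
        ranking = alive[_rank_weights(w_alive)]
        if removed_order:
            # later-removed features rank ahead of earlier-removed ones
            ranking = np.concatenate([ranking] + removed_order[::-1])
        self.feature_importances_ = weights
        self.ranking_ = ranking
        self.top_indices_ = ranking[:target]
        self.n_features_in_ = L
        return self

    def transform(self, X):
        check_is_fitted(self, "top_indices_")
        return np.asarray(X)[:, self.top_indices_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "top_indices_")
        if indices:
            return self.top_indices_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.top_indices_] = True
        return mask


def relieff(
    dataset: GenotypeDataset,
    k_neighbors: int = 10,
    n_probes: int | None = None,
    seed: int | None = None,
) -> ScreeningResult:
    """ReliefF weights and ranking for every SNP of the dataset."""
    est = ReliefF(
        n_neighbors=k_neighbors, n_probes=n_probes, random_state=seed
    ).fit(dataset.genotypes, dataset.phenotype)
    return ScreeningResult(
        est.feature_importances_, est.ranking_, est.ranking_.copy()
    )


def turf(
    dataset: GenotypeDataset,
    target_d: int,
    removal_fraction: float = 0.1,
    k_neighbors: int = 10,
) -> ScreeningResult:
    """TURF screening down to ``target_d`` surviving SNPs."""
    est = TURF(
        n_features_to_select=target_d,
        removal_fraction=removal_fraction,
        n_neighbors=k_neighbors,
    ).fit(dataset.genotypes, dataset.phenotype)
    return ScreeningResult(
        est.feature_importances_, est.ranking_, est.top_indices_.copy()
    )


def select_top(result: ScreeningResult, d: int) -> np.ndarray:
    """The ``d`` highest-weight SNP indices (ties to the lower index)."""
    if d > len(result.ranking):
        raise ValueError("d exceeds the number of ranked SNPs")
    return result.ranking[:d].copy()
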