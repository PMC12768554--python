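"""Representational similarity analysis between RSMs.

Two similarity matrices over a shared vocabulary are compared by Spearman
rank correlation of their off-diagonal upper triangles (second-order
similarity).  Also here: split-half reliability (the within-source upper
bound on any cross-source correlation), inter-annotator agreement for
rating data, and the permutation test asking whether RSM similarity decays
with temporal distance between decades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .embeddings import RSM

__all__ = [
    "RSAResult",
    "PermutationResult",
    "upper_triangle_values",
    "rsa_spearman",
    "split_half_reliability",
    "interannotator_agreement",
    "temporal_permutation_test",
]


@dataclass(frozen=True)
class RSAResult:
    rho: float
    n_pairs: int
    labels: tuple[str, str] = ("", "")


@dataclass(frozen=True)
class PermutationResult:
    """Observed distance-similarity correlation against its shuffle null."""

    rho_obs: float
    null_low: float
    null_high: float
    n_perm: int
    seed: int
    degenerate: bool = False

    @property
    def outside_null(self) -> bool:
        if self.degenerate:
            return False
        return not (self.null_low <= self.rho_obs <= self.null_high)


def upper_triangle_values(rsm: RSM | np.ndarray) -> np.ndarray:
    """Row-major strict upper triangle of a symmetric matrix.

    Cells (i, j) with i < j, traversed row by row; length v(v-1)/2.
    """
    matrix = rsm.matrix if isinstance(rsm, RSM) else np.asarray(rsm, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if matrix.size and np.max(np.abs(matrix - matrix.T)) > 1e-8:
        raise ValueError("matrix asymmetric beyond 1e-8")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _shared_restriction(a: RSM, b: RSM) -> tuple[RSM, RSM]:
    if a.vocabulary == b.vocabulary:
        return a, b
    shared = sorted(set(a.vocabulary) & set(b.vocabulary))
    if not shared:
        raise ValueError("RSMs share no vocabulary")
    return a.restrict(shared), b.restrict(shared)


def rsa_spearman(a: RSM, b: RSM) -> RSAResult:
    """Spearman correlation of two RSMs' upper-triangle cell vectors.

    Vocabularies are intersected (sorted) and identically ordered before
    extraction; ties get average ranks.
    """
    a, b = _shared_restriction(a, b)
    if a.n_words < 3:
        raise ValueError(
            f"need >= 3 shared words for RSA, got {a.n_words} (fewer than 3 cells)"
        )
    ua, ub = upper_triangle_values(a), upper_triangle_values(b)
    rho, _ = stats.spearmanr(ua, ub)
    return RSAResult(float(rho), len(ua), (a.source, b.source))


def split_half_reliability(
    records: pd.DataFrame,
    builder: Callable[[pd.DataFrame], RSM | pd.Series],
    n_splits: int = 5,
    seed: int = 0,
    participant_col: str = "participant_id",
) -> float:
    """Mean correlation between measures built from random participant halves.

    Participants (not records) are partitioned at random, so within-
    participant structure never leaks across halves.  ``builder`` maps a
    record subset either to an :class:`RSM` (association data) or to an
    item-indexed :class:`pandas.Series` of mean values (rating data); the
    halves are compared by Spearman correlation either way.
    """
    participants = records[participant_col].unique()
    if len(participants) < 2:
        raise ValueError("need at least 2 participants to split")
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(n_splits):
        perm = rng.permutation(participants)
        half_a = set(perm[: len(perm) // 2])
        built_a = builder(records[records[participant_col].isin(half_a)])
        built_b = builder(records[~records[participant_col].isin(half_a)])
        if isinstance(built_a, RSM):
            rhos.append(rsa_spearman(built_a, built_b).rho)
        else:
            joined = pd.concat([built_a, built_b], axis=1, join="inner", keys=["a", "b"])
            if len(joined) < 3:
                raise ValueError("halves share fewer than 3 items")
            rho, _ = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
            rhos.append(float(rho))
    return float(np.mean(rhos))


def interannotator_agreement(
    ratings: pd.DataFrame,
    grouping: str = "cohort",
    rater_col: str = "participant_id",
    item_cols: Sequence[str] = ("target", "partner"),
    value_col: str = "rating",
) -> pd.Series:
    """Mean rater-vs-rest Spearman correlation, per group.

    For each rater: correlate their ratings with the item-wise mean of all
    other raters' ratings over the items they share; raters with fewer
    than 3 shared items are skipped with a warning.
    """
    item_cols = list(item_cols)
    out = {}
    for group, gdf in ratings.groupby(grouping):
        raters = gdf[rater_col].unique()
        if len(raters) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 raters")
        sums = gdf.groupby(item_cols)[value_col].sum()
        counts = gdf.groupby(item_cols)[value_col].count()
        rhos = []
        for rater, rdf in gdf.groupby(rater_col):
            own = rdf.groupby(item_cols)[value_col].mean()
            rest_count = counts.loc[own.index] - rdf.groupby(item_cols)[value_col].count()
            valid = rest_count > 0
            own = own[valid]
            if len(own) < 3:
                warnings.warn(f"rater {rater!r} has fewer than 3 shared items; skipped")
                continue
            rest_mean = (
                sums.loc[own.index] - rdf.groupby(item_cols)[value_col].sum().loc[own.index]
            ) / rest_count[valid]
            rho, _ = stats.spearmanr(own, rest_mean)
            rhos.append(float(rho))
        if not rhos:
            raise ValueError(f"group {group!r} has no rater with >= 3 shared items")
        out[group] = float(np.mean(rhos))
    return pd.Series(out, name="agreement")


def temporal_permutation_test(
    decade_rsms: Sequence[tuple[int, RSM]],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Does RSM similarity track temporal distance between decades?

    The observed statistic is the Spearman correlation between
    ``|decade_i - decade_j|`` and the representational divergence (the
    negative of ``rsa_spearman(RSM_i, RSM_j)``) over all decade pairs, so
    similarity decaying with distance yields a positive rho.  The null
    shuffles decade labels and recomputes; the central 95% interval of
    the null is reported.  If the pairwise RSA values are constant the
    statistic is undefined and the result is flagged degenerate.
    """
    if len(decade_rsms) < 3:
        raise ValueError("need at least 3 decades")
    if n_perm < 100:
        warnings.warn("n_perm < 100: null interval will be unstable")
    years = np.array([d for d, _ in decade_rsms], dtype=float)
    rsms = [r for _, r in decade_rsms]
    pairs = list(combinations(range(len(rsms)), 2))
    sims = np.array([rsa_spearman(rsms[i], rsms[j]).rho for i, j in pairs])
    ii = np.array([i for i, _ in pairs])
    jj = np.array([j for _, j in pairs])

    if np.allclose(sims, sims[0]):
        return PermutationResult(float("nan"), float("nan"), float("nan"),
                                 n_perm, seed, degenerate=True)

    def distance_corr(labels: np.ndarray) -> float:
        dist = np.abs(labels[ii] - labels[jj])
        rho, _ = stats.spearmanr(dist, -sims)
        return float(rho)

    rho_obs = distance_corr(years)
    rng = np.random.default_rng(seed)
    null = np.array([distance_corr(rng.permutation(years)) for _ in range(n_perm)])
    null = null[~np.isnan(null)]
    low, high = np.percentile(null, [2.5, 97.5])
    return PermutationResult(rho_obs, float(low), float(high), n_perm, seed)
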