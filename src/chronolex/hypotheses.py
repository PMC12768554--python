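"""Lifespan-weighting hypotheses over decade RSMs.

A cohort's semantic space is modelled as a convex combination of the
decade-level corpus RSMs it has experienced.  Three weighting schemes are
compared: geometric decay favoring the earliest decades (weights
base^x with x counting up from the earliest decade), a uniform mean, and
geometric decay favoring the most recent decades.  The combination that
best correlates (RSA) with a behavioral RSM indicates how the cohort
integrates a lifetime of changing word usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import RSM
from .rsa import rsa_spearman

__all__ = [
    "HYPOTHESES",
    "HypothesisWeights",
    "CohortExposure",
    "compute_weights",
    "weighted_mean_rsm",
    "hypothesis_rsa",
    "HypothesisRSAResult",
    "simulate_hypothesis_pattern",
]

HYPOTHESES = ("early", "uniform", "recent")


@dataclass(frozen=True)
class HypothesisWeights:
    """Normalized decade weights under one weighting hypothesis."""

    hypothesis: str
    decades: tuple[int, ...]
    weights: np.ndarray
    base: float = 0.5

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        if len(w) != len(self.decades):
            raise ValueError("one weight per decade required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        diffs = np.diff(w)
        if self.hypothesis == "early" and np.any(diffs > 1e-12):
            raise ValueError("early weights must be non-increasing over time")
        if self.hypothesis == "recent" and np.any(diffs < -1e-12):
            raise ValueError("recent weights must be non-decreasing over time")
        if self.hypothesis == "uniform" and np.any(np.abs(w - w[0]) > 1e-12):
            raise ValueError("uniform weights must be constant")


@dataclass(frozen=True)
class CohortExposure:
    """The contiguous decades a cohort has lived through."""

    label: str
    experienced_decades: tuple[int, ...]

    def __post_init__(self) -> None:
        d = tuple(self.experienced_decades)
        object.__setattr__(self, "experienced_decades", d)
        if not d:
            raise ValueError("experienced_decades must be non-empty")
        steps = np.diff(d)
        if len(d) > 1 and (np.any(steps <= 0) or np.any(steps != steps[0])):
            raise ValueError("experienced_decades must be contiguous and increasing")


def compute_weights(
    hypothesis: str, decades: Sequence[int], base: float = 0.5
) -> HypothesisWeights:
    """Geometric decade weights, normalized.

    Unnormalized weight of decade index i (0 = earliest): ``base**i`` for
    "early", ``base**(n-1-i)`` for "recent", 1 for "uniform" — the favored
    end always starts at base^0 = 1, and normalization makes any common
    exponent offset irrelevant.
    """
    if not decades:
        raise ValueError("decades must be non-empty")
    if not 0.0 < base < 1.0:
        raise ValueError(f"base must be in (0, 1), got {base}")
    n = len(decades)
    idx = np.arange(n, dtype=float)
    if hypothesis == "early":
        raw = base ** idx
    elif hypothesis == "recent":
        raw = base ** (n - 1 - idx)
    elif hypothesis == "uniform":
        raw = np.ones(n)
    else:
        raise ValueError(f"hypothesis must be one of {HYPOTHESES}, got {hypothesis!r}")
    return HypothesisWeights(hypothesis, tuple(decades), raw / raw.sum(), base)


def weighted_mean_rsm(rsms: Sequence[RSM], w: HypothesisWeights) -> RSM:
    """Cellwise convex combination of RSMs sharing one vocabulary order."""
    if len(rsms) != len(w.weights):
        raise ValueError(f"{len(rsms)} RSMs but {len(w.weights)} weights")
    vocab = rsms[0].vocabulary
    for r in rsms[1:]:
        if r.vocabulary != vocab:
            raise ValueError("all RSMs must share an identical vocabulary order")
    matrix = np.tensordot(w.weights, np.stack([r.matrix for r in rsms]), axes=1)
    return RSM(list(vocab), matrix, source=f"hypothesis:{w.hypothesis}")


@dataclass(frozen=True)
class HypothesisRSAResult:
    """RSA of a behavioral RSM against the three hypothesis RSMs."""

    table: pd.DataFrame  # columns: hypothesis, rho
    best: tuple[str, ...]  # all argmax labels; >1 entry means a tie

    @property
    def is_tie(self) -> bool:
        return len(self.best) > 1


def hypothesis_rsa(
    behavior: RSM,
    decade_rsms: Sequence[tuple[int, RSM]],
    exposures: CohortExposure | None = None,
    base: float = 0.5,
) -> HypothesisRSAResult:
    """Which weighting hypothesis best explains a behavioral RSM?

    Builds the early/uniform/recent combinations of the decade RSMs
    (restricted to the cohort's experienced decades when ``exposures`` is
    given; by default all decades are combined for every cohort, mirroring
    the corpus-vs-association analysis) and scores each by RSA.  Exact
    ties are reported as multiple best labels, never broken silently.
    """
    if len(decade_rsms) < 2:
        raise ValueError("need at least 2 decades")
    if exposures is not None:
        wanted = set(exposures.experienced_decades)
        decade_rsms = [(d, r) for d, r in decade_rsms if d in wanted]
        if len(decade_rsms) != len(wanted):
            have = {d for d, _ in decade_rsms}
            raise ValueError(f"missing decade RSMs for {sorted(wanted - have)}")
    decades = [d for d, _ in decade_rsms]
    rsms = [r for _, r in decade_rsms]
    rows = []
    for hyp in HYPOTHESES:
        combo = weighted_mean_rsm(rsms, compute_weights(hyp, decades, base))
        rows.append({"hypothesis": hyp, "rho": rsa_spearman(behavior, combo).rho})
    table = pd.DataFrame(rows)
    best_rho = table["rho"].max()
    best = tuple(table.loc[table["rho"] >= best_rho - 1e-12, "hypothesis"])
    return HypothesisRSAResult(table, best)


def _symmetric_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    noise = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    noise[iu] = rng.normal(0.0, sd, size=len(iu[0]))
    return noise + noise.T


def simulate_hypothesis_pattern(
    decade_rsms: Sequence[tuple[int, RSM]],
    cohorts: Sequence[CohortExposure],
    hypothesis: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    base: float = 0.5,
) -> pd.DataFrame:
    """Cohort-by-decade RSA pattern implied by one weighting hypothesis.

    Each cohort's semantic RSM is the hypothesis-weighted mean over its
    experienced decades plus symmetric cellwise Gaussian noise (diagonal
    reset to 1); the output correlates each cohort RSM with every single
    decade RSM — the simulated analogue of the cohort-by-decade heat-map
    one would expect under that hypothesis.
    """
    rng = np.random.default_rng(seed)
    axis = [d for d, _ in decade_rsms]
    table = {}
    for cohort in cohorts:
        if not set(cohort.experienced_decades) <= set(axis):
            raise ValueError(
                f"cohort {cohort.label!r} experienced decades outside the axis"
            )
        sub = [(d, r) for d, r in decade_rsms if d in set(cohort.experienced_decades)]
        w = compute_weights(hypothesis, [d for d, _ in sub], base)
        combo = weighted_mean_rsm([r for _, r in sub], w)
        matrix = combo.matrix + _symmetric_noise(combo.n_words, noise_sd, rng)
        np.fill_diagonal(matrix, 1.0)
        noisy = RSM(combo.vocabulary, matrix, source=f"cohort:{cohort.label}")
        table[cohort.label] = {
            d: rsa_spearman(noisy, r).rho for d, r in decade_rsms
        }
    return pd.DataFrame(table).T.loc[[c.label for c in cohorts], axis]
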