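"""Stimulus construction for the changed/unchanged relatedness experiment.

Target words are classified as semantically changed or unchanged by the
cosine between their aligned vectors in an early and a late decade
(default 1950 vs 1990, threshold 0.35, strict inequalities — a word
landing exactly on the threshold is left unassigned).  Each target is
paired with its nearest neighbors from each decade plus randomly sampled
non-neighbors, the pairs are dealt into counterbalance lists (25 targets,
75 pairs, 12-or-13 changed targets per list), and rating tables are
cleaned: catch-trial/duration exclusion, duplicate-pair removal, and
subsampling to an exact number of ratings per cohort per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import AlignedSeries, DecadeEmbeddings, cosine_rsm, self_similarity

__all__ = [
    "TargetWord",
    "StimulusSet",
    "classify_change",
    "select_targets",
    "nearest_neighbors",
    "sample_non_neighbors",
    "build_stimulus_set",
    "build_counterbalance_lists",
    "clean_ratings",
    "dedupe_pairs",
    "subsample_ratings",
]

PAIR_TYPES = ("n1950", "n1990", "non_neighbor")


@dataclass(frozen=True)
class TargetWord:
    word: str
    change_status: str  # "changed" | "unchanged"
    self_sim: float
    log_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.change_status not in ("changed", "unchanged"):
            raise ValueError(f"bad change_status {self.change_status!r}")


@dataclass
class StimulusSet:
    """Targets plus their per-type partner lists (before list assembly)."""

    targets: list[TargetWord]
    pairs: dict[str, dict[str, list[str]]]  # word -> pair_type -> partners

    def to_frame(self) -> pd.DataFrame:
        status = {t.word: t.change_status for t in self.targets}
        rows = [
            {"target": w, "partner": p, "pair_type": ptype, "change_status": status[w]}
            for w, by_type in self.pairs.items()
            for ptype, partners in by_type.items()
            for p in partners
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Change classification and neighbor selection
# ---------------------------------------------------------------------------

def classify_change(
    series: AlignedSeries,
    words: list[str],
    t1: int = 1950,
    t2: int = 1990,
    threshold: float = 0.35,
) -> list[TargetWord]:
    """Classify words by their t1-t2 self-cosine against a threshold.

    Strictly below the threshold -> changed; strictly above -> unchanged;
    exactly at the threshold -> excluded with a warning (the boundary is
    deliberately unassigned).
    """
    if not series.aligned:
        raise ValueError("series is unaligned; align first (align_series)")
    out = []
    for word in words:
        sim = self_similarity(series, word, t1, t2)
        if sim < threshold:
            out.append(TargetWord(word, "changed", sim))
        elif sim > threshold:
            out.append(TargetWord(word, "unchanged", sim))
        else:
            warnings.warn(f"{word!r} sits exactly at threshold {threshold}; unassigned")
    return out


def select_targets(
    classified: list[TargetWord],
    n_changed: int = 150,
    n_unchanged: int = 150,
    freq_range: tuple[float, float] | None = None,
) -> list[TargetWord]:
    """Pick the most-changed and most-stable targets.

    Changed candidates are ranked by ascending self-similarity (most
    changed first), unchanged by descending (most stable first).  An
    optional (min, max) log-frequency window filters candidates whose
    ``log_frequency`` is set.
    """
    pool = classified
    if freq_range is not None:
        lo, hi = freq_range
        pool = [
            t for t in pool
            if t.log_frequency is None or lo <= t.log_frequency <= hi
        ]
    changed = sorted((t for t in pool if t.change_status == "changed"),
                     key=lambda t: (t.self_sim, t.word))
    unchanged = sorted((t for t in pool if t.change_status == "unchanged"),
                       key=lambda t: (-t.self_sim, t.word))
    if len(changed) < n_changed or len(unchanged) < n_unchanged:
        raise ValueError(
            f"not enough candidates: {len(changed)} changed (need {n_changed}), "
            f"{len(unchanged)} unchanged (need {n_unchanged})"
        )
    return changed[:n_changed] + unchanged[:n_unchanged]


def nearest_neighbors(emb: DecadeEmbeddings, word: str, k: int = 10) -> list[str]:
    """Top-k cosine neighbors of ``word`` (itself excluded).

    Exact ties are broken lexicographically so the selection is
    deterministic across runs.
    """
    if word not in emb:
        raise KeyError(f"{word!r} not in vocabulary")
    if k >= len(emb.vocabulary):
        raise ValueError(f"k={k} >= vocabulary size {len(emb.vocabulary)}")
    zero = emb.zero_norm_words
    if zero:
        raise ValueError(f"zero-norm vectors (cosine undefined): {zero}")
    normed = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    idx = emb.vocabulary.index(word)
    sims = normed @ normed[idx]
    return _neighbors_from_sims(sims, list(emb.vocabulary), idx, k)


def _neighbors_from_sims(sims: np.ndarray, vocab: list[str], word_idx: int, k: int) -> list[str]:
    order = sorted(
        ((float(-sims[i]), vocab[i]) for i in range(len(vocab)) if i != word_idx),
    )
    return [w for _, w in order[:k]]


def sample_non_neighbors(
    vocab: list[str],
    word: str,
    excluded: set[str],
    k: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Uniform seeded sample from the complement of a word's neighbor set."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    complement = sorted(set(vocab) - set(excluded) - {word})
    if len(complement) < k:
        raise ValueError(
            f"complement of {word!r} has {len(complement)} words, need {k}"
        )
    return list(rng.choice(complement, size=k, replace=False))


def build_stimulus_set(
    series: AlignedSeries,
    t1: int = 1950,
    t2: int = 1990,
    threshold: float = 0.35,
    n_changed: int = 150,
    n_unchanged: int = 150,
    k_neighbors: int = 10,
    k_non_neighbors: int = 10,
    seed: int = 0,
    candidate_words: list[str] | None = None,
) -> StimulusSet:
    """Run the full target-and-pair construction over an aligned series.

    Per target: ``k_neighbors`` nearest neighbors from each of the two
    decades and ``k_non_neighbors`` words sampled from outside the union
    of those neighbor sets ("exclusion depth" = the selected neighbors
    only).
    """
    words = candidate_words if candidate_words is not None else series.vocabulary
    classified = classify_change(series, words, t1, t2, threshold)
    targets = select_targets(classified, n_changed, n_unchanged)
    rng = np.random.default_rng(seed)

    emb1, emb2 = series.get(t1), series.get(t2)
    rsm1, rsm2 = cosine_rsm(emb1), cosine_rsm(emb2)
    vocab = list(series.vocabulary)
    index = {w: i for i, w in enumerate(vocab)}

    pairs: dict[str, dict[str, list[str]]] = {}
    for t in targets:
        i = index[t.word]
        n50 = _neighbors_from_sims(rsm1.matrix[i], vocab, i, k_neighbors)
        n90 = _neighbors_from_sims(rsm2.matrix[i], vocab, i, k_neighbors)
        non = sample_non_neighbors(
            vocab, t.word, set(n50) | set(n90), k_non_neighbors, rng
        )
        pairs[t.word] = {"n1950": n50, "n1990": n90, "non_neighbor": non}
    return StimulusSet(targets, pairs)


# ---------------------------------------------------------------------------
# Counterbalance lists
# ---------------------------------------------------------------------------

def _deal_appearances(
    words: list[str], per_list: list[int], rng: np.random.Generator
) -> list[list[str]]:
    """Deal each word into lists, appearances balanced, no repeats per list."""
    appearances = sum(per_list) // len(words)
    pool: list[str] = []
    for _ in range(appearances):
        block = list(words)
        rng.shuffle(block)
        pool.extend(block)
    lists: list[list[str]] = []
    start = 0
    for count in per_list:
        lists.append(pool[start : start + count])
        start += count
    # repair duplicates within a list by swapping with another list that
    # holds neither word
    for li, lst in enumerate(lists):
        seen = set()
        for pos, word in enumerate(lst):
            if word not in seen:
                seen.add(word)
                continue
            swapped = False
            for lj in range(len(lists)):
                if lj == li:
                    continue
                other = lists[lj]
                if word in other:
                    continue
                for pos2, cand in enumerate(other):
                    if cand != word and cand not in lst:
                        lst[pos], other[pos2] = cand, word
                        seen.add(cand)
                        swapped = True
                        break
                if swapped:
                    break
            if not swapped:
                raise RuntimeError("could not balance list assignment")
    return lists


def build_counterbalance_lists(
    stimulus_set: StimulusSet, n_lists: int = 120, seed: int = 0
) -> pd.DataFrame:
    """Deal targets and their pairs into counterbalance lists.

    Each list holds ``total/n_appearances`` targets split as evenly as
    possible between changed and unchanged (12/13 or 13/12 in the default
    design), each target contributing one pair of each type, i.e. 75 pairs
    for 25 targets.  A target's j-th appearance across lists uses its j-th
    partner of each type, so after all lists every partner of every target
    is covered at least once.
    """
    status = {t.word: t.change_status for t in stimulus_set.targets}
    changed = [t.word for t in stimulus_set.targets if t.change_status == "changed"]
    unchanged = [t.word for t in stimulus_set.targets if t.change_status == "unchanged"]
    k = min(
        len(v) for by_type in stimulus_set.pairs.values() for v in by_type.values()
    )
    n_targets = len(changed) + len(unchanged)
    # each target appears k times overall (one partner of each type per
    # appearance), so total slots = n_targets * k, dealt evenly into lists
    if (n_targets * k) % n_lists:
        raise ValueError(
            f"cannot cover {n_targets} targets x {k} appearances evenly with "
            f"{n_lists} lists ({(n_targets * k) % n_lists} slots left over)"
        )
    per_list_total = n_targets * k // n_lists
    ch_slots_total = len(changed) * k
    base_ch = ch_slots_total // n_lists
    n_high = ch_slots_total - base_ch * n_lists  # lists with base_ch + 1 changed
    rng = np.random.default_rng(seed)
    ch_counts = np.array([base_ch + 1] * n_high + [base_ch] * (n_lists - n_high))
    rng.shuffle(ch_counts)
    un_counts = per_list_total - ch_counts
    if np.any(un_counts < 0) or un_counts.sum() != len(unchanged) * k:
        raise ValueError("unchanged-target slots do not balance; adjust n_lists")

    ch_lists = _deal_appearances(changed, list(ch_counts), rng)
    un_lists = _deal_appearances(unchanged, list(un_counts), rng)

    appearance_counter: dict[str, int] = {w: 0 for w in status}
    rows = []
    for list_id in range(n_lists):
        for word in [*ch_lists[list_id], *un_lists[list_id]]:
            j = appearance_counter[word]
            appearance_counter[word] += 1
            by_type = stimulus_set.pairs[word]
            for ptype in PAIR_TYPES:
                rows.append(
                    {
                        "list_id": list_id,
                        "target": word,
                        "partner": by_type[ptype][j % len(by_type[ptype])],
                        "pair_type": ptype,
                        "change_status": status[word],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rating-table hygiene
# ---------------------------------------------------------------------------

def clean_ratings(
    records: pd.DataFrame, min_catch: int = 5, min_minutes: float = 4.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep ratings from participants who passed the attention checks.

    A participant survives with ``catch_score >= min_catch`` (default: all
    5 catch trials correct) and ``duration`` strictly greater than
    ``min_minutes``.  Returns the filtered records and per-filter
    participant exclusion counts.
    """
    per_part = records.groupby("participant_id").agg(
        catch_score=("catch_score", "min"), duration=("duration", "min")
    )
    fail_catch = per_part["catch_score"] < min_catch
    fail_time = per_part["duration"] <= min_minutes
    keep = per_part.index[~(fail_catch | fail_time)]
    report = {
        "excluded_catch": int(fail_catch.sum()),
        "excluded_duration": int((fail_time & ~fail_catch).sum()),
        "kept_participants": len(keep),
    }
    return records[records["participant_id"].isin(keep)].copy(), report


def _canonical_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def dedupe_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse ratings of duplicated unordered pairs to one pair key.

    When a target's two neighbor lists share a partner the same unordered
    pair is rated under two pair types; the first-listed pair type (in
    n1950, n1990, non_neighbor precedence) wins, and the losing type's
    rating rows are dropped.
    """
    records = records.copy()
    keys = [
        _canonical_key(t, p) for t, p in zip(records["target"], records["partner"])
    ]
    records["_key"] = keys
    precedence = {p: i for i, p in enumerate(PAIR_TYPES)}
    winner = (
        records.assign(_prec=records["pair_type"].map(precedence))
        .groupby("_key")["_prec"]
        .min()
    )
    keep = records["pair_type"].map(precedence).to_numpy() == winner.loc[records["_key"]].to_numpy()
    return records[keep].drop(columns=["_key"]).reset_index(drop=True)


def subsample_ratings(
    records: pd.DataFrame,
    per_cohort: int = 5,
    seed: int = 0,
    on_short: str = "error",
) -> pd.DataFrame:
    """Subsample to exactly ``per_cohort`` ratings per (pair, cohort).

    Pairs with too few ratings in either cohort either raise (listing the
    offenders) or are dropped with a warning (``on_short="drop"``).
    """
    if on_short not in ("error", "drop"):
        raise ValueError("on_short must be 'error' or 'drop'")
    rng = np.random.default_rng(seed)
    counts = records.groupby(["target", "partner", "cohort"]).size().unstack(fill_value=0)
    short = counts[(counts < per_cohort).any(axis=1)]
    keep_records = records
    if len(short):
        if on_short == "error":
            raise ValueError(
                f"{len(short)} pairs have < {per_cohort} ratings in some cohort: "
                f"{list(short.index[:5])}"
            )
        warnings.warn(f"dropping {len(short)} under-sampled pairs")
        bad = set(short.index)
        mask = [
            (t, p) not in bad for t, p in zip(records["target"], records["partner"])
        ]
        keep_records = records[mask]
    sampled = keep_records.groupby(
        ["target", "partner", "cohort"], group_keys=False
    ).sample(n=per_cohort, random_state=rng)
    return sampled.reset_index(drop=True)
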