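"""Cohort association networks and PPMI / random-walk similarity.

Free-association data (a participant of known age produces up to three
responses to each cue word) is aggregated per age cohort into a weighted
directed cue-to-response count matrix.  Similarity between words is then
derived with the standard association-network chain: PPMI weighting of the
counts, row normalization into a transition matrix, a decaying (Katz)
random walk (I - aP)^-1 adding exponentially discounted indirect paths, a
second PPMI pass, renormalization to conditional probabilities, and cosine
similarity between the resulting row vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import RSM

__all__ = [
    "CohortSpec",
    "AssocNetwork",
    "WalkParams",
    "read_association_csv",
    "build_network",
    "filter_cues",
    "ppmi_transform",
    "row_normalize",
    "katz_walk",
    "assoc_similarity",
]

RECORD_COLUMNS = ["participant_id", "age", "cue", "response", "position"]


@dataclass(frozen=True)
class CohortSpec:
    """Half-open age window [min_age, max_age) defining one cohort."""

    label: str
    min_age: int
    max_age: int

    def __post_init__(self) -> None:
        if not self.min_age < self.max_age:
            raise ValueError(f"min_age must be < max_age ({self.min_age}, {self.max_age})")

    def contains(self, age) -> bool:
        return (self.min_age <= age) & (age < self.max_age)


@dataclass
class AssocNetwork:
    """Directed cue-to-response count matrix over an ordered vocabulary."""

    vocabulary: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        v = len(self.vocabulary)
        if self.counts.shape != (v, v):
            raise ValueError(f"counts shape {self.counts.shape} != ({v}, {v})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def responses_per_cue(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)


@dataclass(frozen=True)
class WalkParams:
    """Decay parameter for the Katz walk.

    alpha : geometric decay of indirect-path contributions, in (0, 1).
        Row-stochastic transition matrices have spectral radius <= 1, so
        any alpha < 1 keeps the walk series summable.  Default 0.75; the
        right value for real association data is an empirical question, so
        treat this as a knob rather than a constant.
    max_terms : truncation order used by the series-sum oracle in tests.
    """

    alpha: float = 0.75
    max_terms: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------

def read_association_csv(path: str | Path, fmt: str = "auto") -> pd.DataFrame:
    """Read association records from CSV in wide (SWOW-style) or long format.

    Wide: columns ``participant_id, age, cue, R1, R2, R3`` — missing
    responses as empty cells.  Long: ``participant_id, age, cue, response,
    position``.  Returns a long-format DataFrame with RECORD_COLUMNS.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if fmt == "auto":
        fmt = "wide" if {"R1", "R2", "R3"} & cols else "long"
    if fmt == "wide":
        missing = {"participant_id", "age", "cue"} - cols
        if missing:
            raise ValueError(f"wide association CSV missing columns: {sorted(missing)}")
        resp_cols = [c for c in ("R1", "R2", "R3") if c in cols]
        long = df.melt(
            id_vars=["participant_id", "age", "cue"],
            value_vars=resp_cols,
            var_name="position",
            value_name="response",
        )
        long = long.dropna(subset=["response"])
        long = long[long["response"].astype(str).str.strip() != ""]
        long["position"] = long["position"].str.lstrip("R").astype(int)
        return long[RECORD_COLUMNS].reset_index(drop=True)
    missing = set(RECORD_COLUMNS) - cols
    if missing:
        raise ValueError(f"long association CSV missing columns: {sorted(missing)}")
    return df[RECORD_COLUMNS].copy()


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"association records missing columns: {sorted(missing)}")
    bad_pos = ~records["position"].isin([1, 2, 3])
    if bad_pos.any():
        raise ValueError("response position must be in {1, 2, 3}")
    if (records["age"] < 0).any():
        raise ValueError("ages must be non-negative")
    return records


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(records: pd.DataFrame, cohort: CohortSpec | None = None) -> AssocNetwork:
    """Aggregate cue-response records (optionally one cohort) into counts.

    ``counts[i, j]`` = number of in-cohort records with cue i and response
    j; all response positions weigh equally.  Vocabulary is the sorted
    union of cues and responses appearing in the retained records.
    """
    records = _validate_records(records)
    if cohort is not None:
        records = records[cohort.contains(records["age"])]
    if len(records) == 0:
        return AssocNetwork([], np.zeros((0, 0), dtype=int))
    cues = records["cue"].astype(str)
    resps = records["response"].astype(str)
    vocab = sorted(set(cues) | set(resps))
    index = {w: i for i, w in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)), dtype=int)
    np.add.at(counts, (cues.map(index).to_numpy(), resps.map(index).to_numpy()), 1)
    return AssocNetwork(vocab, counts)


def filter_cues(net: AssocNetwork, min_responses: int = 15) -> AssocNetwork:
    """Drop cues with fewer than ``min_responses`` responses (inclusive keep).

    Applied once, not iterated: surviving cues keep all their responses
    even if some response words lost their own cue rows.  The vocabulary is
    recomputed as surviving cues plus the words they still point to.
    """
    if min_responses < 1:
        raise ValueError("min_responses must be >= 1")
    keep_rows = net.responses_per_cue >= min_responses
    if not keep_rows.any():
        raise ValueError(f"no cue has >= {min_responses} responses")
    vocab_arr = np.asarray(net.vocabulary, dtype=object)
    kept_cues = set(vocab_arr[keep_rows])
    sub = net.counts[keep_rows]
    kept_resps = set(vocab_arr[sub.sum(axis=0) > 0])
    new_vocab = sorted(kept_cues | kept_resps)
    index = {w: i for i, w in enumerate(net.vocabulary)}
    sel = [index[w] for w in new_vocab]
    counts = net.counts[np.ix_(sel, sel)].copy()
    # non-cue rows (response-only words) stay, but as zero out-rows
    is_cue = np.array([w in kept_cues for w in new_vocab])
    counts[~is_cue] = 0
    return AssocNetwork(new_vocab, counts)


# ---------------------------------------------------------------------------
# Similarity chain
# ---------------------------------------------------------------------------

def ppmi_transform(m: np.ndarray) -> np.ndarray:
    """Positive pointwise mutual information, base-2 logs.

    ``out[i, j] = max(0, log2(p_ij / (p_i * p_j)))`` with all probabilities
    taken from the matrix's own marginals; zero cells stay exactly zero.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("PPMI input must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("PPMI input has zero grand total")
    row = m.sum(axis=1, keepdims=True) / total
    col = m.sum(axis=0, keepdims=True) / total
    out = np.zeros_like(m)
    nz = m > 0
    expected = (row @ col) * total
    out[nz] = np.log2(m[nz] / expected[nz])
    np.maximum(out, 0.0, out=out)
    return out


def row_normalize(m: np.ndarray) -> np.ndarray:
    """Scale each row to sum to one; all-zero rows stay zero (warned)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("row_normalize input must be non-negative")
    sums = m.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(sums[:, 0] == 0)
    if zero_rows.size:
        warnings.warn(f"{zero_rows.size} all-zero rows left unnormalized")
    out = np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
    return out


def katz_walk(P: np.ndarray, params: WalkParams = WalkParams()) -> np.ndarray:
    """Decayed walk sum over transition matrix P, in closed form.

    Sums ``alpha^k P^k`` over k >= 0, i.e. ``(I - alpha P)^{-1}``: direct
    links plus exponentially discounted indirect paths.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    try:
        K = np.linalg.solve(np.eye(n) - params.alpha * P, np.eye(n))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"(I - alpha P) is singular at alpha={params.alpha}; try a smaller alpha"
        ) from err
    return K


def assoc_similarity(net: AssocNetwork, params: WalkParams = WalkParams()) -> RSM:
    """Full association-similarity chain: counts to cosine RSM.

    Stages: PPMI(counts) -> row-normalize -> Katz walk -> PPMI ->
    row-normalize (conditional probabilities) -> cosine between rows.
    Words with an all-zero final row (response-only words) get similarity
    0 to everything, diagonal 1.
    """
    if net.n_words == 0:
        raise ValueError("empty network")
    stage = ppmi_transform(net.counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage = row_normalize(stage)
    stage = katz_walk(stage, params)
    stage = ppmi_transform(stage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage = row_normalize(stage)
    norms = np.linalg.norm(stage, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} words have empty association profiles; "
            "their similarities are set to 0"
        )
    safe = np.where(zero, 1.0, norms)
    unit = stage / safe[:, None]
    matrix = unit @ unit.T
    matrix = np.clip((matrix + matrix.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    return RSM(list(net.vocabulary), matrix, source="cohort association")
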