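"""Per-decade word embeddings, Procrustes alignment, and cosine RSMs.

Diachronic semantic spaces are represented as one embedding matrix per
decade (word2vec text format on disk).  Decades trained independently live
in arbitrary rotations of each other; an orthogonal Procrustes map onto a
common reference decade makes word vectors directly comparable across time,
so that the cosine between a word's 1950s and 1990s vectors measures how
much its meaning changed.  Decade-level representational similarity
matrices (RSMs) — word-by-word cosine similarity — are the currency every
downstream comparison uses.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "DecadeEmbeddings",
    "AlignedSeries",
    "RSM",
    "load_word2vec_text",
    "save_word2vec_text",
    "intersect_vocabulary",
    "procrustes_align",
    "align_series",
    "cosine_rsm",
    "self_similarity",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class DecadeEmbeddings:
    """Word vectors for one decade.

    Parameters
    ----------
    decade : int
        Year label, e.g. ``1950``.
    vocabulary : list of str
        Ordered, duplicate-free word list; one row of ``vectors`` per word.
    vectors : ndarray of shape (n_words, dim)
        Raw vectors as read from disk; never re-normalized on load
        (normalization happens inside cosine computations).
    """

    decade: int
    vocabulary: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError(
                f"vocabulary length {len(self.vocabulary)} does not match "
                f"row count {self.vectors.shape[0]}"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            dups = pd.Series(self.vocabulary)
            dups = sorted(dups[dups.duplicated()].unique())
            raise ValueError(f"duplicate words in vocabulary: {dups}")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def zero_norm_words(self) -> list[str]:
        """Words whose vector has zero norm (cosine undefined for these)."""
        norms = np.linalg.norm(self.vectors, axis=1)
        return [w for w, nrm in zip(self.vocabulary, norms) if nrm == 0.0]

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word {word!r} not in decade {self.decade}") from None

    def restrict(self, words: list[str]) -> "DecadeEmbeddings":
        """Return a copy restricted to ``words`` in the given order."""
        missing = [w for w in words if w not in self._index]
        if missing:
            raise KeyError(f"words not in decade {self.decade}: {missing[:5]}")
        rows = [self._index[w] for w in words]
        return DecadeEmbeddings(self.decade, list(words), self.vectors[rows])


@dataclass
class AlignedSeries:
    """An ordered series of decade embeddings over one shared vocabulary."""

    decades: list[DecadeEmbeddings]
    aligned: bool = False
    reference_decade: int | None = None

    def __post_init__(self) -> None:
        if not self.decades:
            raise ValueError("series must contain at least one decade")
        vocab = self.decades[0].vocabulary
        dim = self.decades[0].dim
        for emb in self.decades[1:]:
            if emb.vocabulary != vocab:
                raise ValueError("all decades must share an identical vocabulary order")
            if emb.dim != dim:
                raise ValueError("all decades must share one embedding dimension")

    @property
    def vocabulary(self) -> list[str]:
        return self.decades[0].vocabulary

    @property
    def decade_labels(self) -> list[int]:
        return [e.decade for e in self.decades]

    def get(self, decade: int) -> DecadeEmbeddings:
        for emb in self.decades:
            if emb.decade == decade:
                return emb
        raise KeyError(f"decade {decade} not in series {self.decade_labels}")


@dataclass
class RSM:
    """Representational similarity matrix over an ordered vocabulary.

    ``source`` tags provenance: a corpus decade (``"decade:1950"``), a
    cohort association network, cohort ratings, or a weighting hypothesis.
    """

    vocabulary: list[str]
    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        v = len(self.vocabulary)
        if self.matrix.shape != (v, v):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({v}, {v})")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if v else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix asymmetric beyond tolerance: {asym:.3g}")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def restrict(self, words: list[str]) -> "RSM":
        idx = [self._index[w] for w in words]
        return RSM(list(words), self.matrix[np.ix_(idx, idx)], self.source)

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.vocabulary, columns=self.vocabulary).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "") -> "RSM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), source)

    def save(self, path: str | Path) -> None:
        """Write matrix as ``.npy`` with a JSON sidecar (vocabulary, source)."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.matrix)
        sidecar = {"vocabulary": self.vocabulary, "source": self.source}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "RSM":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        matrix = np.load(path.with_suffix(".npy"))
        return cls(sidecar["vocabulary"], matrix, sidecar.get("source", ""))


# ---------------------------------------------------------------------------
# word2vec text I/O
# ---------------------------------------------------------------------------

def _infer_decade(path: Path) -> int | None:
    m = re.search(r"(1[6-9]\d\d|20\d\d)", path.stem)
    return int(m.group(1)) if m else None


def load_word2vec_text(path: str | Path, decade: int | None = None) -> DecadeEmbeddings:
    """Read embeddings in word2vec text format.

    The dialect: an optional ``"n d"`` header line, then one line per word,
    ``word v1 ... vd``.  File word order is preserved.  ``decade`` defaults
    to the first four-digit year found in the file name.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty embeddings file")

    start = 0
    head = lines[0].split()
    if len(head) == 2 and all(tok.lstrip("+-").isdigit() for tok in head):
        start = 1
    if start == len(lines):
        raise ValueError(f"{path}: header but no vectors")

    words: list[str] = []
    rows: list[list[float]] = []
    dim: int | None = None
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split()
        word, values = parts[0], parts[1:]
        if dim is None:
            dim = len(values)
            if dim == 0:
                raise ValueError(f"{path}, line {lineno}: no vector components")
        elif len(values) != dim:
            raise ValueError(
                f"{path}, line {lineno}: expected {dim} components, got {len(values)}"
            )
        words.append(word)
        rows.append([float(v) for v in values])

    if decade is None:
        decade = _infer_decade(path)
    if decade is None:
        raise ValueError(
            f"{path}: decade label not given and not inferable from the file name"
        )
    return DecadeEmbeddings(decade, words, np.array(rows))


def save_word2vec_text(emb: DecadeEmbeddings, path: str | Path, header: bool = True) -> None:
    """Write embeddings in word2vec text format (round-trips with the loader)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"{len(emb.vocabulary)} {emb.dim}\n")
        for word, row in zip(emb.vocabulary, emb.vectors):
            fh.write(word + " " + " ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Vocabulary intersection and alignment
# ---------------------------------------------------------------------------

def intersect_vocabulary(
    series: list[DecadeEmbeddings], extra: list[str] | None = None
) -> AlignedSeries:
    """Restrict all decades to their (sorted) shared vocabulary.

    ``extra`` optionally intersects further with an external word list
    (e.g. the cue set of an association dataset).  Returns an unaligned
    series; call :func:`align_series` afterwards.
    """
    if not series:
        raise ValueError("need at least one decade")
    shared = set(series[0].vocabulary)
    for emb in series[1:]:
        shared &= set(emb.vocabulary)
    if extra is not None:
        shared &= set(extra)
    if not shared:
        raise ValueError("vocabulary intersection is empty")
    ordered = sorted(shared)
    return AlignedSeries([emb.restrict(ordered) for emb in series], aligned=False)


def procrustes_align(
    source: DecadeEmbeddings, target: DecadeEmbeddings
) -> tuple[np.ndarray, DecadeEmbeddings]:
    """Orthogonal Procrustes map of ``source`` onto ``target``.

    Returns the orthogonal rotation ``R`` minimizing
    ``||source @ R - target||_F`` and the rotated copy of ``source``.
    """
    if source.vocabulary != target.vocabulary:
        raise ValueError("source and target must share an identical vocabulary order")
    if source.dim != target.dim:
        raise ValueError("source and target must share one embedding dimension")
    rotation, _ = orthogonal_procrustes(source.vectors, target.vectors)
    rotated = replace(source, vectors=source.vectors @ rotation)
    return rotation, rotated


def align_series(series: AlignedSeries, reference_decade: int | None = None) -> AlignedSeries:
    """Align every decade directly onto the reference decade (default: latest).

    Direct-to-reference (rather than chained decade-to-decade) alignment
    keeps every pair of decades comparable and avoids error accumulation.
    """
    if reference_decade is None:
        reference_decade = max(series.decade_labels)
    target = series.get(reference_decade)
    aligned = []
    for emb in series.decades:
        if emb.decade == reference_decade:
            aligned.append(emb)
        else:
            _, rotated = procrustes_align(emb, target)
            aligned.append(rotated)
    return AlignedSeries(aligned, aligned=True, reference_decade=reference_decade)


# ---------------------------------------------------------------------------
# Cosine similarity
# ---------------------------------------------------------------------------

def cosine_rsm(emb: DecadeEmbeddings, subset: list[str] | None = None) -> RSM:
    """Cosine-similarity RSM over ``subset`` (default: full vocabulary)."""
    if subset is not None:
        emb = emb.restrict(subset)
    zero = emb.zero_norm_words
    if zero:
        raise ValueError(f"zero-norm vectors (cosine undefined): {zero}")
    normed = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    matrix = normed @ normed.T
    matrix = np.clip((matrix + matrix.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    return RSM(list(emb.vocabulary), matrix, source=f"decade:{emb.decade}")


def self_similarity(series: AlignedSeries, word: str, t1: int, t2: int) -> float:
    """Cosine between a word's vectors in decades ``t1`` and ``t2``.

    Only meaningful once the series is Procrustes-aligned; low values flag
    words whose dominant usage changed between the two decades.
    """
    if not series.aligned:
        raise ValueError("series is unaligned; align first (align_series)")
    v1 = series.get(t1).vector(word)
    v2 = series.get(t2).vector(word)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        warnings.warn(f"zero-norm vector for {word!r}; self-similarity undefined")
        return float("nan")
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
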