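"""Word-embedding lexicons: word2vec-text I/O, cosine similarity, exact
nearest-neighbour retrieval.

Vocabularies handled here are small (thousands of words at most), so
neighbour search is exact brute force over the full vocabulary — no
approximate indexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmbeddingFormatError, VocabularyError, ZeroVectorError

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingLexicon",
    "read_word2vec_text",
    "write_word2vec_text",
    "cosine",
    "nearest_neighbors",
    "write_neighbors_tsv",
]


@dataclass(frozen=True)
class EmbeddingLexicon:
    """An ordered vocabulary with one fixed-dimension vector per word.

    Parameters
    ----------
    words
        Vocabulary in file order, no duplicates.
    vectors
        Array of shape ``(len(words), d)``.
    unit_normalized
        True if every row has Euclidean norm 1 (within 1e-9).
    """

    words: tuple[str, ...]
    vectors: np.ndarray
    unit_normalized: bool = False
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(self.words):
            raise ValueError("vectors must be a (n_words, d) array")
        object.__setattr__(self, "vectors", vectors)
        index = {w: i for i, w in enumerate(self.words)}
        if len(index) != len(self.words):
            raise ValueError("duplicate words in vocabulary")
        object.__setattr__(self, "_index", index)
        if self.unit_normalized:
            norms = np.linalg.norm(vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("unit_normalized set but some norms differ from 1")

    @property
    def d(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise VocabularyError(word) from None

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index(word)]

    def normalized(self) -> "EmbeddingLexicon":
        """Return a copy with every vector scaled to unit norm."""
        if self.unit_normalized:
            return self
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        if np.any(norms == 0):
            bad = self.words[int(np.argmin(norms))]
            raise ZeroVectorError(f"zero-norm vector for word {bad!r}")
        return EmbeddingLexicon(self.words, self.vectors / norms, unit_normalized=True)


def read_word2vec_text(path: str | Path, case_fold: bool = True) -> EmbeddingLexicon:
    """Read a word2vec text file: header ``"V d"`` then V rows ``word v1 ... vd``.

    Duplicate words (after optional case folding) are dropped with a logged
    warning, keeping the first occurrence. Zero-norm vectors are rejected.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header:
            raise EmbeddingFormatError(f"{path}: empty file")
        parts = header.split()
        if len(parts) != 2:
            raise EmbeddingFormatError(f"{path}: malformed header {header!r}")
        try:
            n_declared, d = int(parts[0]), int(parts[1])
        except ValueError:
            raise EmbeddingFormatError(f"{path}: non-integer header {header!r}") from None
        if n_declared <= 0 or d <= 0:
            raise EmbeddingFormatError(f"{path}: non-positive sizes in header {header!r}")

        words: list[str] = []
        rows: list[np.ndarray] = []
        seen: set[str] = set()
        n_dup = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != d + 1:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected {d + 1} fields, got {len(fields)}"
                )
            word = fields[0]
            if case_fold:
                word = word.casefold()
            try:
                vec = np.array(fields[1:], dtype=np.float64)
            except ValueError:
                raise EmbeddingFormatError(f"{path}:{lineno}: non-numeric vector entry") from None
            if np.linalg.norm(vec) == 0.0:
                raise ZeroVectorError(f"{path}:{lineno}: zero-norm vector for {word!r}")
            if word in seen:
                n_dup += 1
                logger.warning("%s:%d: duplicate word %r dropped", path, lineno, word)
                continue
            seen.add(word)
            words.append(word)
            rows.append(vec)

    if len(words) + n_dup != n_declared:
        raise EmbeddingFormatError(
            f"{path}: header declares {n_declared} rows, found {len(words) + n_dup}"
        )
    return EmbeddingLexicon(tuple(words), np.vstack(rows))


def write_word2vec_text(lex: EmbeddingLexicon, path: str | Path, precision: int = 8) -> None:
    """Write a lexicon in word2vec text layout."""
    path = Path(path)
    fmt = f"%.{precision}f"
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(lex)} {lex.d}\n")
        for word, vec in zip(lex.words, lex.vectors):
            fh.write(word + " " + " ".join(fmt % v for v in vec) + "\n")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors, clamped to [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def nearest_neighbors(
    lex: EmbeddingLexicon,
    word: str,
    m: int,
    exclude: Iterable[str] = (),
) -> list[tuple[str, float]]:
    """Exact top-``m`` cosine neighbours of ``word``, descending similarity.

    The query word itself is always excluded. Ties are broken by ascending
    lexicographic word order so rankings are deterministic.
    """
    qi = lex.index(word)
    excluded = set(exclude)
    excluded.add(word)

    norms = np.linalg.norm(lex.vectors, axis=1)
    sims = lex.vectors @ lex.vectors[qi] / (norms * norms[qi])
    np.clip(sims, -1.0, 1.0, out=sims)

    candidates = [
        (w, float(sims[i])) for i, w in enumerate(lex.words) if w not in excluded
    ]
    if m > len(candidates):
        raise ValueError(
            f"m={m} exceeds {len(candidates)} available candidates for {word!r}"
        )
    candidates.sort(key=lambda pair: (-pair[1], pair[0]))
    return candidates[:m]


def write_neighbors_tsv(
    neighbors: Sequence[tuple[str, float]], path: str | Path
) -> None:
    """Dump a ranked neighbour list as TSV columns (word, rank, cosine)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("word\trank\tcosine\n")
        for rank, (w, c) in enumerate(neighbors, start=1):
            fh.write(f"{w}\t{rank}\t{c:.8f}\n")
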