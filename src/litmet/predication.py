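"""Predication-based Relatedness scoring for "x is a y" statements.

The score adjusts the two keyword vectors toward their contextually shared
sense before taking the cosine: the neighbourhood of the source word y is
searched for vectors close to each keyword, those are averaged into the
keyword vectors, and the cosine of the two adjusted vectors is returned.
High values mean the aligned senses of x and y are close.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingLexicon, cosine, nearest_neighbors
from .errors import ParameterError, VocabularyError

logger = logging.getLogger(__name__)

__all__ = [
    "PredicationParams",
    "Statement",
    "StatementScores",
    "relatedness",
    "plain_cos",
    "score_statements",
    "scores_to_frame",
    "parameter_sweep",
]

SelectionRule = Literal["separate", "common"]


@dataclass(frozen=True)
class PredicationParams:
    """Neighbourhood parameters for the adjusted-vector relatedness score.

    ``k1`` neighbours are averaged into the target (x) vector, ``k2`` into
    the source (y) vector, both drawn from the ``m`` nearest neighbours of
    the source word. Defaults k1=5, k2=5, m=4500; ``m`` is clipped to the
    vocabulary size minus one on smaller lexicons (with a warning).
    """

    k1: int = 5
    k2: int = 5
    m: int = 4500
    selection_rule: SelectionRule = "separate"

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "m"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.k1 > self.m or self.k2 > self.m:
            raise ParameterError(
                f"k1={self.k1}, k2={self.k2} must not exceed m={self.m}"
            )
        if self.selection_rule not in ("separate", "common"):
            raise ParameterError(f"unknown selection_rule {self.selection_rule!r}")

    @property
    def label(self) -> str:
        return f"{self.k1}-{self.k2}-{self.m}"

    def clipped_to(self, vocab_size: int) -> "PredicationParams":
        """Clip ``m`` to ``vocab_size - 1``, warning when clipping occurs."""
        limit = vocab_size - 1
        if self.m <= limit:
            return self
        logger.warning(
            "m=%d exceeds vocabulary size %d; clipping to %d", self.m, vocab_size, limit
        )
        if max(self.k1, self.k2) > limit:
            raise ParameterError(
                f"after clipping, m={limit} < max(k1, k2)={max(self.k1, self.k2)}"
            )
        return replace(self, m=limit)


@dataclass(frozen=True)
class Statement:
    """One "x is a y" item: target word x, source word y, literality label."""

    id: str
    text: str
    x: str
    y: str
    sentence_type: Literal["literal", "metaphor"]

    def __post_init__(self) -> None:
        if not self.x or not self.y:
            raise ValueError(f"statement {self.id}: empty keyword")
        if self.sentence_type not in ("literal", "metaphor"):
            raise ValueError(
                f"statement {self.id}: bad sentence_type {self.sentence_type!r}"
            )


@dataclass(frozen=True)
class StatementScores:
    id: str
    cos: float
    relatedness: float
    z_cos: float
    z_relatedness: float


def _top_k(
    neighbor_words: Sequence[str], key_sims: np.ndarray, k: int
) -> list[int]:
    """Indices of the k neighbours with highest similarity, ties lexicographic."""
    order = sorted(range(len(neighbor_words)), key=lambda i: (-key_sims[i], neighbor_words[i]))
    return order[:k]


def relatedness(
    lex: EmbeddingLexicon, x: str, y: str, params: PredicationParams = PredicationParams()
) -> float:
    """Cosine of the neighbourhood-adjusted x and y vectors.

    With N the ``m`` nearest neighbours of y (x and y excluded):

    - ``separate`` rule: the k1 members of N closest to x are averaged with
      the x vector; the k2 members closest to y are averaged with the y
      vector.
    - ``common`` rule: one set of k1 members of N maximizing the summed
      closeness to x and y is averaged into both vectors.

    The direction matters: the neighbourhood is taken around the source y,
    so relatedness(x, y) != relatedness(y, x) in general.
    """
    if not lex.unit_normalized:
        raise ValueError("relatedness requires a unit-normalized lexicon")
    params = params.clipped_to(len(lex))
    xv = lex.vector(x)
    yv = lex.vector(y)

    exclude = {x, y}
    m_eff = min(params.m, len(lex) - len(exclude))
    if m_eff < max(params.k1, params.k2):
        raise ParameterError(
            f"only {m_eff} neighbourhood candidates for ({x!r}, {y!r}); "
            f"need at least max(k1, k2)={max(params.k1, params.k2)}"
        )
    neighbors = nearest_neighbors(lex, y, m_eff, exclude=exclude)
    words = [w for w, _ in neighbors]
    vecs = lex.vectors[[lex.index(w) for w in words]]
    sims_x = vecs @ xv  # unit vectors: dot product is cosine
    sims_y = vecs @ yv

    if params.selection_rule == "separate":
        s1 = _top_k(words, sims_x, params.k1)
        s2 = _top_k(words, sims_y, params.k2)
        x_adj = np.vstack([xv, vecs[s1]]).mean(axis=0)
        y_adj = np.vstack([yv, vecs[s2]]).mean(axis=0)
    else:
        s = _top_k(words, sims_x + sims_y, params.k1)
        x_adj = np.vstack([xv, vecs[s]]).mean(axis=0)
        y_adj = np.vstack([yv, vecs[s]]).mean(axis=0)
    return cosine(x_adj, y_adj)


def plain_cos(lex: EmbeddingLexicon, x: str, y: str) -> float:
    """Cosine of the raw, unadjusted keyword vectors."""
    return cosine(lex.vector(x), lex.vector(y))


def _zscores(values: np.ndarray) -> np.ndarray:
    """Sample-SD z-scores; all zeros when the SD is 0."""
    sd = values.std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def score_statements(
    lex: EmbeddingLexicon,
    statements: Sequence[Statement],
    params: PredicationParams = PredicationParams(),
) -> list[StatementScores]:
    """Score each statement with Cos and Relatedness, then z-score both
    measures over the scored set.

    Statements with out-of-vocabulary keywords are skipped with a warning.
    Raises :class:`ParameterError` if fewer than 2 statements are scorable.
    """
    params = params.clipped_to(len(lex))  # clip (and warn) once for the batch
    ids: list[str] = []
    cos_vals: list[float] = []
    rel_vals: list[float] = []
    for st in statements:
        try:
            c = plain_cos(lex, st.x, st.y)
            r = relatedness(lex, st.x, st.y, params)
        except VocabularyError as err:
            logger.warning("statement %s skipped: %s", st.id, err)
            continue
        ids.append(st.id)
        cos_vals.append(c)
        rel_vals.append(r)

    if len(ids) < 2:
        raise ParameterError(
            f"need at least 2 scorable statements to z-score, got {len(ids)}"
        )
    z_cos = _zscores(np.array(cos_vals))
    z_rel = _zscores(np.array(rel_vals))
    return [
        StatementScores(i, c, r, float(zc), float(zr))
        for i, c, r, zc, zr in zip(ids, cos_vals, rel_vals, z_cos, z_rel)
    ]


def scores_to_frame(
    statements: Sequence[Statement], scores: Sequence[StatementScores]
) -> pd.DataFrame:
    """Join statements and scores into the canonical scores table."""
    by_id = {st.id: st for st in statements}
    rows = [
        {
            "id": sc.id,
            "x": by_id[sc.id].x,
            "y": by_id[sc.id].y,
            "sentence_type": by_id[sc.id].sentence_type,
            "cos": sc.cos,
            "relatedness": sc.relatedness,
            "z_cos": sc.z_cos,
            "z_relatedness": sc.z_relatedness,
        }
        for sc in scores
    ]
    return pd.DataFrame(rows)


def parameter_sweep(
    lex: EmbeddingLexicon,
    statements: Sequence[Statement],
    grid: Iterable[tuple[int, int, int]],
    selection_rule: SelectionRule = "separate",
) -> pd.DataFrame:
    """Mean/SD relatedness per (k1, k2, m) triple over the statement set."""
    grid = list(grid)
    if not grid:
        raise ParameterError("empty parameter grid")
    rows = []
    for triple in grid:
        try:
            k1, k2, m = triple
            params = PredicationParams(k1=k1, k2=k2, m=m, selection_rule=selection_rule)
        except (TypeError, ParameterError) as err:
            raise ParameterError(f"invalid parameter triple {triple!r}: {err}") from None
        scores = score_statements(lex, statements, params)
        vals = np.array([s.relatedness for s in scores])
        rows.append(
            {
                "k1": k1,
                "k2": k2,
                "m": m,
                "n_scored": len(vals),
                "mean_relatedness": vals.mean(),
                "sd_relatedness": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
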