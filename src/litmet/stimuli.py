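"""Stimulus selection and matching.

Literal items are chosen by lowest Relatedness; each is then paired with a
metaphor by exhaustive greedy search on four z-normalized lexical
covariates (keyword lengths and logged frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import NormalizationError, SizingError
from .predication import StatementScores

__all__ = [
    "StimulusFeatures",
    "MatchResult",
    "normalize_features",
    "greedy_match",
    "select_low_relatedness",
    "features_to_frame",
    "match_to_frame",
]

_MEASURES = ("length1", "length2", "logfreq1", "logfreq2")


@dataclass(frozen=True)
class StimulusFeatures:
    """Lexical covariates for one statement's keywords x and y.

    Frequencies must already be logged by the caller (log base is the
    caller's choice). The ``z_*`` fields are filled by
    :func:`normalize_features` over a pooled normalization set.
    """

    id: str
    length1: int
    length2: int
    logfreq1: float
    logfreq2: float
    z_length1: float = float("nan")
    z_length2: float = float("nan")
    z_logfreq1: float = float("nan")
    z_logfreq2: float = float("nan")

    def __post_init__(self) -> None:
        if self.length1 <= 0 or self.length2 <= 0:
            raise ValueError(f"{self.id}: keyword lengths must be positive")

    def zvector(self) -> np.ndarray:
        return np.array(
            [self.z_length1, self.z_length2, self.z_logfreq1, self.z_logfreq2]
        )


@dataclass(frozen=True)
class MatchResult:
    """Literal-to-metaphor pairing with per-pair summed z-differences."""

    pairs: tuple[tuple[str, str, float], ...]  # (literal id, metaphor id, summed diff)
    mean_summed_difference: float
    sd_summed_difference: float
    max_summed_difference: float


def normalize_features(features: Sequence[StimulusFeatures]) -> list[StimulusFeatures]:
    """Z-score the four measures over the pooled item set (sample SD).

    Raises :class:`NormalizationError` naming the first measure with zero
    variance.
    """
    if len(features) < 2:
        raise SizingError("need at least 2 items to normalize features")
    zcols = {}
    for measure in _MEASURES:
        raw = np.array([getattr(f, measure) for f in features], dtype=np.float64)
        sd = raw.std(ddof=1)
        if sd == 0.0:
            raise NormalizationError(measure)
        zcols[measure] = (raw - raw.mean()) / sd
    return [
        replace(
            f,
            z_length1=float(zcols["length1"][i]),
            z_length2=float(zcols["length2"][i]),
            z_logfreq1=float(zcols["logfreq1"][i]),
            z_logfreq2=float(zcols["logfreq2"][i]),
        )
        for i, f in enumerate(features)
    ]


def _pair_distance(a: StimulusFeatures, b: StimulusFeatures, metric: str) -> float:
    diff = a.zvector() - b.zvector()
    if np.any(np.isnan(diff)):
        raise ValueError(f"unnormalized features for {a.id!r}/{b.id!r}")
    if metric == "absolute":
        return float(np.abs(diff).sum())
    if metric == "squared":
        return float((diff**2).sum())
    raise ValueError(f"unknown metric {metric!r}")


def greedy_match(
    literals: Sequence[StimulusFeatures],
    metaphors: Sequence[StimulusFeatures],
    metric: Literal["absolute", "squared"] = "absolute",
    method: Literal["greedy", "optimal"] = "greedy",
) -> MatchResult:
    """Pair every literal with a metaphor by repeated exhaustive search.

    At each step the globally closest remaining (literal, metaphor) pair —
    smallest summed difference over the four z-measures — is recorded and
    both items are removed, until all literals are matched. Ties are broken
    by smallest literal id, then smallest metaphor id.

    ``method="optimal"`` instead solves the assignment problem minimizing
    the total summed difference (provided for comparison; not the default
    sequential procedure).
    """
    if len(metaphors) < len(literals):
        raise SizingError(
            f"{len(metaphors)} metaphors cannot cover {len(literals)} literals"
        )
    lits = sorted(literals, key=lambda f: f.id)
    mets = sorted(metaphors, key=lambda f: f.id)

    pairs: list[tuple[str, str, float]] = []
    if method == "optimal":
        cost = np.array([[_pair_distance(l, m, metric) for m in mets] for l in lits])
        rows, cols = linear_sum_assignment(cost)
        for r, c in sorted(zip(rows, cols)):
            pairs.append((lits[r].id, mets[c].id, float(cost[r, c])))
    elif method == "greedy":
        remaining_l = list(lits)
        remaining_m = list(mets)
        while remaining_l:
            best: tuple[float, str, str, int, int] | None = None
            for i, lit in enumerate(remaining_l):
                for j, met in enumerate(remaining_m):
                    d = _pair_distance(lit, met, metric)
                    key = (d, lit.id, met.id, i, j)
                    if best is None or key[:3] < best[:3]:
                        best = key
            assert best is not None
            d, lid, mid, i, j = best
            pairs.append((lid, mid, d))
            remaining_l.pop(i)
            remaining_m.pop(j)
    else:
        raise ValueError(f"unknown method {method!r}")

    dists = np.array([p[2] for p in pairs])
    return MatchResult(
        pairs=tuple(pairs),
        mean_summed_difference=float(dists.mean()),
        sd_summed_difference=float(dists.std(ddof=1)) if len(dists) > 1 else 0.0,
        max_summed_difference=float(dists.max()),
    )


def select_low_relatedness(scores: Sequence[StatementScores], n: int) -> list[str]:
    """Ids of the n lowest-relatedness statements, ties broken by id."""
    if n > len(scores):
        raise SizingError(f"requested {n} of {len(scores)} scored statements")
    ranked = sorted(scores, key=lambda s: (s.relatedness, s.id))
    return [s.id for s in ranked[:n]]


def features_to_frame(features: Sequence[StimulusFeatures]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in features])


def match_to_frame(match: MatchResult) -> pd.DataFrame:
    return pd.DataFrame(
        list(match.pairs), columns=["literal_id", "metaphor_id", "summed_difference"]
    )
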