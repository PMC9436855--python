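"""Synthetic inputs for every pipeline stage.

Provides clustered embedding lexicons, literal/metaphor statement sets with
controllable similarity structure, and trial-level literality-decision data
generated from a mixed model with participant and presentation-order random
intercepts, right-skewed multiplicative RT noise, and a configurable rate
of implausibly fast/slow contaminant responses.

One global seed drives independent per-operation streams (spawned from a
``numpy.random.SeedSequence``), so any single stage is reproducible in
isolation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import EmbeddingLexicon
from .errors import ConfigError, ParameterError, SizingError
from .predication import Statement
from .stimuli import StimulusFeatures

__all__ = [
    "ClusteredLexicon",
    "SimulationConfig",
    "SimulatedTrials",
    "generate_lexicon",
    "generate_statements",
    "simulate_trials",
]

# fixed-effect terms recognised by the RT and accuracy generators;
# predictors are the z-scored item covariates, sentence_type coded
# literal=1 / metaphor=0 (metaphor is the reference level)
RT_TERMS = (
    "intercept",
    "z_cos",
    "z_relatedness",
    "z_length1",
    "z_length2",
    "sentence_type",
    "z_length1:z_length2",
    "z_cos:z_relatedness",
    "z_cos:sentence_type",
    "z_relatedness:sentence_type",
    "z_cos:z_relatedness:sentence_type",
)
ACC_TERMS = (
    "intercept",
    "z_cos",
    "z_relatedness",
    "z_length1",
    "z_logfreq1",
    "sentence_type",
    "z_cos:z_relatedness",
    "z_cos:sentence_type",
    "z_relatedness:sentence_type",
    "z_cos:z_relatedness:sentence_type",
)

# Defaults echo the scale of the published RT coefficient table (intercept
# ~1660 ms, three-way interaction ~370 ms); random-effect SDs are chosen
# for realism, not taken from any report.
_DEFAULT_RT_EFFECTS = {
    "intercept": 1660.0,
    "z_relatedness": -320.0,
    "z_cos": 205.0,
    "z_length1": 30.0,
    "z_length2": 57.0,
    "sentence_type": -55.0,
    "z_length1:z_length2": 31.0,
    "z_cos:z_relatedness": -414.0,
    "z_cos:sentence_type": -275.0,
    "z_relatedness:sentence_type": 342.0,
    "z_cos:z_relatedness:sentence_type": 372.0,
}
_DEFAULT_ACC_EFFECTS = {
    "intercept": 0.72,
    "z_relatedness": 0.29,
    "sentence_type": 0.11,
    "z_cos": -0.107,
    "z_length1": -0.034,
    "z_logfreq1": -0.023,
    "z_relatedness:sentence_type": -0.335,
    "z_cos:z_relatedness:sentence_type": -0.179,
    "z_cos:z_relatedness": 0.163,
    "z_cos:sentence_type": 0.088,
}


@dataclass(frozen=True)
class ClusteredLexicon(EmbeddingLexicon):
    """Synthetic lexicon retaining the cluster label of each word."""

    cluster_of: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Generative parameters for trial-level RT/accuracy data."""

    n_participants: int = 66
    n_items_per_type: int = 40
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RT_EFFECTS)
    )
    accuracy_fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ACC_EFFECTS)
    )
    subject_intercept_sd: float = 300.0
    order_intercept_sd: float = 80.0
    accuracy_subject_sd: float = 0.08
    residual_sigma: float = 0.35  # lognormal sigma of the multiplicative noise
    fast_rate: float = 0.0
    fast_range: tuple[float, float] = (100.0, 400.0)
    slow_rate: float = 0.0
    slow_range: tuple[float, float] = (5000.0, 8000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_items_per_type <= 0:
            raise ConfigError("participant and item counts must be positive")
        for name in ("fast_rate", "slow_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {r}")
        if self.fast_rate + self.slow_rate > 1.0:
            raise ConfigError("fast_rate + slow_rate exceed 1")
        for name in ("subject_intercept_sd", "order_intercept_sd",
                     "accuracy_subject_sd", "residual_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for term in self.fixed_effects:
            if term not in RT_TERMS:
                raise ConfigError(f"unknown RT fixed-effect term {term!r}")
        for term in self.accuracy_fixed_effects:
            if term not in ACC_TERMS:
                raise ConfigError(f"unknown accuracy fixed-effect term {term!r}")


@dataclass
class SimulatedTrials:
    """Trial table plus the generator's self-report."""

    trials: pd.DataFrame
    n_fast_planted: int
    n_slow_planted: int
    participant_intercepts: np.ndarray
    order_intercepts: np.ndarray
    config: SimulationConfig


def _pseudoword(rng: np.random.Generator, length: int) -> str:
    vowels = "aeiou"
    consonants = "".join(c for c in string.ascii_lowercase if c not in vowels)
    out = []
    for i in range(length):
        pool = consonants if i % 2 == 0 else vowels
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def generate_lexicon(
    n_clusters: int,
    words_per_cluster: int,
    d: int,
    within_cluster_concentration: float = 8.0,
    seed: int = 0,
) -> ClusteredLexicon:
    """Unit-normalized lexicon of pseudowords grouped into clusters.

    Each word vector is ``normalize(concentration * center + noise)`` around
    its cluster's random unit-vector center, so same-cluster pairs have
    systematically higher expected cosine than cross-cluster pairs; the
    concentration -> infinity limit collapses each cluster onto its center.
    """
    if n_clusters <= 0 or words_per_cluster <= 0:
        raise ParameterError("cluster counts must be positive")
    if d < 2:
        raise ParameterError("embedding dimension must be >= 2")
    if within_cluster_concentration < 0:
        raise ParameterError("concentration must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    centers = rng.normal(size=(n_clusters, d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)

    words: list[str] = []
    vectors: list[np.ndarray] = []
    cluster_of: dict[str, int] = {}
    seen: set[str] = set()
    for ci in range(n_clusters):
        for _ in range(words_per_cluster):
            w = _pseudoword(rng, int(rng.integers(3, 10)))
            while w in seen:
                w = _pseudoword(rng, int(rng.integers(3, 10)))
            seen.add(w)
            v = within_cluster_concentration * centers[ci] + rng.normal(size=d)
            norm = np.linalg.norm(v)
            if norm == 0.0:  # essentially impossible; regenerate deterministically
                v = centers[ci]
                norm = 1.0
            words.append(w)
            vectors.append(v / norm)
            cluster_of[w] = ci

    return ClusteredLexicon(
        tuple(words), np.vstack(vectors), unit_normalized=True, cluster_of=cluster_of
    )


def generate_statements(
    lex: ClusteredLexicon,
    n_literal: int,
    n_metaphor: int,
    seed: int = 0,
) -> tuple[list[Statement], list[StimulusFeatures]]:
    """Draw literal items as within-cluster word pairs and metaphors as
    cross-cluster pairs, with per-word log frequencies for the matching
    stage.

    The resulting Cos/Relatedness distributions are separated (literal >
    metaphor on average) but overlapping, which is what the downstream
    selection and matching stages need to be exercised.
    """
    if not lex.cluster_of:
        raise ParameterError("lexicon carries no cluster assignment")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    clusters: dict[int, list[str]] = {}
    for w, c in lex.cluster_of.items():
        clusters.setdefault(c, []).append(w)
    cluster_ids = sorted(clusters)
    if n_literal > 0 and not any(len(v) >= 2 for v in clusters.values()):
        raise SizingError("no cluster has two words; cannot form literal pairs")
    if n_metaphor > 0 and len(cluster_ids) < 2:
        raise SizingError("need >= 2 clusters to form metaphor pairs")

    logfreq = {w: float(rng.normal(8.0, 2.0)) for w in lex.words}

    used: set[tuple[str, str]] = set()
    statements: list[Statement] = []
    features: list[StimulusFeatures] = []

    def add(idx: int, stype: str, x: str, y: str) -> None:
        sid = f"{stype[:3]}{idx:03d}"
        statements.append(
            Statement(sid, f"A {x} is a {y}.", x=x, y=y, sentence_type=stype)
        )
        features.append(
            StimulusFeatures(
                sid,
                length1=len(x),
                length2=len(y),
                logfreq1=logfreq[x],
                logfreq2=logfreq[y],
            )
        )

    for i in range(n_literal):
        for _ in range(10000):
            ci = cluster_ids[rng.integers(len(cluster_ids))]
            if len(clusters[ci]) < 2:
                continue
            x, y = rng.choice(clusters[ci], size=2, replace=False)
            if (x, y) not in used:
                used.add((x, y))
                add(i, "literal", str(x), str(y))
                break
        else:
            raise SizingError("could not draw enough distinct literal pairs")

    for i in range(n_metaphor):
        for _ in range(10000):
            ca, cb = rng.choice(cluster_ids, size=2, replace=False)
            x = clusters[ca][rng.integers(len(clusters[ca]))]
            y = clusters[cb][rng.integers(len(clusters[cb]))]
            if (x, y) not in used:
                used.add((x, y))
                add(i, "metaphor", x, y)
                break
        else:
            raise SizingError("could not draw enough distinct metaphor pairs")

    return statements, features


def _linear_predictor(items: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """Evaluate named fixed effects on the item covariates (absent = 0)."""
    st = (items["sentence_type"] == "literal").astype(float).to_numpy()
    cols = {
        "intercept": np.ones(len(items)),
        "sentence_type": st,
    }
    for zc in ("z_cos", "z_relatedness", "z_length1", "z_length2", "z_logfreq1"):
        if zc in items:
            cols[zc] = items[zc].to_numpy(dtype=float)
    eta = np.zeros(len(items))
    for term, coef in effects.items():
        parts = term.split(":")
        val = np.ones(len(items))
        for pt in parts:
            if pt not in cols:
                raise ConfigError(f"term {term!r} needs item column {pt!r}")
            val = val * cols[pt]
        eta += coef * val
    return eta


def simulate_trials(items: pd.DataFrame, config: SimulationConfig) -> SimulatedTrials:
    """Simulate one literality-decision session per participant.

    ``items`` must have one row per statement with columns ``statement_id``,
    ``sentence_type`` and the z-scored predictors referenced by the
    configured fixed effects. Each participant sees every item once, in
    an independently shuffled order; ``order`` is the presentation position.

    RT = (fixed effects + participant intercept + order intercept) x
    mean-one lognormal noise. Accuracy is drawn from a linear-probability
    model clamped to [0.01, 0.99]. Contaminant trials overwrite the RT with
    uniform draws from the configured fast/slow ranges.
    """
    required = {"statement_id", "sentence_type"}
    if not required <= set(items.columns):
        raise ConfigError(f"items table missing columns {required - set(items.columns)}")
    items = items.reset_index(drop=True)
    n_items = len(items)
    n_sub = config.n_participants
    n_trials = n_sub * n_items

    ss = np.random.SeedSequence(config.seed)
    r_perm, r_sub, r_ord, r_noise, r_acc, r_cont = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    eta_rt_item = _linear_predictor(items, config.fixed_effects)
    eta_acc_item = _linear_predictor(items, config.accuracy_fixed_effects)

    sub_int = r_sub.normal(0.0, config.subject_intercept_sd, n_sub)
    ord_int = r_ord.normal(0.0, config.order_intercept_sd, n_items)
    acc_sub = r_acc.normal(0.0, config.accuracy_subject_sd, n_sub)

    rows_item = np.empty(n_trials, dtype=np.int64)
    rows_sub = np.repeat(np.arange(n_sub), n_items)
    rows_order = np.tile(np.arange(n_items), n_sub)
    for s in range(n_sub):
        rows_item[s * n_items : (s + 1) * n_items] = r_perm.permutation(n_items)

    mu = eta_rt_item[rows_item] + sub_int[rows_sub] + ord_int[rows_order]
    if config.residual_sigma > 0:
        # mean-one lognormal multiplier keeps planted effects unbiased
        noise = np.exp(
            r_noise.normal(0.0, config.residual_sigma, n_trials)
            - 0.5 * config.residual_sigma**2
        )
    else:
        noise = np.ones(n_trials)
    rt = mu * noise
    rt = np.maximum(rt, 1.0)

    p_acc = np.clip(eta_acc_item[rows_item] + acc_sub[rows_sub], 0.01, 0.99)
    accuracy = (r_acc.random(n_trials) < p_acc).astype(int)

    u = r_cont.random(n_trials)
    fast_mask = u < config.fast_rate
    slow_mask = (u >= config.fast_rate) & (u < config.fast_rate + config.slow_rate)
    rt[fast_mask] = r_cont.uniform(*config.fast_range, int(fast_mask.sum()))
    rt[slow_mask] = r_cont.uniform(*config.slow_range, int(slow_mask.sum()))

    stype = items["sentence_type"].to_numpy()[rows_item]
    is_literal = stype == "literal"
    response = np.where(
        accuracy.astype(bool) == is_literal, "literal-true", "not-literal"
    )

    trials = pd.DataFrame(
        {
            "participant_id": [f"p{s:03d}" for s in rows_sub],
            "order": rows_order + 1,
            "statement_id": items["statement_id"].to_numpy()[rows_item],
            "sentence_type": stype,
            "rt_ms": rt,
            "response": response,
            "accuracy": accuracy,
        }
    )
    return SimulatedTrials(
        trials=trials,
        n_fast_planted=int(fast_mask.sum()),
        n_slow_planted=int(slow_mask.sum()),
        participant_intercepts=sub_int,
        order_intercepts=ord_int,
        config=config,
    )
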