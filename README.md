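# litmet

Predication-based semantic relatedness scoring and literality-decision
analysis, as a tested, reusable pipeline.

The package covers four stages, each runnable on fully synthetic inputs:

1. **Scoring** (`litmet.embeddings`, `litmet.predication`) — reads a
   word-embedding space in word2vec text format and scores "x is a y"
   statements with two measures: **Cos**, the cosine similarity of the raw
   keyword vectors, and **Relatedness**, the cosine of the two vectors
   after each has been pulled toward the contextually shared sense by
   averaging in near neighbours of the source word y (defaults k1=5, k2=5,
   m=4500, clipped on small vocabularies). Both measures are z-scored over
   the scored set.
2. **Stimulus selection and matching** (`litmet.stimuli`) — selects the
   lowest-Relatedness literal statements and pairs each with a metaphor by
   repeated exhaustive search over four z-normalized lexical covariates
   (keyword lengths and log frequencies).
3. **Simulation** (`litmet.synthetic_data`) — generates clustered embedding
   lexicons, literal/metaphor statement sets, and trial-level RT/accuracy
   data from a generative mixed model with participant and
   presentation-order random intercepts, right-skewed multiplicative RT
   noise, and a configurable rate of implausibly fast/slow contaminant
   responses.
4. **Analysis** (`litmet.behavior_analysis`) — two-stage RT trimming
   (absolute 400/5000 ms cutoffs, then a 3-SD rule on the survivors),
   correctness filtering, AIC-guided mixed-model ladders, REML coefficient
   tables with Satterthwaite degrees of freedom, matched-pair
   literality-advantage comparison, and per-type correlations between
   model-estimated RTs and the semantic predictors.

Mixed models are fitted by `litmet.lmm`, a profiled-likelihood solver for
crossed random-intercept designs (validated against statsmodels and lme4;
roughly 100x faster than a generic solver on crossed designs, which makes
the replicated recovery and type-I studies in the test suite feasible).

## CLI

Every stage is exposed through one entry point:

```sh
# full synthetic pipeline from a single config
litmet run --config config.yaml --seed 1 --out out/

# single stages
litmet score --embeddings vectors.txt --statements statements.csv --out out/
litmet match --literals lit_features.csv --metaphors met_features.csv --out match.csv
litmet simulate --config config.yaml --out out/
litmet analyze --trials trials.csv --config config.yaml --out out/
```

A minimal config for an end-to-end synthetic run:

```yaml
seed: 1
synthetic:
  n_clusters: 8
  words_per_cluster: 30
  dim: 30
  concentration: 6.0
  n_literal: 40
  n_metaphor: 40
simulation:
  n_participants: 66
  fast_rate: 0.02
  slow_rate: 0.02
```

`litmet run` writes `scores.csv`, `features.csv`, `match.csv`,
`trials.csv`, the trim report, ladder/coefficient tables, the pairwise
report, and a `manifest.json` recording inputs, outputs, seed, and config
hash per stage. Reruns with the same config and seed are byte-identical.

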