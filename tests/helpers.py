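"""Shared utilities for the simulation-based model tests."""

import numpy as np
import pandas as pd

from litmet import behavior_analysis as ba
from litmet.synthetic_data import SimulationConfig, simulate_trials

# patsy's name for the treatment-coded sentence-type contrast
ST = "C(sentence_type, Treatment('metaphor'))[T.literal]"

# planted-term -> fitted-coefficient name, for the RT model formula
RT_TERM_TO_COEF = {
    "intercept": "Intercept",
    "sentence_type": ST,
    "z_cos": "z_cos",
    "z_relatedness": "z_relatedness",
    "z_length1": "z_length1",
    "z_length2": "z_length2",
    "z_length1:z_length2": "z_length1:z_length2",
    "z_cos:z_relatedness": "z_cos:z_relatedness",
    "z_cos:sentence_type": f"z_cos:{ST}",
    "z_relatedness:sentence_type": f"z_relatedness:{ST}",
    "z_cos:z_relatedness:sentence_type": f"z_cos:z_relatedness:{ST}",
}

# same mapping for the accuracy model formula
ACC_TERM_TO_COEF = {
    "intercept": "Intercept",
    "sentence_type": ST,
    "z_cos": "z_cos",
    "z_relatedness": "z_relatedness",
    "z_length1": "z_length1",
    "z_logfreq1": "z_logfreq1",
    "z_cos:z_relatedness": "z_cos:z_relatedness",
    "z_cos:sentence_type": f"z_cos:{ST}",
    "z_relatedness:sentence_type": f"z_relatedness:{ST}",
    "z_cos:z_relatedness:sentence_type": f"z_cos:z_relatedness:{ST}",
}


def make_items(n_items: int, seed: int) -> pd.DataFrame:
    """Item covariate table with bounded z-scored predictors (bounded so the
    planted RT linear predictor stays positive)."""
    rng = np.random.default_rng(seed)
    half = n_items // 2
    return pd.DataFrame(
        {
            "statement_id": [f"it{i:03d}" for i in range(n_items)],
            "sentence_type": ["literal"] * half + ["metaphor"] * (n_items - half),
            "z_cos": rng.uniform(-1.5, 1.5, n_items),
            "z_relatedness": rng.uniform(-1.5, 1.5, n_items),
            "z_length1": rng.uniform(-1.5, 1.5, n_items),
            "z_length2": rng.uniform(-1.5, 1.5, n_items),
            "z_logfreq1": rng.uniform(-1.5, 1.5, n_items),
            "z_logfreq2": rng.uniform(-1.5, 1.5, n_items),
        }
    )


def simulate_merged(items: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate trials and merge the item covariates back in."""
    sim = simulate_trials(items, config)
    return sim.trials.merge(items, on=["statement_id", "sentence_type"])


def coef_lookup(fit: "ba.ModelFit") -> dict[str, tuple[float, float, float]]:
    """Map coefficient name -> (estimate, se, p)."""
    return {
        row.term: (row.estimate, row.se, row.p)
        for row in fit.coefficients.itertuples(index=False)
    }
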