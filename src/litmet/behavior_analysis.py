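"""Preprocessing and mixed-effects analysis of literality-decision data.

Implements the two-stage RT trim (absolute cutoffs, then an SD criterion
computed on the survivors), correctness filtering, AIC-guided model-ladder
development, the RT and accuracy coefficient tables, the matched-pair
literality-advantage analysis, and per-type correlations between
model-estimated RTs and the semantic predictors.

Convention notes: continuous predictors are expected z-scored; sentence
type is treatment-coded with metaphor as the reference level. Ladders are
fitted by maximum likelihood (AIC comparison across fixed-effect
structures), coefficient tables by REML with Satterthwaite degrees of
freedom. R^2 is the squared Pearson correlation of fitted vs observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .errors import DataError, SizingError
from .lmm import LMMResult, fit_lmm
from .stimuli import MatchResult

__all__ = [
    "TrimReport",
    "ModelFit",
    "ModelLadder",
    "ModelSpec",
    "trim_rts",
    "filter_correct",
    "preprocess_trials",
    "fit_mixed",
    "fit_model_ladder",
    "fit_rt_model",
    "fit_accuracy_model",
    "default_rt_ladder",
    "pairwise_advantage",
    "estimated_rt_correlation",
    "PairwiseReport",
]

_ST = "C(sentence_type, Treatment('metaphor'))"
RT_FORMULA = f"z_length1*z_length2 + z_cos*z_relatedness*{_ST}"
ACCURACY_FORMULA = f"z_cos*z_relatedness*{_ST} + z_length1 + z_logfreq1"


@dataclass(frozen=True)
class TrimReport:
    n_total: int
    n_fast_removed: int
    n_slow_removed: int
    n_sd_removed: int
    n_incorrect_removed: int
    n_retained: int
    mean_rt_after_absolute_trim: float
    sd_rt_after_absolute_trim: float

    def __post_init__(self) -> None:
        removed = (
            self.n_fast_removed
            + self.n_slow_removed
            + self.n_sd_removed
            + self.n_incorrect_removed
        )
        if self.n_retained != self.n_total - removed:
            raise ValueError("trim counts do not reconcile")


def trim_rts(
    trials: pd.DataFrame,
    low_ms: float = 400.0,
    high_ms: float = 5000.0,
    sd_mult: float = 3.0,
) -> tuple[pd.DataFrame, TrimReport]:
    """Two-stage RT trim.

    Stage 1 removes responses faster than ``low_ms`` or slower than
    ``high_ms``. Stage 2 computes the mean and SD of the stage-1 survivors
    and removes responses beyond ``mean ± sd_mult * SD``.
    """
    if len(trials) == 0:
        raise DataError("empty trial table")
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
        raise DataError("non-positive or non-finite RTs")

    fast = rt < low_ms
    slow = rt > high_ms
    stage1 = trials[~fast & ~slow]
    rt1 = stage1["rt_ms"].to_numpy(dtype=float)
    if rt1.size == 0:
        raise DataError("no trials survive the absolute RT cutoffs")
    mean1 = float(rt1.mean())
    sd1 = float(rt1.std(ddof=1)) if rt1.size > 1 else 0.0

    outlying = (rt1 < mean1 - sd_mult * sd1) | (rt1 > mean1 + sd_mult * sd1)
    retained = stage1[~outlying]

    report = TrimReport(
        n_total=len(trials),
        n_fast_removed=int(fast.sum()),
        n_slow_removed=int(slow.sum()),
        n_sd_removed=int(outlying.sum()),
        n_incorrect_removed=0,
        n_retained=len(retained),
        mean_rt_after_absolute_trim=mean1,
        sd_rt_after_absolute_trim=sd1,
    )
    return retained.reset_index(drop=True), report


def filter_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Retain only accuracy == 1 rows."""
    if "accuracy" not in trials.columns or trials["accuracy"].isna().any():
        raise DataError("missing accuracy values")
    acc = trials["accuracy"].astype(int)
    if not acc.isin((0, 1)).all():
        raise DataError("accuracy must be coded 0/1")
    return trials[acc == 1].reset_index(drop=True)


def preprocess_trials(
    trials: pd.DataFrame,
    low_ms: float = 400.0,
    high_ms: float = 5000.0,
    sd_mult: float = 3.0,
) -> tuple[pd.DataFrame, TrimReport]:
    """Trim RTs, then drop incorrect responses; report carries all counts."""
    trimmed, rep = trim_rts(trials, low_ms, high_ms, sd_mult)
    correct = filter_correct(trimmed)
    full = TrimReport(
        n_total=rep.n_total,
        n_fast_removed=rep.n_fast_removed,
        n_slow_removed=rep.n_slow_removed,
        n_sd_removed=rep.n_sd_removed,
        n_incorrect_removed=len(trimmed) - len(correct),
        n_retained=len(correct),
        mean_rt_after_absolute_trim=rep.mean_rt_after_absolute_trim,
        sd_rt_after_absolute_trim=rep.sd_rt_after_absolute_trim,
    )
    return correct, full


@dataclass
class ModelFit:
    """One fitted mixed model with its bookkeeping."""

    name: str
    formula: str
    random: tuple[str, ...]
    aic: float
    r2: float
    coefficients: pd.DataFrame
    singular: bool
    result: LMMResult | None = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)
    accepted: bool | None = None
    aic_diff: float | None = None
    r2_diff: float | None = None
    error: str | None = None

    def predict_fixed(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level predictions (random effects at 0) for new items."""
        if self.result is None or self.design_info is None:
            raise ValueError(f"model {self.name!r} has no usable fit")
        (X,) = patsy.build_design_matrices([self.design_info], data)
        return self.result.predict_fixed(np.asarray(X))


@dataclass
class ModelLadder:
    fits: list[ModelFit]

    def accepted_path(self) -> list[str]:
        return [f.name for f in self.fits if f.accepted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [f.name for f in self.fits],
                "formula": [f.formula for f in self.fits],
                "random": ["+".join(f.random) for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "aic_diff": [f.aic_diff for f in self.fits],
                "r2": [f.r2 for f in self.fits],
                "r2_diff": [f.r2_diff for f in self.fits],
                "accepted": [f.accepted for f in self.fits],
                "error": [f.error for f in self.fits],
            }
        )


@dataclass(frozen=True)
class ModelSpec:
    name: str
    formula: str  # fixed-effects right-hand side (patsy)
    random: tuple[str, ...] = ("participant_id",)  # grouping columns


def fit_mixed(
    data: pd.DataFrame,
    formula: str,
    response: str,
    random: Sequence[str] = ("participant_id", "order"),
    reml: bool = True,
    name: str = "model",
) -> ModelFit:
    """Fit one mixed model from a patsy fixed-effects formula."""
    y = data[response].to_numpy(dtype=float)
    if np.var(y) == 0.0:
        raise DataError(f"response {response!r} has zero variance")
    dm = patsy.dmatrix(formula, data, return_type="dataframe")
    if len(dm) != len(data):
        raise DataError("design matrix dropped rows (missing predictor values?)")
    factors = {g: data[g].to_numpy() for g in random}
    res = fit_lmm(
        y,
        dm.to_numpy(),
        factors,
        fe_names=list(dm.columns),
        reml=reml,
    )
    r2 = float(np.corrcoef(res.fitted, y)[0, 1] ** 2)
    return ModelFit(
        name=name,
        formula=formula,
        random=tuple(random),
        aic=res.aic,
        r2=r2,
        coefficients=res.coef_table(),
        singular=res.singular,
        result=res,
        design_info=dm.design_info,
    )


def fit_model_ladder(
    data: pd.DataFrame,
    ladder_spec: Sequence[ModelSpec],
    response: str = "rt_ms",
) -> ModelLadder:
    """Fit models in order (ML), accepting a step when its AIC is lower
    than the last accepted model's. Diffs are against the last accepted
    model. Failed fits are recorded and the ladder continues.
    """
    if len(ladder_spec) < 1:
        raise DataError("empty ladder")
    fits: list[ModelFit] = []
    last_accepted: ModelFit | None = None
    for spec in ladder_spec:
        try:
            fit = fit_mixed(
                data, spec.formula, response, random=spec.random, reml=False,
                name=spec.name,
            )
        except (DataError, np.linalg.LinAlgError, ValueError) as err:
            fits.append(
                ModelFit(
                    name=spec.name,
                    formula=spec.formula,
                    random=tuple(spec.random),
                    aic=float("nan"),
                    r2=float("nan"),
                    coefficients=pd.DataFrame(),
                    singular=True,
                    accepted=False,
                    error=str(err),
                )
            )
            continue
        if last_accepted is None:
            fit.accepted = True
            fit.aic_diff = None
            fit.r2_diff = None
            last_accepted = fit
        else:
            fit.aic_diff = fit.aic - last_accepted.aic
            fit.r2_diff = fit.r2 - last_accepted.r2
            fit.accepted = fit.aic < last_accepted.aic
            if fit.accepted:
                last_accepted = fit
        fits.append(fit)
    return ModelLadder(fits)


def default_rt_ladder() -> list[ModelSpec]:
    """The RT model-development sequence: random effects first, then word
    lengths, log frequencies, and the semantic interaction block."""
    p = ("participant_id",)
    po = ("participant_id", "order")
    return [
        ModelSpec("M1", "1", p),
        ModelSpec("M2", "1", po),
        ModelSpec("M3", "z_length1", po),
        ModelSpec("M4", "z_length1 + z_length2", po),
        ModelSpec("M5", "z_length1*z_length2", po),
        ModelSpec("M6", "z_length1*z_length2 + z_logfreq1", po),
        ModelSpec("M7", "z_length1*z_length2 + z_logfreq2", po),
        ModelSpec("M8", RT_FORMULA, po),
    ]


def fit_rt_model(trials: pd.DataFrame) -> ModelFit:
    """REML fit of the full RT model: length interaction plus the
    Cos x Relatedness x SentenceType block, random intercepts for
    participant and presentation order."""
    return fit_mixed(
        trials,
        RT_FORMULA,
        "rt_ms",
        random=("participant_id", "order"),
        reml=True,
        name="rt_full",
    )


def fit_accuracy_model(trials: pd.DataFrame) -> ModelFit:
    """Linear mixed model on 0/1 accuracy (probability scale), random
    participant intercept only."""
    if trials["accuracy"].nunique() < 2:
        raise DataError("accuracy has zero variance; nothing to model")
    return fit_mixed(
        trials,
        ACCURACY_FORMULA,
        "accuracy",
        random=("participant_id",),
        reml=True,
        name="accuracy_full",
    )


@dataclass
class PairwiseReport:
    """Matched-pair comparison of correct-decision RTs."""

    pairs: pd.DataFrame  # literal_id, metaphor_id, literal_rt, metaphor_rt, ...
    n_metaphor_advantage: int  # literal member slower
    n_literality_advantage: int
    p_relatedness_metaphor_advantage: float
    p_relatedness_literality_advantage: float
    n_excluded: int


def pairwise_advantage(
    match: MatchResult,
    trials: pd.DataFrame,
    scores: pd.DataFrame,
) -> PairwiseReport:
    """Per matched pair, compare mean correct RTs of the literal and
    metaphor members; within each advantage group, test whether the
    literal-minus-metaphor Relatedness differences differ from zero
    (two-tailed one-sample t-test).

    ``trials`` should already be trimmed; only correct responses enter the
    means. Pairs in which either member has no correct trial are excluded
    with a warning count.
    """
    correct = filter_correct(trials)
    mean_rt = correct.groupby("statement_id")["rt_ms"].mean()
    rel = scores.set_index("id")["relatedness"]

    rows = []
    n_excluded = 0
    for lit_id, met_id, dist in match.pairs:
        if lit_id not in mean_rt.index or met_id not in mean_rt.index:
            n_excluded += 1
            continue
        lit_rt = float(mean_rt[lit_id])
        met_rt = float(mean_rt[met_id])
        rows.append(
            {
                "literal_id": lit_id,
                "metaphor_id": met_id,
                "summed_difference": dist,
                "literal_rt": lit_rt,
                "metaphor_rt": met_rt,
                "metaphor_advantage": lit_rt > met_rt,
                "relatedness_diff": float(rel[lit_id] - rel[met_id]),
            }
        )
    if not rows:
        raise DataError("no matched pair has correct trials for both members")
    pairs = pd.DataFrame(rows)

    def _group_p(mask: pd.Series) -> float:
        diffs = pairs.loc[mask, "relatedness_diff"].to_numpy()
        if diffs.size < 2:
            return float("nan")
        return float(stats.ttest_1samp(diffs, 0.0).pvalue)

    adv = pairs["metaphor_advantage"]
    return PairwiseReport(
        pairs=pairs,
        n_metaphor_advantage=int(adv.sum()),
        n_literality_advantage=int((~adv).sum()),
        p_relatedness_metaphor_advantage=_group_p(adv),
        p_relatedness_literality_advantage=_group_p(~adv),
        n_excluded=n_excluded,
    )


def estimated_rt_correlation(
    model: ModelFit,
    items: pd.DataFrame,
    sentence_type: str,
    predictor: str = "relatedness",
) -> float:
    """Pearson r between per-item model-estimated responses (fixed effects
    only, random effects at their mean) and a predictor, within one
    sentence type."""
    subset = items[items["sentence_type"] == sentence_type]
    if len(subset) < 3:
        raise SizingError(
            f"need >= 3 items of type {sentence_type!r}, got {len(subset)}"
        )
    predicted = model.predict_fixed(subset)
    return float(stats.pearsonr(predicted, subset[predictor].to_numpy())[0])
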