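import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litmet import behavior_analysis as ba
from litmet.errors import DataError, SizingError
from litmet.stimuli import MatchResult
from litmet.synthetic_data import SimulationConfig, _DEFAULT_RT_EFFECTS

from helpers import (
    RT_TERM_TO_COEF,
    ACC_TERM_TO_COEF,
    coef_lookup,
    make_items,
    simulate_merged,
)
from oracles import oracle_pearson


def _trials(rts, accuracy=None, **extra):
    n = len(rts)
    base = {
        "participant_id": [f"p{i % 3}" for i in range(n)],
        "order": [(i % 5) + 1 for i in range(n)],
        "statement_id": [f"s{i % 4}" for i in range(n)],
        "sentence_type": ["literal" if i % 2 else "metaphor" for i in range(n)],
        "rt_ms": rts,
        "accuracy": accuracy if accuracy is not None else [1] * n,
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestTrimRts:
    def test_planted_fast_and_slow_counts(self, rng):
        clean = rng.uniform(800, 1200, 85).tolist()
        fast = rng.uniform(50, 399, 10).tolist()
        slow = rng.uniform(5001, 9000, 5).tolist()
        df = _trials(clean + fast + slow)
        retained, rep = ba.trim_rts(df)
        assert rep.n_fast_removed == 10
        assert rep.n_slow_removed == 5
        assert rep.n_sd_removed == 0  # clean block is tight
        assert rep.n_retained == 85
        assert len(retained) == 85

    def test_sd_stage_catches_within_bounds_outlier(self, rng):
        clean = rng.normal(1000, 30, 200).clip(800, 1200).tolist()
        df = _trials(clean + [4500.0])  # inside (400, 5000) but way out by SD
        retained, rep = ba.trim_rts(df)
        assert rep.n_fast_removed == 0 and rep.n_slow_removed == 0
        assert rep.n_sd_removed == 1
        assert 4500.0 not in retained["rt_ms"].values

    def test_stage2_stats_computed_on_stage1_survivors(self, rng):
        clean = rng.uniform(900, 1100, 50)
        df = _trials(clean.tolist() + [100.0, 7000.0])
        _, rep = ba.trim_rts(df)
        assert rep.mean_rt_after_absolute_trim == pytest.approx(clean.mean())
        assert rep.sd_rt_after_absolute_trim == pytest.approx(clean.std(ddof=1))

    def test_no_removals_when_all_in_range(self, rng):
        df = _trials(rng.uniform(900, 1100, 40).tolist())
        retained, rep = ba.trim_rts(df)
        assert rep.n_retained == rep.n_total == len(retained) == 40
        assert (
            rep.n_fast_removed == rep.n_slow_removed == rep.n_sd_removed == 0
        )

    def test_stage1_idempotent(self, rng):
        rts = np.concatenate(
            [
                rng.uniform(100, 9000, 300),
                rng.uniform(401, 4999, 100),
            ]
        )
        retained, _ = ba.trim_rts(_trials(rts.tolist()))
        _, rep2 = ba.trim_rts(retained)
        assert rep2.n_fast_removed == 0
        assert rep2.n_slow_removed == 0

    @settings(max_examples=40, deadline=None)
    @given(
        rts=st.lists(
            st.floats(min_value=1.0, max_value=20000.0, allow_nan=False),
            min_size=2,
            max_size=150,
        )
    )
    def test_counts_always_reconcile(self, rts):
        df = _trials(rts)
        if not any(400.0 <= r <= 5000.0 for r in rts):
            with pytest.raises(DataError):
                ba.trim_rts(df)
            return
        retained, rep = ba.trim_rts(df)
        assert rep.n_retained == len(retained)
        assert (
            rep.n_total
            == rep.n_retained
            + rep.n_fast_removed
            + rep.n_slow_removed
            + rep.n_sd_removed
        )

    def test_empty_input(self):
        with pytest.raises(DataError, match="empty"):
            ba.trim_rts(_trials([]))

    def test_nonpositive_rt(self):
        with pytest.raises(DataError):
            ba.trim_rts(_trials([500.0, -1.0]))


class TestFilterCorrect:
    def test_all_correct_unchanged(self):
        df = _trials([500.0] * 6)
        out = ba.filter_correct(df)
        assert len(out) == 6

    def test_three_incorrect_of_ten(self):
        df = _trials([500.0] * 10, accuracy=[1] * 7 + [0] * 3)
        assert len(ba.filter_correct(df)) == 7

    def test_missing_accuracy_raises(self):
        df = _trials([500.0] * 4)
        df.loc[2, "accuracy"] = np.nan
        with pytest.raises(DataError, match="accuracy"):
            ba.filter_correct(df)

    def test_preprocess_reports_incorrect_count(self, rng):
        rts = rng.uniform(900, 1100, 20).tolist() + [100.0]
        df = _trials(rts, accuracy=[1] * 15 + [0] * 6)
        correct, rep = ba.preprocess_trials(df)
        assert rep.n_fast_removed == 1
        assert rep.n_incorrect_removed == len(df) - 1 - rep.n_sd_removed - len(correct)
        assert rep.n_retained == len(correct)


class TestModelLadder:
    def test_single_model_trivially_accepted(self):
        items = make_items(20, seed=1)
        data = simulate_merged(items, SimulationConfig(n_participants=10, seed=1))
        ladder = ba.fit_model_ladder(
            data, [ba.ModelSpec("only", "z_cos", ("participant_id",))]
        )
        fit = ladder.fits[0]
        assert fit.accepted is True
        assert fit.aic_diff is None

    def test_planted_three_way_step_accepted(self):
        items = make_items(40, seed=7)
        cfg = SimulationConfig(
            n_participants=30, residual_sigma=0.3, subject_intercept_sd=300,
            order_intercept_sd=80, seed=42,
        )
        data = simulate_merged(items, cfg)
        ladder = ba.fit_model_ladder(data, ba.default_rt_ladder())
        m8 = ladder.fits[-1]
        assert m8.name == "M8"
        assert m8.accepted is True
        assert m8.aic_diff < 0

    def test_null_three_way_step_rejected_in_majority(self):
        # base model has everything but the three-way term; the step adds
        # only that term, whose planted coefficient is zero
        base = (
            "z_length1*z_length2 + (z_cos + z_relatedness + "
            "C(sentence_type, Treatment('metaphor')))**2"
        )
        full = ba.RT_FORMULA
        eff = dict(_DEFAULT_RT_EFFECTS)
        eff["z_cos:z_relatedness:sentence_type"] = 0.0
        items = make_items(40, seed=8)
        po = ("participant_id", "order")
        rejected = 0
        n_reps = 15
        for rep in range(n_reps):
            cfg = SimulationConfig(
                n_participants=20, fixed_effects=eff, residual_sigma=0.3,
                subject_intercept_sd=300, order_intercept_sd=80, seed=900 + rep,
            )
            data = simulate_merged(items, cfg)
            ladder = ba.fit_model_ladder(
                data,
                [ba.ModelSpec("base", base, po), ba.ModelSpec("plus3way", full, po)],
            )
            if not ladder.fits[1].accepted:
                rejected += 1
        assert rejected > n_reps / 2

    def test_ladder_frame_columns(self):
        items = make_items(20, seed=2)
        data = simulate_merged(items, SimulationConfig(n_participants=8, seed=3))
        ladder = ba.fit_model_ladder(data, ba.default_rt_ladder()[:3])
        frame = ladder.to_frame()
        assert list(frame["name"]) == ["M1", "M2", "M3"]
        assert frame["aic"].notna().all()

    def test_empty_ladder(self):
        with pytest.raises(DataError):
            ba.fit_model_ladder(pd.DataFrame({"rt_ms": [1.0]}), [])


class TestFitRtModel:
    def test_noise_free_recovery_to_machine_precision(self):
        items = make_items(80, seed=11)
        cfg = SimulationConfig(
            n_participants=12,
            subject_intercept_sd=0.0,
            order_intercept_sd=0.0,
            residual_sigma=0.0,
            seed=11,
        )
        data = simulate_merged(items, cfg)
        fit = ba.fit_rt_model(data)
        co = coef_lookup(fit)
        for term, true in cfg.fixed_effects.items():
            est = co[RT_TERM_TO_COEF[term]][0]
            assert est == pytest.approx(true, abs=1e-6)

    def test_metaphor_is_reference_level(self):
        items = make_items(20, seed=4)
        data = simulate_merged(items, SimulationConfig(n_participants=8, seed=5))
        fit = ba.fit_rt_model(data)
        assert any("[T.literal]" in t for t in fit.coefficients["term"])
        assert not any("[T.metaphor]" in t for t in fit.coefficients["term"])

    def test_r2_is_squared_fitted_observed_correlation(self):
        items = make_items(20, seed=6)
        data = simulate_merged(items, SimulationConfig(n_participants=8, seed=6))
        fit = ba.fit_rt_model(data)
        want = oracle_pearson(
            fit.result.fitted.tolist(), data["rt_ms"].tolist()
        ) ** 2
        assert fit.r2 == pytest.approx(want, abs=1e-10)
        assert 0.0 <= fit.r2 <= 1.0


class TestFitAccuracyModel:
    # effect sizes chosen so the linear-probability predictor stays inside
    # the [0.01, 0.99] clamp; otherwise clamping attenuates the estimates
    IN_RANGE_EFFECTS = {
        "intercept": 0.75,
        "z_relatedness": 0.06,
        "sentence_type": 0.05,
        "z_cos": -0.04,
        "z_length1": -0.03,
        "z_logfreq1": -0.02,
        "z_relatedness:sentence_type": -0.05,
        "z_cos:z_relatedness": 0.03,
        "z_cos:sentence_type": 0.03,
        "z_cos:z_relatedness:sentence_type": -0.03,
    }

    def test_all_correct_degenerate_input(self):
        items = make_items(10, seed=9)
        data = simulate_merged(items, SimulationConfig(n_participants=5, seed=9))
        data["accuracy"] = 1
        with pytest.raises(DataError, match="zero variance"):
            ba.fit_accuracy_model(data)

    def test_recovery_within_2se_scaled_replicates(self):
        # scaled-down version of the 100-replicate recovery study
        # (25 replicates, >= 21 required per coefficient ~ the 90% bar)
        items = make_items(80, seed=10)
        n_reps = 25
        cover = {t: 0 for t in self.IN_RANGE_EFFECTS}
        for rep in range(n_reps):
            cfg = SimulationConfig(
                n_participants=66,
                accuracy_fixed_effects=self.IN_RANGE_EFFECTS,
                accuracy_subject_sd=0.05,
                seed=2000 + rep,
            )
            data = simulate_merged(items, cfg)
            fit = ba.fit_accuracy_model(data)
            co = coef_lookup(fit)
            for term, true in self.IN_RANGE_EFFECTS.items():
                est, se, _ = co[ACC_TERM_TO_COEF[term]]
                if abs(est - true) <= 2 * se:
                    cover[term] += 1
        for term, n_ok in cover.items():
            assert n_ok >= 21, f"{term}: {n_ok}/{n_reps}"


class TestPairwiseAdvantage:
    @staticmethod
    def _fixture():
        # 4 matched pairs, 2 correct trials per statement, hand-set RTs
        match = MatchResult(
            pairs=(("L1", "M1", 0.1), ("L2", "M2", 0.2), ("L3", "M3", 0.1),
                   ("L4", "M4", 0.3)),
            mean_summed_difference=0.175,
            sd_summed_difference=0.0957,
            max_summed_difference=0.3,
        )
        rt = {
            "L1": [1000, 1100], "M1": [900, 950],   # literal slower -> metaphor adv
            "L2": [800, 820], "M2": [1200, 1300],   # literality advantage
            "L3": [1500, 1700], "M3": [1000, 1000],  # metaphor adv
            "L4": [700, 900], "M4": [850, 950],     # literality advantage
        }
        rows = []
        for sid, rts in rt.items():
            for i, r in enumerate(rts):
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "order": i + 1,
                        "statement_id": sid,
                        "sentence_type": "literal" if sid[0] == "L" else "metaphor",
                        "rt_ms": float(r),
                        "accuracy": 1,
                    }
                )
        trials = pd.DataFrame(rows)
        scores = pd.DataFrame(
            {
                "id": ["L1", "L2", "L3", "L4", "M1", "M2", "M3", "M4"],
                "relatedness": [0.5, 0.9, 0.55, 0.85, 0.4, 0.3, 0.43, 0.35],
                "sentence_type": ["literal"] * 4 + ["metaphor"] * 4,
            }
        )
        return match, trials, scores

    def test_hand_fixture_counts_and_means(self):
        match, trials, scores = self._fixture()
        rep = ba.pairwise_advantage(match, trials, scores)
        assert rep.n_metaphor_advantage == 2
        assert rep.n_literality_advantage == 2
        row = rep.pairs.set_index("literal_id").loc["L1"]
        assert row["literal_rt"] == pytest.approx(1050.0)
        assert row["metaphor_rt"] == pytest.approx(925.0)
        assert row["relatedness_diff"] == pytest.approx(0.5 - 0.4)

    def test_constructed_dominance_zero_metaphor_advantage(self):
        match, trials, scores = self._fixture()
        # make every literal strictly faster
        trials.loc[trials["sentence_type"] == "literal", "rt_ms"] = 500.0
        rep = ba.pairwise_advantage(match, trials, scores)
        assert rep.n_metaphor_advantage == 0
        assert rep.n_literality_advantage == 4

    def test_pair_without_correct_trials_excluded(self):
        match, trials, scores = self._fixture()
        trials.loc[trials["statement_id"] == "M4", "accuracy"] = 0
        rep = ba.pairwise_advantage(match, trials, scores)
        assert rep.n_excluded == 1
        assert len(rep.pairs) == 3

    def test_group_t_test_matches_scipy(self):
        from scipy import stats

        match, trials, scores = self._fixture()
        rep = ba.pairwise_advantage(match, trials, scores)
        adv = rep.pairs[rep.pairs["metaphor_advantage"]]
        want = stats.ttest_1samp(adv["relatedness_diff"].to_numpy(), 0.0).pvalue
        assert rep.p_relatedness_metaphor_advantage == pytest.approx(want)


class TestEstimatedRtCorrelation:
    @staticmethod
    def _fit_simple(slope):
        rng = np.random.default_rng(0)
        n = 60
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(6), 10),
                "order": np.tile(np.arange(10), 6) + 1,
                "z_relatedness": rng.normal(size=n),
            }
        )
        df["rt_ms"] = 1000.0 + slope * df["z_relatedness"]
        return ba.fit_mixed(
            df, "z_relatedness", "rt_ms", random=("participant_id",), name="simple"
        )

    @staticmethod
    def _items(n=8):
        rng = np.random.default_rng(1)
        z = np.sort(rng.normal(size=n))
        return pd.DataFrame(
            {
                "statement_id": [f"s{i}" for i in range(n)],
                "sentence_type": ["literal"] * n,
                "z_relatedness": z,
                "relatedness": 0.5 + 0.1 * z,  # monotone in the z predictor
            }
        )

    def test_strictly_increasing_gives_r_one(self):
        fit = self._fit_simple(slope=50.0)
        r = ba.estimated_rt_correlation(fit, self._items(), "literal", "relatedness")
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_pearson(self):
        fit = self._fit_simple(slope=-30.0)
        items = self._items(5)
        r = ba.estimated_rt_correlation(fit, items, "literal", "relatedness")
        pred = fit.predict_fixed(items)
        want = oracle_pearson(pred.tolist(), items["relatedness"].tolist())
        assert r == pytest.approx(want, abs=1e-12)

    def test_too_few_items(self):
        fit = self._fit_simple(slope=10.0)
        with pytest.raises(SizingError):
            ba.estimated_rt_correlation(
                fit, self._items(2), "literal", "relatedness"
            )
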