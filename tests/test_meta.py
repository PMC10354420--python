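"""Meta-analysis: study effects, heterogeneity, pooling, meta-regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from ckd_cea.errors import (
    DegenerateDesignError,
    InsufficientStudiesError,
    InvalidTrialError,
)
from ckd_cea.meta import (
    EffectEstimate,
    EffectPooler,
    TrialRecord,
    heterogeneity,
    meta_regress,
    pool,
    read_trials_csv,
    study_effect,
    trials_to_frame,
)
from conftest import make_trial


class TestStudyEffect:
    def test_hand_arithmetic(self):
        e = study_effect(make_trial(n=100, mean_trt=-20.0, mean_ctl=0.0, sd=10.0))
        assert e.md == -20.0
        assert e.se == pytest.approx(math.sqrt(2.0), rel=1e-12)
        assert e.ci_low == pytest.approx(-20.0 - 1.96 * math.sqrt(2.0))

    def test_equal_arms_give_zero_md(self):
        e = study_effect(make_trial(mean_trt=5.0, mean_ctl=5.0, sd=33.0))
        assert e.md == 0.0

    def test_doubling_n_halves_variance(self):
        e1 = study_effect(make_trial(n=50))
        e2 = study_effect(make_trial(n=100))
        assert e2.se**2 == pytest.approx(e1.se**2 / 2.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(n_trt=1), dict(sd_trt=0.0), dict(sd_ctl=-1.0), dict(n_ctl=0),
    ])
    def test_invalid_trial_rejected(self, bad):
        kw = dict(study_id="x", n_trt=10, mean_trt=0.0, sd_trt=1.0,
                  n_ctl=10, mean_ctl=0.0, sd_ctl=1.0)
        kw.update(bad)
        with pytest.raises(InvalidTrialError):
            TrialRecord(**kw)

    def test_se_back_computed_from_ci(self):
        e = EffectEstimate.from_ci(-19.01, -26.70, -11.32)
        assert e.se == pytest.approx((26.70 - 11.32) / (2 * 1.96))


class TestHeterogeneity:
    def test_two_study_oracle(self, two_effects):
        """Closed form: Q=2, df=1, tau2=1, I2=0.5 for effects (0,1) and (2,1)."""
        h = heterogeneity(two_effects)
        assert h.Q == pytest.approx(2.0, abs=1e-12)
        assert h.df == 1
        assert h.tau2 == pytest.approx(1.0, abs=1e-12)
        assert h.I2 == pytest.approx(0.5, abs=1e-12)

    def test_identical_effects_homogeneous(self):
        h = heterogeneity([EffectEstimate(1.0, 2.0), EffectEstimate(1.0, 2.0)])
        assert h.Q == 0.0 and h.I2 == 0.0 and h.tau2 == 0.0

    def test_requires_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            heterogeneity([EffectEstimate(0.0, 1.0)])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(0.1, 10)),
                    min_size=2, max_size=8))
    def test_truncation_bounds(self, pairs):
        h = heterogeneity([EffectEstimate(md, se) for md, se in pairs])
        assert h.tau2 >= 0.0
        assert 0.0 <= h.I2 < 1.0

    def test_brute_force_oracle_random_instances(self, rng):
        """Q, tau2, I2 re-derived from their defining formulas on 100
        random 3-study instances agree to 1e-9."""
        for _ in range(100):
            md = rng.normal(0, 10, size=3)
            se = rng.uniform(0.5, 5.0, size=3)
            h = heterogeneity([EffectEstimate(m, s) for m, s in zip(md, se)])
            w = 1.0 / se**2
            mbar = (w * md).sum() / w.sum()
            q = (w * (md - mbar) ** 2).sum()
            tau2 = max(0.0, (q - 2) / (w.sum() - (w**2).sum() / w.sum()))
            i2 = max(0.0, (q - 2) / q) if q > 0 else 0.0
            assert h.Q == pytest.approx(q, abs=1e-9)
            assert h.tau2 == pytest.approx(tau2, abs=1e-9)
            assert h.I2 == pytest.approx(i2, abs=1e-9)


class TestPool:
    def test_two_study_random_oracle(self, two_effects):
        r = pool(two_effects, rule="random")
        assert r.md == pytest.approx(1.0, abs=1e-12)
        assert r.se == pytest.approx(1.0, abs=1e-12)
        assert r.model == "random"

    def test_single_study_identity(self):
        e = EffectEstimate(-3.0, 0.5)
        r = pool([e])
        assert (r.md, r.se, r.model, r.k) == (-3.0, 0.5, "fixed", 1)

    def test_auto_selects_random_under_high_i2(self, rng):
        # substantial heterogeneity, like the pooled creatinine evidence
        effects = [EffectEstimate(float(rng.normal(-19, 20)), 2.0)
                   for _ in range(34)]
        r = pool(effects, rule="auto")
        assert r.I2 > 0.25
        assert r.model == "random"

    def test_auto_boundary_ties_go_random(self):
        # identical effects: p_Q = 1, I2 = 0 -> fixed is the only fixed case
        r = pool([EffectEstimate(1.0, 1.0), EffectEstimate(1.0, 1.0)], "auto")
        assert r.model == "fixed"

    def test_tau2_zero_makes_models_agree(self):
        effects = [EffectEstimate(1.0, 1.0), EffectEstimate(1.2, 1.0)]
        assert heterogeneity(effects).tau2 == 0.0
        rf = pool(effects, rule="fixed")
        rr = pool(effects, rule="random")
        assert rr.md == pytest.approx(rf.md, abs=1e-12)
        assert rr.se == pytest.approx(rf.se, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientStudiesError):
            pool([])

    def test_matches_statsmodels_dl(self, rng):
        """Independent oracle: statsmodels combine_effects with DL tau2."""
        md = rng.normal(-10, 8, size=12)
        se = rng.uniform(0.5, 4.0, size=12)
        mine = pool([EffectEstimate(m, s) for m, s in zip(md, se)], "random")
        sm_res = combine_effects(md, se**2, method_re="dl")
        assert mine.md == pytest.approx(float(sm_res.mean_effect_re), rel=1e-10)
        assert mine.tau2 == pytest.approx(float(sm_res.tau2), rel=1e-10)
        fixed = pool([EffectEstimate(m, s) for m, s in zip(md, se)], "fixed")
        assert fixed.md == pytest.approx(float(sm_res.mean_effect_fe), rel=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(-30, 30), st.floats(0.2, 5)),
                    min_size=2, max_size=10),
           st.sampled_from(["fixed", "random", "auto"]))
    def test_pooled_md_is_convex_combination(self, pairs, rule):
        effects = [EffectEstimate(md, se) for md, se in pairs]
        r = pool(effects, rule=rule)
        mds = [e.md for e in effects]
        assert min(mds) - 1e-9 <= r.md <= max(mds) + 1e-9

    def test_normalized_weights_sum_to_one(self, two_effects):
        effects = two_effects + [EffectEstimate(5.0, 0.3)]
        w = np.array([1.0 / e.se**2 for e in effects])
        assert abs((w / w.sum()).sum() - 1.0) < 1e-12
        r = pool(effects, rule="fixed")
        assert r.md == pytest.approx(float((w * [0, 2, 5]).sum() / w.sum()))


class TestMetaRegression:
    def test_recovers_exact_line(self):
        trials = [
            make_trial(f"t{i}", n=10_000, mean_trt=2.0 * x + 1.0, mean_ctl=0.0,
                       sd=0.1, mean_age=x)
            for i, x in enumerate([1.0, 2.0, 3.0, 4.0])
        ]
        r = meta_regress(trials, "mean_age")
        assert r.slope == pytest.approx(2.0, abs=1e-6)
        assert r.p_value < 1e-10

    def test_independent_covariate_not_significant(self):
        rng = np.random.default_rng(3)
        trials = [
            make_trial(f"s{i}", n=50, mean_trt=float(rng.normal(-19, 20)),
                       mean_ctl=0.0, sd=12.0,
                       mean_age=float(rng.uniform(38, 75)))
            for i in range(30)
        ]
        r = meta_regress(trials, "mean_age")
        assert r.p_value > 0.05

    def test_constant_covariate_is_degenerate(self):
        trials = [make_trial(f"t{i}", mean_age=50.0) for i in range(5)]
        with pytest.raises(DegenerateDesignError):
            meta_regress(trials, "mean_age")

    def test_needs_three_trials(self):
        trials = [make_trial(f"t{i}", mean_age=float(i)) for i in range(2)]
        with pytest.raises(InsufficientStudiesError):
            meta_regress(trials, "mean_age")


class TestEstimatorAndIO:
    def test_effect_pooler_fit_attributes(self, rng):
        trials = [make_trial(f"t{i}", mean_trt=float(rng.normal(-19, 5)))
                  for i in range(6)]
        p = EffectPooler(rule="auto").fit(trials)
        assert p.model_ in ("fixed", "random")
        assert p.md_ == p.result_.md
        assert len(p.effects_) == 6
        assert p.get_params() == {"rule": "auto"}

    def test_csv_roundtrip(self, tmp_path, rng):
        trials = [
            make_trial(f"t{i}", mean_trt=float(rng.normal(-19, 5)),
                       sample_size=200.0, mean_age=55.0 + i, male_prop=0.6,
                       dis_duration=5.0, trt_duration=12.0)
            for i in range(4)
        ]
        path = tmp_path / "trials.csv"
        trials_to_frame(trials).to_csv(path, index=False)
        back = read_trials_csv(path)
        assert [t.study_id for t in back] == [t.study_id for t in trials]
        assert back[2].mean_trt == pytest.approx(trials[2].mean_trt)
        assert back[1].covariates["mean_age"] == pytest.approx(56.0)
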