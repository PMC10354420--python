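"""Markov cohort model: matrix construction, trace, payoffs, comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckd_cea.errors import ConfigError, InfeasibleMatrixError
from ckd_cea.markov import (
    STATES,
    ModelConfig,
    Payoffs,
    annual_drug_cost,
    build_matrix,
    compare,
    run_trace,
)

UNIT_UTILS = Payoffs(costs={}, utilities={s: 1.0 for s in STATES[:4]})
MORT0 = {s: 0.0 for s in STATES[:4]}


class TestDrugCost:
    def test_published_dosing_arithmetic(self):
        # CNY 43.26 per 42 tablets, 12/day, 365 days, compliance 92.75%
        cost = annual_drug_cost(43.26, 42, 12, 0.9275, 365)
        assert cost == pytest.approx(4184.3235, abs=0.01)

    def test_per_tablet_identity(self):
        assert annual_drug_cost(42.0, 42, 1, 1.0, 1) == pytest.approx(1.0)

    def test_linear_in_compliance(self):
        assert annual_drug_cost(50.0, 10, 2, 0.8, 100) == \
            pytest.approx(2 * annual_drug_cost(50.0, 10, 2, 0.4, 100))

    def test_compliance_bounds(self):
        with pytest.raises(ConfigError):
            annual_drug_cost(50.0, 10, 2, 0.0, 100)
        with pytest.raises(ConfigError):
            annual_drug_cost(50.0, 10, 2, 1.2, 100)


class TestBuildMatrix:
    def test_hemodialysis_split_on_published_fraction(self):
        m = build_matrix(0.0, 0.2, MORT0, hd_fraction=0.891)
        row = m[STATES.index("ckd4")]
        assert row[STATES.index("ckd5_hd")] == pytest.approx(0.1782, abs=1e-12)
        assert row[STATES.index("ckd5_nohd")] == pytest.approx(0.0218, abs=1e-12)
        assert row[STATES.index("ckd4")] == pytest.approx(0.8, abs=1e-12)

    def test_all_zero_probabilities_identity_like(self):
        m = build_matrix(0.0, 0.0, MORT0, 0.891)
        assert np.allclose(m, np.eye(5))

    def test_death_first_ordering(self):
        m = build_matrix(0.5, 0.0, {"ckd3": 0.2, "ckd4": 0.0,
                                    "ckd5_nohd": 0.0, "ckd5_hd": 0.0}, 0.891)
        i = STATES.index("ckd3")
        assert m[i, STATES.index("death")] == pytest.approx(0.2)
        assert m[i, STATES.index("ckd4")] == pytest.approx(0.5 * 0.8)

    def test_progression_first_infeasible_when_sum_exceeds_one(self):
        with pytest.raises(InfeasibleMatrixError):
            build_matrix(0.7, 0.0, {"ckd3": 0.5, "ckd4": 0.0,
                                    "ckd5_nohd": 0.0, "ckd5_hd": 0.0},
                         0.891, ordering="progression_first")

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(InfeasibleMatrixError):
            build_matrix(1.2, 0.0, MORT0, 0.891)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1), st.floats(0, 1))
    def test_rows_always_stochastic(self, p34, p45, m3, m4, hd):
        m = build_matrix(p34, p45, {"ckd3": m3, "ckd4": m4,
                                    "ckd5_nohd": 0.1, "ckd5_hd": 0.1}, hd)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m.min() >= 0.0 and m.max() <= 1.0
        # no transitions to earlier stages: lower triangle empty
        assert np.allclose(np.tril(m, -1), 0.0)


class TestRunTrace:
    def test_half_cycle_constant_utility_totals_horizon(self):
        """Identity matrix, utility 1, r=0: total QALYs = 1/2 + 19 + 1/2 = 20."""
        trace = run_trace(np.eye(5), UNIT_UTILS,
                          ModelConfig(horizon=20, discount_rate=0.0))
        assert trace.total_qalys == pytest.approx(20.0, abs=1e-12)

    def test_end_of_cycle_discounting_matches_annuity(self):
        """Without half-cycle weighting, a unit utility stream discounted at
        5% over 20 years is the closed-form annuity (1 - 1.05^-20)/0.05."""
        trace = run_trace(np.eye(5), UNIT_UTILS,
                          ModelConfig(horizon=20, discount_rate=0.05,
                                      half_cycle=False))
        annuity = (1.0 - 1.05**-20) / 0.05
        assert trace.total_qalys == pytest.approx(annuity, abs=1e-9)
        assert trace.total_qalys == pytest.approx(12.4622, abs=1e-4)

    def test_occupancy_conserved_and_death_monotone(self):
        m = build_matrix(0.1, 0.2, {"ckd3": 0.02, "ckd4": 0.05,
                                    "ckd5_nohd": 0.25, "ckd5_hd": 0.12}, 0.891)
        trace = run_trace(m, UNIT_UTILS, ModelConfig(horizon=20))
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        death = trace.occupancy[:, STATES.index("death")]
        assert (np.diff(death) >= -1e-15).all()

    def test_discounting_never_increases_totals(self):
        m = build_matrix(0.1, 0.2, {"ckd3": 0.02, "ckd4": 0.05,
                                    "ckd5_nohd": 0.25, "ckd5_hd": 0.12}, 0.891)
        pay = Payoffs(costs={s: 1000.0 for s in STATES[:4]},
                      utilities={s: 0.7 for s in STATES[:4]})
        undisc = run_trace(m, pay, ModelConfig(horizon=20, discount_rate=0.0))
        disc = run_trace(m, pay, ModelConfig(horizon=20, discount_rate=0.05))
        assert disc.total_cost < undisc.total_cost
        assert disc.total_qalys < undisc.total_qalys

    def test_slower_progression_never_loses_qalys(self):
        mort = {"ckd3": 0.02, "ckd4": 0.05, "ckd5_nohd": 0.25, "ckd5_hd": 0.12}
        pay = Payoffs(costs={}, utilities={"ckd3": 0.76, "ckd4": 0.65,
                                           "ckd5_nohd": 0.45, "ckd5_hd": 0.52})
        q = [run_trace(build_matrix(p, 0.2, mort, 0.891), pay,
                       ModelConfig(horizon=20)).total_qalys
             for p in (0.05, 0.10, 0.20)]
        assert q[0] > q[1] > q[2]

    def test_initial_must_be_distribution(self):
        with pytest.raises(ConfigError):
            run_trace(np.eye(5), UNIT_UTILS, ModelConfig(), initial=[0.5] * 5)

    def test_trace_dataframe_shape(self):
        trace = run_trace(np.eye(5), UNIT_UTILS, ModelConfig(horizon=5))
        df = trace.to_dataframe()
        assert list(df["cycle"]) == list(range(6))
        assert set(STATES) <= set(df.columns)


class TestPayoffs:
    def test_death_pinned_to_zero(self):
        p = Payoffs(costs={"death": 100.0}, utilities={"death": 1.0})
        assert p.costs["death"] == 0.0 and p.utilities["death"] == 0.0

    def test_utility_range_enforced(self):
        with pytest.raises(ConfigError):
            Payoffs(costs={}, utilities={"ckd3": 1.5})

    def test_extra_cost_only_touches_named_states(self):
        p = Payoffs(costs={s: 10.0 for s in STATES[:4]},
                    utilities={s: 0.5 for s in STATES[:4]})
        q = p.with_extra_cost({"ckd3": 5.0})
        assert q.costs["ckd3"] == 15.0 and q.costs["ckd4"] == 10.0


class TestCompare:
    def test_icer_from_printed_increments(self):
        """dCost 24,721 over dQALY 0.39 is ~63,387 CNY/QALY at printed
        precision (an unrounded dQALY near 0.3924 reproduces ~63,001)."""
        r = compare((301_999.0, 4.04), (326_720.0, 4.43), wtp=80_976.0)
        assert r.delta_cost == pytest.approx(24_721.0)
        assert r.icer == pytest.approx(24_721.0 / 0.39, rel=1e-9)
        assert r.icer == pytest.approx(63_387.2, abs=0.1)
        assert r.cost_effective  # ICER below the WTP threshold

    def test_nmb_arithmetic(self):
        r = compare((0.0, 0.0), (24_721.0, 0.39), wtp=80_976.0)
        assert r.nmb == pytest.approx(80_976.0 * 0.39 - 24_721.0, rel=1e-12)
        assert r.nmb == pytest.approx(6_859.64, abs=0.01)

    def test_dominance_flag_suppresses_icer(self):
        r = compare((10.0, 1.0), (9.0, 1.1), wtp=1.0)
        assert r.dominant and r.icer is None and r.cost_effective

    def test_dominated_flag(self):
        r = compare((10.0, 1.0), (20.0, 0.5), wtp=1.0)
        assert r.dominated and r.icer is None and not r.cost_effective

    def test_identical_arms_are_a_wash(self):
        r = compare((100.0, 2.0), (100.0, 2.0), wtp=50_000.0)
        assert r.delta_cost == 0.0 and r.delta_qaly == 0.0
        assert r.icer is None and r.nmb == 0.0
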