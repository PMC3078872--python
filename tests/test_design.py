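"""Design solver: critical values, event targets and published design tables."""

import math
import warnings

import pytest

from tamsdesign import (
    DesignSpec,
    attained_power,
    build_design,
    critical_hr,
    initial_events,
    variance_alt,
    variance_null,
)


class TestVarianceFormulas:
    def test_null_variance_values(self):
        assert variance_null(264, 1.0) == pytest.approx(0.0075758, abs=1e-6)
        assert variance_null(140, 1.0) == pytest.approx(0.0142857, abs=1e-6)

    def test_single_arm_limit(self):
        # A -> infinity: all information from the control arm
        assert variance_null(200, 1e9) == pytest.approx(1 / 200, rel=1e-6)

    def test_alt_variance_values(self):
        assert variance_alt(264, 222) == pytest.approx(0.0082924, abs=1e-6)
        assert variance_alt(73, 60) == pytest.approx(0.030366, abs=1e-5)
        assert variance_alt(50, 50) == pytest.approx(2 / 50)

    @pytest.mark.parametrize("fn, args", [
        (variance_null, (0, 1.0)),
        (variance_null, (100, 0.0)),
        (variance_alt, (0, 10)),
        (variance_alt, (10, 0)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestCriticalHR:
    def test_level_half_gives_null_hr(self):
        assert critical_hr(0.5, 0.123) == pytest.approx(1.0)
        assert critical_hr(0.5, 0.05, hr_null=0.9) == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "alpha, e, expected",
        [
            (0.025, 262, 0.843),  # final stage of the 4-stage single-outcome design
            (0.25, 140, 0.923),  # stage 2
            (0.1, 217, 0.884),  # stage 3
        ],
    )
    def test_published_critical_values(self, alpha, e, expected):
        delta = critical_hr(alpha, math.sqrt(variance_null(e, 1.0)))
        assert round(delta, 3) == expected

    def test_probability_interpretation(self):
        # P(estimate below delta | H0) = alpha by construction
        from scipy.stats import norm

        sigma0 = 0.12
        delta = critical_hr(0.1, sigma0, hr_null=1.0)
        assert norm.cdf(math.log(delta) / sigma0) == pytest.approx(0.1, abs=1e-12)


class TestAttainedPower:
    def test_threshold_at_alternative_gives_half(self):
        assert attained_power(0.75, 0.75, 0.2) == pytest.approx(0.5)

    def test_published_stage_powers(self):
        p1 = attained_power(1.0, 0.75, math.sqrt(variance_alt(73, 60)))
        assert p1 == pytest.approx(0.95, abs=0.005)
        delta4 = critical_hr(0.025, math.sqrt(variance_null(264, 1.0)))
        p4 = attained_power(delta4, 0.75, math.sqrt(variance_alt(264, 222)))
        assert p4 == pytest.approx(0.90, abs=0.005)


class TestInitialEvents:
    def test_standard_two_arm_count(self):
        # ceil of 2 * (z_0.9 + z_0.975)^2 / ln(4/3)^2 = ceil(253.9)
        assert initial_events(0.025, 0.9, 1.0, 0.75, 1.0) == 254

    def test_zero_numerator_clamped(self):
        assert initial_events(0.5, 0.5, 1.0, 0.75, 1.0) == 1

    def test_unequal_allocation(self):
        assert initial_events(0.5, 0.95, 1.0, 0.75, 0.5) == 99

    def test_alternative_must_beat_null(self):
        with pytest.raises(ValueError):
            initial_events(0.025, 0.9, 1.0, 1.1, 1.0)


class TestPublishedDesigns:
    def test_four_stage_two_outcome_equal_allocation(self):
        """Worked 4-stage design, A=1, total accrual 200/yr: events, totals, times."""
        spec = DesignSpec(
            4,
            (0.5, 0.25, 0.125, 0.025),
            (0.95, 0.95, 0.95, 0.9),
            0.75,
            accrual=200,
            accrual_basis="total",
            hazard_I=0.693,
            hazard_D=0.347,
        )
        res = build_design(spec)
        assert res.e_control == (73, 139, 198, 264)
        for t, expected in zip(res.times, (1.7, 2.6, 3.3, 5.0)):
            assert t == pytest.approx(expected, abs=0.1)
        for st, expected in zip(res.stages, (133, 256, 369, 486)):
            assert st.e_total_alt == pytest.approx(expected, abs=1.5)
        assert res.total_patients == pytest.approx(1000, abs=10)

    def test_four_stage_two_outcome_unequal_allocation(self):
        spec = DesignSpec(
            4,
            (0.5, 0.25, 0.125, 0.025),
            (0.95, 0.95, 0.95, 0.9),
            0.75,
            allocation=0.5,
            accrual=200,
            accrual_basis="total",
            hazard_I=0.693,
            hazard_D=0.347,
        )
        res = build_design(spec)
        assert res.e_control[-1] == 399
        assert abs(res.e_control[1] - 211) <= 1  # printed value sits on a rounding boundary
        assert res.stages[-1].e_total_alt == pytest.approx(568, abs=1.5)
        assert res.times[-1] == pytest.approx(5.4, abs=0.1)

    def test_three_stage_design_events_and_times(self, table4a_design):
        e = table4a_design.e_control
        assert abs(e[0] - 73) <= 1
        assert e[1] == 140
        assert abs(e[2] - 264) <= 1
        assert table4a_design.times[0] == pytest.approx(1.53, abs=0.02)
        # cumulative stage times 1.53, 2.27, 4.37
        assert table4a_design.times[1] == pytest.approx(2.27, abs=0.02)
        assert table4a_design.times[2] == pytest.approx(4.37, abs=0.03)
        assert [round(d, 3) for d in table4a_design.deltas] == [1.0, 0.923, 0.843]

    def test_four_stage_single_outcome(self, table8_design):
        e = table8_design.e_control
        assert abs(e[0] - 73) <= 1
        assert e[1:] == (140, 217, 262)
        assert [round(d, 3) for d in table8_design.deltas] == [1.0, 0.923, 0.884, 0.843]

    def test_single_stage_reduces_to_one_look_trial(self):
        spec = DesignSpec(1, 0.025, 0.9, 0.75, accrual=250, hazard_I=0.347, hazard_D=0.347)
        res = build_design(spec)
        assert len(res.stages) == 1
        st = res.stages[0]
        assert st.outcome_kind == "D"
        # one-look event count: slightly above the closed-form initial estimate
        assert initial_events(0.025, 0.9, 1.0, 0.75, 1.0) <= st.e_control <= 270
        assert st.power_marginal >= 0.9


class TestDesignProperties:
    def test_event_targets_are_minimal(self, table4a_design, power_at_events):
        """One event fewer at any stage drops the attained power below nominal."""
        for st in table4a_design.stages:
            assert st.power_marginal >= st.omega
            lower = power_at_events(table4a_design, st.index, st.e_control - 1)
            assert lower < st.omega

    def test_monotone_response_to_alpha_and_omega(self):
        def solve(alpha_last, omega_last):
            spec = DesignSpec(
                2,
                (0.5, alpha_last),
                (0.95, omega_last),
                0.75,
                accrual=125,
                hazard_I=0.693,
                hazard_D=0.347,
            )
            return build_design(spec).e_control[-1]

        base = solve(0.1, 0.85)
        assert solve(0.05, 0.85) >= base  # stricter level
        assert solve(0.1, 0.95) >= base  # higher power

    def test_timing_scale_equivariance(self, table4a_design):
        """Hazards x k with rates x k: identical e and delta, times / k."""
        k = 2.5
        spec = table4a_design.spec
        scaled = DesignSpec(
            3,
            spec.alpha,
            spec.omega,
            spec.hr_alt,
            accrual=tuple(k * r for r in spec.accrual),
            hazard_I=k * spec.hazard_I,
            hazard_D=k * spec.hazard_D,
        )
        res = build_design(scaled)
        assert res.e_control == table4a_design.e_control
        assert res.deltas == pytest.approx(table4a_design.deltas, rel=1e-12)
        assert res.times == pytest.approx(
            tuple(t / k for t in table4a_design.times), rel=1e-6
        )

    def test_delta_bounded_by_null_hr(self, table8_design):
        for st in table8_design.stages:
            assert st.delta <= 1.0
            if st.alpha == 0.5:
                assert st.delta == pytest.approx(1.0)


class TestValidation:
    def test_ascending_alpha_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            DesignSpec(2, (0.1, 0.25), (0.95, 0.9), 0.75, accrual=100,
                       hazard_I=0.7, hazard_D=0.35)

    def test_alternative_must_be_below_null(self):
        with pytest.raises(ValueError, match="hr_alt"):
            DesignSpec(2, (0.5, 0.025), (0.95, 0.9), 1.2, accrual=100,
                       hazard_I=0.7, hazard_D=0.35)

    def test_many_stages_warns(self):
        with pytest.warns(UserWarning, match="6 stages"):
            DesignSpec(7, (0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.025),
                       0.95, 0.75, accrual=100, hazard_I=0.7, hazard_D=0.35)

    def test_intermediate_hazard_below_definitive_warns(self):
        with pytest.warns(UserWarning, match="at least as often"):
            DesignSpec(2, (0.5, 0.025), (0.95, 0.9), 0.75, accrual=100,
                       hazard_I=0.2, hazard_D=0.35)

    def test_degenerate_design_is_flagged_not_fatal(self):
        """Tight late alpha on a single outcome: a stage of zero length."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = DesignSpec(3, (0.1, 0.05, 0.025), (0.95, 0.95, 0.9), 0.75,
                              accrual=125, hazard_I=0.693, hazard_D=0.693)
        res = build_design(spec)
        assert res.degenerate
        assert "zero length" in res.message
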