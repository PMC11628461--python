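"""Unit and property tests for the single-compartment mechanics functions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventpower import (
    DeadSpaceViolationError,
    DegenerateExpirationError,
    InvalidParameterError,
    RespiratoryMechanics,
    VentilationPattern,
    breath_timing,
    elastic_power,
    intrinsic_peep,
    mechanical_power,
    plateau_pressure,
    rate_from_alveolar_ventilation,
    time_constant,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def mech(e=10.0, r_aw=1.0, r_tube=7.0, v_d=0.2):
    return RespiratoryMechanics(
        elastance=e, airway_resistance=r_aw, tube_resistance=r_tube, dead_space=v_d
    )


class TestTimeConstant:
    @pytest.mark.parametrize(
        "e, r_aw, r_tube, expected",
        [
            (10.0, 1.0, 7.0, 0.8),   # normal lung, 8-mm tube
            (1.0, 1.0, 0.0, 1.0),    # identity case
            (20.0, 1.0, 12.0, 0.65), # stiff lung, 7-mm tube
        ],
    )
    def test_tau_is_resistance_over_elastance(self, e, r_aw, r_tube, expected):
        assert time_constant(mech(e, r_aw, r_tube)) == pytest.approx(expected, rel=1e-12)

    def test_zero_resistance_gives_zero_tau(self):
        assert time_constant(mech(r_aw=0.0, r_tube=0.0)) == 0.0

    @pytest.mark.parametrize("field", ["elastance", "dead_space"])
    def test_nonpositive_required_parameters_rejected(self, field):
        kwargs = dict(elastance=10.0, airway_resistance=1.0, tube_resistance=7.0,
                      dead_space=0.2)
        kwargs[field] = 0.0
        with pytest.raises(InvalidParameterError):
            RespiratoryMechanics(**kwargs)

    def test_negative_resistance_rejected(self):
        with pytest.raises(InvalidParameterError):
            mech(r_aw=-1.0)


class TestBreathTiming:
    @pytest.mark.parametrize(
        "rr, ie, t_in, t_ex",
        [(10.0, 1.0, 3.0, 3.0), (20.0, 0.5, 1.0, 2.0), (15.0, 2.0, 8.0 / 3.0, 4.0 / 3.0)],
    )
    def test_cycle_split(self, rr, ie, t_in, t_ex):
        got_in, got_ex = breath_timing(rr, ie)
        assert got_in == pytest.approx(t_in, rel=1e-12)
        assert got_ex == pytest.approx(t_ex, rel=1e-12)

    @given(rr=st.floats(1.0, 60.0), ie=st.floats(0.05, 10.0))
    def test_defining_relations_hold(self, rr, ie):
        t_in, t_ex = breath_timing(rr, ie)
        assert t_in + t_ex == pytest.approx(60.0 / rr, rel=1e-12)
        assert t_in / t_ex == pytest.approx(ie, rel=1e-9)

    def test_pattern_timing_matches_free_function(self):
        pattern = VentilationPattern(tidal_volume=0.5, respiratory_rate=15, ie_ratio=0.7)
        t_in, t_ex = breath_timing(15, 0.7)
        assert pattern.inspiratory_time == pytest.approx(t_in, rel=1e-15)
        assert pattern.expiratory_time == pytest.approx(t_ex, rel=1e-15)

    @pytest.mark.parametrize("rr, ie", [(0.0, 1.0), (10.0, 0.0), (-5.0, 1.0)])
    def test_nonpositive_inputs_rejected(self, rr, ie):
        with pytest.raises(InvalidParameterError):
            breath_timing(rr, ie)


class TestIntrinsicPeep:
    def test_long_expiration_recovers_external_peep(self):
        m = mech()
        tau = time_constant(m)
        # rr such that t_ex = 100 tau with ie = 1
        rr = 60.0 / (2 * 100 * tau)
        pattern = VentilationPattern(0.5, rr, 1.0, external_peep=3.0)
        assert intrinsic_peep(m, pattern) == pytest.approx(3.0, abs=1e-10)

    def test_half_life_expiration_gives_unit_ratio(self):
        # t_ex = tau ln 2 makes x = 1/2 and x/(1-x) = 1: iPEEP = E V_T
        m = mech(e=10.0, r_aw=8.0, r_tube=0.0)
        tau = time_constant(m)
        t_ex = tau * math.log(2.0)
        rr = 60.0 / (2 * t_ex)
        pattern = VentilationPattern(0.5, rr, 1.0, external_peep=0.0)
        assert intrinsic_peep(m, pattern) == pytest.approx(5.0, rel=1e-12)

    def test_strictly_above_external_peep_for_finite_expiration(self):
        m = mech()
        pattern = VentilationPattern(0.5, 15.0, 1.0, external_peep=2.0)
        assert intrinsic_peep(m, pattern) > 2.0

    def test_monotone_decreasing_in_expiratory_time(self):
        m = mech()
        values = [
            intrinsic_peep(m, VentilationPattern(0.5, rr, 1.0))
            for rr in (30.0, 20.0, 12.0, 6.0)  # decreasing rate = increasing t_ex
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize(
        "grow", ["resistance", "elastance_volume", "rate"],
    )
    def test_strictly_increasing_in_drivers(self, grow):
        """iPEEP build-up grows with R, with E*V_T, and with rr at fixed I:E."""
        def value(scale):
            if grow == "resistance":
                m = mech(r_tube=7.0 * scale)
                pattern = VentilationPattern(0.5, 15.0, 1.0)
            elif grow == "elastance_volume":
                # raise E and V_T together at fixed R so E*V_T grows but tau shifts too;
                # keep tau fixed by scaling R with E
                m = mech(e=10.0 * scale, r_aw=1.0 * scale, r_tube=7.0 * scale)
                pattern = VentilationPattern(0.5, 15.0, 1.0)
            else:
                m = mech()
                pattern = VentilationPattern(0.5, 15.0 * scale, 1.0)
            return intrinsic_peep(m, pattern)

        assert value(1.0) < value(1.5) < value(2.0)

    def test_zero_resistance_is_analytic_limit(self):
        m = mech(r_aw=0.0, r_tube=0.0)
        pattern = VentilationPattern(0.5, 15.0, 1.0, external_peep=4.0)
        assert intrinsic_peep(m, pattern) == 4.0

    def test_degenerate_expiration_raises_instead_of_overflow(self):
        m = mech(e=1.0, r_aw=0.0, r_tube=1e10)  # tau = 1e10 s
        pattern = VentilationPattern(0.5, 60.0, 1e6)  # t_ex ~ 1e-6 s, ratio ~ 1e-16
        with pytest.raises(DegenerateExpirationError):
            intrinsic_peep(m, pattern)


class TestRateFromAlveolarVentilation:
    @pytest.mark.parametrize(
        "v_alv, v_t, v_d, expected",
        [(10.0, 0.4, 0.2, 50.0), (10.0, 1.2, 0.2, 10.0)],
    )
    def test_constraint(self, v_alv, v_t, v_d, expected):
        assert rate_from_alveolar_ventilation(v_alv, v_t, v_d) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("v_t", [0.2, 0.15])
    def test_tidal_volume_at_or_below_dead_space_rejected(self, v_t):
        with pytest.raises(DeadSpaceViolationError):
            rate_from_alveolar_ventilation(10.0, v_t, 0.2)

    def test_diverges_approaching_dead_space(self):
        near = rate_from_alveolar_ventilation(10.0, 0.2002, 0.2)
        far = rate_from_alveolar_ventilation(10.0, 0.4, 0.2)
        assert near > 100 * far


class TestMechanicalPower:
    def test_pure_elastic_limit(self):
        """R = 0 and PEEP = 0: total power reduces to the elastic term."""
        m = mech(r_aw=0.0, r_tube=0.0)
        pattern = VentilationPattern(0.5, 12.0, 1.0)
        power = mechanical_power(m, pattern)
        assert power.resistive == 0.0
        assert power.ipeep == 0.0
        assert power.total == pytest.approx(1.5, rel=1e-12)

    @given(
        v_t=st.floats(0.25, 1.5),
        rr=st.floats(5.0, 40.0),
        ie=st.floats(0.2, 3.0),
        r_total=st.floats(0.5, 25.0),
    )
    def test_resistive_term_two_forms_agree(self, v_t, rr, ie, r_total):
        """rr(1+r)/(60 r) R V_T^2 is algebraically R * (V_T/t_in) * V_T."""
        m = mech(r_aw=r_total, r_tube=0.0)
        pattern = VentilationPattern(v_t, rr, ie)
        power = mechanical_power(m, pattern)
        flow_form = 0.1 * rr * r_total * pattern.inspiratory_flow * v_t
        assert power.resistive == pytest.approx(flow_form, rel=1e-12)

    @given(
        v_t=st.floats(0.25, 1.5),
        rr=st.floats(5.0, 30.0),
        ie=st.floats(0.3, 3.0),
        peep=st.floats(0.0, 10.0),
    )
    def test_decomposition_sums_and_components_nonnegative(self, v_t, rr, ie, peep):
        power = mechanical_power(mech(), VentilationPattern(v_t, rr, ie, peep))
        assert power.total == pytest.approx(
            power.elastic + power.resistive + power.ipeep, rel=1e-12
        )
        assert min(power.elastic, power.resistive, power.ipeep) >= 0.0

    def test_power_above_peep_flag_removes_external_baseline(self):
        m = mech()
        pattern = VentilationPattern(0.5, 15.0, 1.0, external_peep=5.0)
        full = mechanical_power(m, pattern)
        above = mechanical_power(m, pattern, power_above_peep=True)
        baseline = 0.1 * 15.0 * 5.0 * 0.5  # 0.1 rr PEEP V_T
        assert full.ipeep - above.ipeep == pytest.approx(baseline, rel=1e-12)
        assert full.elastic == above.elastic and full.resistive == above.resistive

    @pytest.mark.parametrize("driver", ["elastance", "resistance", "v_alv"])
    def test_total_power_strictly_increasing_in_drivers(self, driver):
        def total(scale):
            e = 10.0 * scale if driver == "elastance" else 10.0
            r = 8.0 * scale if driver == "resistance" else 8.0
            v_alv = 10.0 * scale if driver == "v_alv" else 10.0
            m = mech(e=e, r_aw=0.0, r_tube=r)
            rr = rate_from_alveolar_ventilation(v_alv, 0.5, 0.2)
            return mechanical_power(m, VentilationPattern(0.5, rr, 1.0)).total

        assert total(1.0) < total(1.3) < total(1.6)

    def test_all_components_diverge_near_dead_space(self):
        """With the rate tied to alveolar ventilation, every component blows
        up as V_T approaches the dead space."""
        m = mech()
        v_d = m.dead_space

        def breakdown(v_t):
            rr = rate_from_alveolar_ventilation(10.0, v_t, v_d)
            return mechanical_power(m, VentilationPattern(v_t, rr, 1.0))

        near = breakdown(v_d * 1.001)
        far = breakdown(2 * v_d)
        assert near.elastic >= 10 * far.elastic
        assert near.resistive >= 10 * far.resistive
        assert near.ipeep >= 10 * far.ipeep


class TestElasticPower:
    def test_value_at_elastic_optimum_point(self):
        # V_T = 0.4 L with rr = 50/min from the ventilation constraint
        assert elastic_power(10.0, 0.4, 50.0) == pytest.approx(4.0, rel=1e-12)

    def test_zero_elastance_gives_zero_power(self):
        assert elastic_power(0.0, 0.5, 12.0) == 0.0

    def test_quadratic_in_tidal_volume(self):
        assert elastic_power(10.0, 0.8, 12.0) == pytest.approx(
            4 * elastic_power(10.0, 0.4, 12.0), rel=1e-12
        )

    @given(ie=st.floats(0.1, 4.0))
    def test_bit_identical_under_ie_changes(self, ie):
        """Elastic power never depends on the flow waveform timing."""
        m = mech()
        reference = mechanical_power(m, VentilationPattern(0.5, 15.0, 1.0)).elastic
        other = mechanical_power(m, VentilationPattern(0.5, 15.0, ie)).elastic
        assert other == reference  # exact, not approx


class TestPlateauPressure:
    @pytest.mark.parametrize(
        "e, v_t, ipeep, expected",
        [(10.0, 0.5, 0.0, 5.0), (10.0, 0.0, 2.5, 2.5), (20.0, 0.3, 2.0, 8.0)],
    )
    def test_linear_superposition(self, e, v_t, ipeep, expected):
        assert plateau_pressure(mech(e=e), v_t, ipeep) == pytest.approx(expected, rel=1e-12)
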