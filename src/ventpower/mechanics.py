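"""Single-compartment respiratory mechanics and mechanical power.

The respiratory system is modelled as a linear RC compartment: an elastic
balloon with constant elastance ``E`` (lung plus chest wall, mbar/L) filled
through a constant resistance ``R`` (airway plus endotracheal tube,
mbar/L/s).  Ventilation is volume-controlled with constant inspiratory flow;
during expiration the ventilator holds airway pressure at the external PEEP
and the lung empties passively with time constant ``tau = R/E``.

Unit conventions, fixed package-wide and never converted implicitly:
volumes L, pressures mbar, resistance mbar/L/s, elastance mbar/L, times s,
rates 1/min, power J/min.  The single conversion factor 0.1 J per mbar·L is
applied exactly once, in the power functions of this module.

Mechanical power decomposes per breath into

* elastic work  ``WOB_el = 1/2 E V_T^2``  (filling the balloon),
* resistive work ``WOB_res = R V' V_T``   (driving flow through R),
* intrinsic-PEEP work ``WOB_iPEEP = iPEEP V_T`` (pushing against the
  end-expiratory pressure left over from incomplete exhalation),

each in mbar·L; total power is ``0.1 rr (WOB_el + WOB_res + WOB_iPEEP)``
in J/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateExpirationError, DeadSpaceViolationError, InvalidParameterError

__all__ = [
    "RespiratoryMechanics",
    "VentilationPattern",
    "PowerBreakdown",
    "PatientScale",
    "time_constant",
    "breath_timing",
    "intrinsic_peep",
    "rate_from_alveolar_ventilation",
    "mechanical_power",
    "elastic_power",
    "plateau_pressure",
]

#: Conversion factor from mbar·L/min to J/min (1 mbar·L = 0.1 J).
MBAR_L_TO_J = 0.1

#: If 1 - exp(-t_ex/tau) falls below this, intrinsic PEEP is treated as
#: divergent rather than returned as a huge non-physical number.
_DEGENERATE_EXPIRATION_FLOOR = 1e-15


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise InvalidParameterError(message)


@dataclass(frozen=True)
class RespiratoryMechanics:
    """Patient-side parameters of the linear single-compartment model.

    Parameters
    ----------
    elastance
        Respiratory-system elastance E (lung + chest wall), mbar/L. Must be > 0.
    airway_resistance
        Airway component of the flow resistance, mbar/L/s. Must be >= 0.
    tube_resistance
        Endotracheal/tracheostomy-tube component of the resistance, mbar/L/s.
        Must be >= 0.
    dead_space
        Anatomic (series) dead space V_D, L. Must be > 0.

    The total resistance ``R = airway_resistance + tube_resistance`` must be
    >= 0; ``R = 0`` is allowed and treated everywhere as the analytic limit of
    instantaneous passive emptying (tau = 0, no intrinsic PEEP build-up).
    """

    elastance: float
    airway_resistance: float
    tube_resistance: float
    dead_space: float

    def __post_init__(self) -> None:
        _require(self.elastance > 0, f"elastance must be > 0 mbar/L, got {self.elastance}")
        _require(
            self.airway_resistance >= 0,
            f"airway_resistance must be >= 0 mbar/L/s, got {self.airway_resistance}",
        )
        _require(
            self.tube_resistance >= 0,
            f"tube_resistance must be >= 0 mbar/L/s, got {self.tube_resistance}",
        )
        _require(self.dead_space > 0, f"dead_space must be > 0 L, got {self.dead_space}")

    @property
    def resistance(self) -> float:
        """Total resistance R = airway + tube, mbar/L/s."""
        return self.airway_resistance + self.tube_resistance

    @property
    def time_constant(self) -> float:
        """Expiratory time constant tau = R/E, s (0 when R = 0)."""
        return self.resistance / self.elastance


@dataclass(frozen=True)
class VentilationPattern:
    """Ventilator-side settings of one periodic breath cycle.

    Parameters
    ----------
    tidal_volume
        V_T, L delivered per breath. Must be > 0.
    respiratory_rate
        rr, breaths/min. Must be > 0.
    ie_ratio
        I:E ratio r = t_in/t_ex (dimensionless). Must be > 0.
    external_peep
        Externally applied PEEP, mbar. Must be >= 0.
    """

    tidal_volume: float
    respiratory_rate: float
    ie_ratio: float = 1.0
    external_peep: float = 0.0

    def __post_init__(self) -> None:
        _require(self.tidal_volume > 0, f"tidal_volume must be > 0 L, got {self.tidal_volume}")
        _require(
            self.respiratory_rate > 0,
            f"respiratory_rate must be > 0 /min, got {self.respiratory_rate}",
        )
        _require(self.ie_ratio > 0, f"ie_ratio must be > 0, got {self.ie_ratio}")
        _require(
            self.external_peep >= 0,
            f"external_peep must be >= 0 mbar, got {self.external_peep}",
        )

    @property
    def cycle_time(self) -> float:
        """Breath cycle duration T = 60/rr, s."""
        return 60.0 / self.respiratory_rate

    @property
    def inspiratory_time(self) -> float:
        """t_in = T r / (1 + r), s."""
        return self.cycle_time * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def expiratory_time(self) -> float:
        """t_ex = T / (1 + r), s."""
        return self.cycle_time / (1.0 + self.ie_ratio)

    @property
    def inspiratory_flow(self) -> float:
        """Constant inspiratory flow V' = V_T / t_in, L/s."""
        return self.tidal_volume / self.inspiratory_time


@dataclass(frozen=True)
class PowerBreakdown:
    """Mechanical power split into its three physical components, J/min."""

    elastic: float
    resistive: float
    ipeep: float

    @property
    def total(self) -> float:
        """Total mechanical power = elastic + resistive + ipeep, J/min."""
        return self.elastic + self.resistive + self.ipeep


@dataclass(frozen=True)
class PatientScale:
    """Body-scale quantities used to express settings per kg.

    ``alveolar_minute_ventilation`` is the effective gas-exchanging
    ventilation V'_alv = rr (V_T - V_D), L/min; in adults the anatomic dead
    space scales roughly as 2.2 mL per kg of body weight.
    """

    body_weight: float
    alveolar_minute_ventilation: float

    def __post_init__(self) -> None:
        _require(self.body_weight > 0, f"body_weight must be > 0 kg, got {self.body_weight}")
        _require(
            self.alveolar_minute_ventilation > 0,
            f"alveolar_minute_ventilation must be > 0 L/min, got {self.alveolar_minute_ventilation}",
        )


def time_constant(mech: RespiratoryMechanics) -> float:
    """Expiratory time constant tau = R/E for passive lung emptying, s."""
    return mech.time_constant


def breath_timing(respiratory_rate: float, ie_ratio: float) -> tuple[float, float]:
    """Split one breath cycle into (t_in, t_ex), s.

    The two defining relations are t_in + t_ex = 60/rr and t_in/t_ex = r.
    """
    _require(respiratory_rate > 0, f"respiratory_rate must be > 0 /min, got {respiratory_rate}")
    _require(ie_ratio > 0, f"ie_ratio must be > 0, got {ie_ratio}")
    cycle = 60.0 / respiratory_rate
    t_ex = cycle / (1.0 + ie_ratio)
    t_in = cycle - t_ex
    return t_in, t_ex


def intrinsic_peep(mech: RespiratoryMechanics, pattern: VentilationPattern) -> float:
    """Steady-state intrinsic PEEP, mbar.

    During each expiration of length t_ex the lung empties passively toward
    the external-PEEP equilibrium, leaving a residual volume
    ``V_T exp(-t_ex/tau)``; residues of successive breaths form a geometric
    series whose steady-state sum gives

        iPEEP = PEEP + E V_T x / (1 - x),    x = exp(-t_ex / tau).

    The ratio x/(1-x) is evaluated as 1/expm1(t_ex/tau) for numerical
    accuracy at large t_ex/tau.  When R = 0 (tau = 0) the analytic limit
    iPEEP = PEEP is returned.

    Raises
    ------
    DegenerateExpirationError
        If t_ex/tau is so small that 1 - x underflows: the series diverges
        and no steady state exists at these settings.
    """
    tau = mech.time_constant
    if tau == 0.0:
        return pattern.external_peep
    ratio = pattern.expiratory_time / tau
    one_minus_x = -math.expm1(-ratio)  # 1 - exp(-ratio), accurate for small ratio
    if one_minus_x < _DEGENERATE_EXPIRATION_FLOOR:
        raise DegenerateExpirationError(
            f"expiratory time {pattern.expiratory_time:.3g} s is degenerate relative to "
            f"tau = {tau:.3g} s: intrinsic PEEP diverges"
        )
    buildup = mech.elastance * pattern.tidal_volume / math.expm1(ratio)
    return pattern.external_peep + buildup


def rate_from_alveolar_ventilation(v_alv: float, v_t: float, v_d: float) -> float:
    """Respiratory rate required for alveolar minute ventilation v_alv, /min.

    rr = V'_alv / (V_T - V_D): only the fraction of each breath exceeding the
    dead space exchanges gas, so the rate diverges as V_T approaches V_D.

    Raises
    ------
    DeadSpaceViolationError
        If v_t <= v_d (tidal volume must exceed the anatomic dead space).
    """
    _require(v_alv > 0, f"v_alv must be > 0 L/min, got {v_alv}")
    _require(v_d > 0, f"v_d must be > 0 L, got {v_d}")
    if v_t <= v_d:
        raise DeadSpaceViolationError(
            f"tidal volume {v_t} L must exceed anatomic dead space {v_d} L"
        )
    return v_alv / (v_t - v_d)


def mechanical_power(
    mech: RespiratoryMechanics,
    pattern: VentilationPattern,
    *,
    power_above_peep: bool = False,
) -> PowerBreakdown:
    """Total mechanical power and its decomposition, J/min.

    Evaluates, with r = t_in/t_ex and iPEEP from :func:`intrinsic_peep`,

        MP = 0.1 rr { V_T^2 [ E/2 + rr (1+r)/(60 r) R ] + iPEEP V_T }.

    The resistive factor ``rr (1+r)/(60 r) R`` is algebraically identical to
    ``R V'/V_T`` with V' the constant inspiratory flow; tests hold the two
    forms to 1e-12 relative agreement.

    By default the iPEEP term uses the full end-expiratory pressure including
    external PEEP, i.e. the power delivered at the airway above atmospheric.
    With ``power_above_peep=True`` only the intrinsic build-up above the
    external PEEP is charged, i.e. power above the PEEP baseline.

    Raises
    ------
    DegenerateExpirationError
        Propagated from :func:`intrinsic_peep` when no steady state exists.
    """
    rr = pattern.respiratory_rate
    v_t = pattern.tidal_volume
    r = pattern.ie_ratio

    elastic = MBAR_L_TO_J * rr * 0.5 * mech.elastance * v_t**2
    resistive = MBAR_L_TO_J * rr * v_t**2 * rr * (1.0 + r) / (60.0 * r) * mech.resistance

    ipeep_pressure = intrinsic_peep(mech, pattern)
    if power_above_peep:
        ipeep_pressure -= pattern.external_peep
    ipeep = MBAR_L_TO_J * rr * ipeep_pressure * v_t

    return PowerBreakdown(elastic=elastic, resistive=resistive, ipeep=ipeep)


def elastic_power(elastance: float, v_t: float, rr: float) -> float:
    """Elastic component of mechanical power, J/min.

    MP_el = 0.1 rr V_T^2 E/2.  Depends only on elastance, tidal volume and
    rate — independent of the I:E ratio, resistance and flow waveform, hence
    valid for both volume- and pressure-controlled modes.
    """
    _require(elastance >= 0, f"elastance must be >= 0 mbar/L, got {elastance}")
    _require(v_t > 0, f"v_t must be > 0 L, got {v_t}")
    _require(rr > 0, f"rr must be > 0 /min, got {rr}")
    return MBAR_L_TO_J * rr * 0.5 * elastance * v_t**2


def plateau_pressure(mech: RespiratoryMechanics, v_t: float, ipeep: float = 0.0) -> float:
    """End-inspiratory plateau pressure E V_T + iPEEP, mbar.

    In the linear model the plateau sits E·V_T above the end-expiratory
    baseline; passing the baseline pressure as ``ipeep`` generalizes the
    zero-PEEP expression, to which it reduces when ipeep = 0.
    """
    _require(v_t >= 0, f"v_t must be >= 0 L, got {v_t}")
    _require(ipeep >= 0, f"ipeep must be >= 0 mbar, got {ipeep}")
    return mech.elastance * v_t + ipeep
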