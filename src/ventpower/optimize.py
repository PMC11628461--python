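"""Constrained minimization of mechanical power over ventilator settings.

With alveolar minute ventilation held fixed, tidal volume and respiratory
rate are tied through rr = V'_alv / (V_T - V_D), leaving V_T and the I:E
ratio as the free settings.  This module minimizes either the total
mechanical power or its elastic component over that constraint set,
generates power-versus-tidal-volume curves (one per minute ventilation,
each point carrying its own optimal I:E), and turns the elastic-optimum
closed form — V_T* = 2 V_D, i.e. about 4.4 mL/kg body weight — into a
concrete settings recommendation.

Everything here is deterministic: grids, bounded scalar minimization and
explicit tie-breaks; no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    DegenerateExpirationError,
    InvalidParameterError,
    NoFeasiblePointError,
)
from .mechanics import (
    PowerBreakdown,
    RespiratoryMechanics,
    VentilationPattern,
    elastic_power,
    intrinsic_peep,
    mechanical_power,
    rate_from_alveolar_ventilation,
)

__all__ = [
    "SearchSpace",
    "IEOptimum",
    "CurvePoint",
    "OptimizationResult",
    "SettingsRecommendation",
    "optimal_vt_elastic",
    "optimal_vt_per_kg",
    "best_ie_for_vt",
    "minimize_total_power",
    "power_curve",
    "recommend_settings",
    "flatness_metric",
]

Objective = Literal["total", "elastic"]

#: Points within this relative power of the minimum are tied; ties break to
#: the smallest tidal volume (clinical conservatism) and smallest I:E.
_TIE_TOLERANCE = 1e-9

#: Log-spaced bracketing scan size preceding the bounded scalar refinement.
_IE_SCAN_POINTS = 64


@dataclass(frozen=True)
class SearchSpace:
    """Grid bounds for the tidal-volume / I:E search.

    Defaults cover the clinically plotted range and resolve the optimum to
    the millilitre: V_T from just above the dead space to 2 L in 1-mL steps,
    I:E between 0.1 and 4.
    """

    vt_min: float
    vt_max: float = 2.0
    vt_step: float = 0.001
    ie_min: float = 0.1
    ie_max: float = 4.0

    def __post_init__(self) -> None:
        if not (self.vt_max > self.vt_min > 0):
            raise InvalidParameterError(
                f"need vt_max > vt_min > 0, got vt_min={self.vt_min}, vt_max={self.vt_max}"
            )
        if self.vt_step <= 0:
            raise InvalidParameterError(f"vt_step must be > 0, got {self.vt_step}")
        if not (0 < self.ie_min < self.ie_max):
            raise InvalidParameterError(
                f"need 0 < ie_min < ie_max, got ie_min={self.ie_min}, ie_max={self.ie_max}"
            )

    @classmethod
    def default_for(cls, mech: RespiratoryMechanics, margin: float = 0.01) -> "SearchSpace":
        """Default space for a given patient: V_T in [V_D + margin, 2 L]."""
        return cls(vt_min=mech.dead_space + margin)

    def vt_grid(self) -> np.ndarray:
        """The tidal-volume grid, rounded to nanolitres to keep mL points exact."""
        n = int(math.floor((self.vt_max - self.vt_min) / self.vt_step + 1e-9)) + 1
        return np.round(self.vt_min + self.vt_step * np.arange(n), 9)


@dataclass(frozen=True)
class IEOptimum:
    """I:E ratio minimizing total power at one fixed tidal volume."""

    ie: float
    power: PowerBreakdown
    bound_limited: bool = False
    indifferent: bool = False


@dataclass(frozen=True)
class CurvePoint:
    """One point of a power-versus-tidal-volume curve."""

    v_t: float
    rr: float
    ie: float
    power: PowerBreakdown


@dataclass(frozen=True)
class OptimizationResult:
    """Arg-min ventilator settings plus the full search curve."""

    vt_star: float
    rr_star: float
    ie_star: float
    power_star: PowerBreakdown
    objective: Objective
    curve: tuple[CurvePoint, ...] = field(repr=False)

    def curve_frame(self) -> pd.DataFrame:
        """Curve as a DataFrame (column layout shared with CSV export)."""
        return curve_points_frame(self.curve, self.vt_star)


@dataclass(frozen=True)
class SettingsRecommendation:
    """Elastic-power-minimizing settings per the four-step recipe."""

    vt: float
    rr: float
    ie: float
    external_peep: float
    ipeep_buildup: float
    notes: str


def optimal_vt_elastic(v_d: float) -> float:
    """Tidal volume minimizing elastic power under the ventilation constraint, L.

    Substituting rr = V'_alv/(V_T - V_D) into MP_el = 0.1 rr V_T^2 E/2 gives
    an objective proportional to V_T^2/(V_T - V_D), stationary exactly at
    V_T = 2 V_D — independent of elastance and of the minute ventilation.
    """
    if v_d <= 0:
        raise InvalidParameterError(f"dead space must be > 0 L, got {v_d}")
    return 2.0 * v_d


def optimal_vt_per_kg(
    body_weight: float, dead_space_per_kg: float = 2.2
) -> tuple[float, float]:
    """Elastic-optimal tidal volume per kg and in absolute litres.

    With anatomic dead space scaling as ``dead_space_per_kg`` (mL/kg, adult
    default 2.2), the 2 x V_D optimum becomes 2 x 2.2 = 4.4 mL/kg.

    Returns
    -------
    (per_kg, absolute)
        Optimum in mL/kg and in L for this body weight.
    """
    if body_weight <= 0:
        raise InvalidParameterError(f"body_weight must be > 0 kg, got {body_weight}")
    if dead_space_per_kg < 0:
        raise InvalidParameterError(
            f"dead_space_per_kg must be >= 0 mL/kg, got {dead_space_per_kg}"
        )
    per_kg = 2.0 * dead_space_per_kg
    return per_kg, per_kg * body_weight / 1000.0


def _total_power_at(
    mech: RespiratoryMechanics,
    v_t: float,
    rr: float,
    ie: float,
    external_peep: float,
) -> PowerBreakdown:
    pattern = VentilationPattern(
        tidal_volume=v_t, respiratory_rate=rr, ie_ratio=ie, external_peep=external_peep
    )
    return mechanical_power(mech, pattern)


def best_ie_for_vt(
    mech: RespiratoryMechanics,
    v_t: float,
    v_alv: float,
    ie_bounds: tuple[float, float] = (0.1, 4.0),
    external_peep: float = 0.0,
) -> IEOptimum:
    """I:E ratio minimizing total mechanical power at fixed tidal volume.

    The rate follows from the alveolar-ventilation constraint.  A 64-point
    log-spaced scan over ``ie_bounds`` brackets the minimum, then bounded
    scalar minimization refines it.  Short inspiration (small r) is
    penalized by the resistive flow term, short expiration (large r) by
    intrinsic-PEEP build-up, so an interior optimum normally exists; if the
    refined optimum is not strictly interior the result is flagged
    ``bound_limited``.

    When R = 0 the total power is independent of timing; the documented
    tie-break returns ie = 1 flagged ``indifferent`` (unit I:E also balances
    peak inspiratory and expiratory flow).
    """
    lo, hi = ie_bounds
    if not (0 < lo < hi):
        raise InvalidParameterError(f"invalid ie_bounds {ie_bounds}")
    rr = rate_from_alveolar_ventilation(v_alv, v_t, mech.dead_space)

    if mech.resistance == 0.0:
        ie = min(max(1.0, lo), hi)
        return IEOptimum(
            ie=ie,
            power=_total_power_at(mech, v_t, rr, ie, external_peep),
            indifferent=True,
        )

    def objective(ie: float) -> float:
        try:
            return _total_power_at(mech, v_t, rr, ie, external_peep).total
        except DegenerateExpirationError:
            return math.inf

    scan = np.logspace(math.log10(lo), math.log10(hi), _IE_SCAN_POINTS)
    values = np.array([objective(ie) for ie in scan])
    if not np.isfinite(values).any():
        raise DegenerateExpirationError(
            f"no feasible I:E ratio in [{lo}, {hi}] at V_T = {v_t} L: expiration always degenerate"
        )
    i = int(np.argmin(values))
    bracket_lo = scan[max(i - 1, 0)]
    bracket_hi = scan[min(i + 1, len(scan) - 1)]
    result = minimize_scalar(
        objective,
        bounds=(bracket_lo, bracket_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ie_star = float(result.x)
    power_star = _total_power_at(mech, v_t, rr, ie_star, external_peep)
    # Prefer the scan point if refinement did not actually improve on it.
    if values[i] < power_star.total:
        ie_star = float(scan[i])
        power_star = _total_power_at(mech, v_t, rr, ie_star, external_peep)
    bound_limited = i == 0 or i == len(scan) - 1
    return IEOptimum(ie=ie_star, power=power_star, bound_limited=bound_limited)


def minimize_total_power(
    mech: RespiratoryMechanics,
    v_alv: float,
    space: SearchSpace | None = None,
    objective: Objective = "total",
    external_peep: float = 0.0,
    ie_fixed: float | None = None,
) -> OptimizationResult:
    """Minimize mechanical power over the tidal-volume grid.

    For each grid V_T the rate follows from the ventilation constraint and,
    unless ``ie_fixed`` is given, the I:E ratio is optimized per point
    (``objective="total"``) or set to the indifferent default 1
    (``objective="elastic"``, which is timing-independent).  Ties within
    1e-9 relative power break to the smallest V_T.

    Raises
    ------
    NoFeasiblePointError
        If no grid point lies strictly above the dead space or every point
        is degenerate.
    """
    if v_alv <= 0:
        raise InvalidParameterError(f"v_alv must be > 0 L/min, got {v_alv}")
    if space is None:
        space = SearchSpace.default_for(mech)
    if space.vt_min <= mech.dead_space:
        raise InvalidParameterError(
            f"search space vt_min = {space.vt_min} L must exceed dead space "
            f"{mech.dead_space} L"
        )
    if objective not in ("total", "elastic"):
        raise InvalidParameterError(f"objective must be 'total' or 'elastic', got {objective!r}")

    points: list[CurvePoint] = []
    for v_t in space.vt_grid():
        rr = rate_from_alveolar_ventilation(v_alv, float(v_t), mech.dead_space)
        try:
            if ie_fixed is not None:
                power = _total_power_at(mech, float(v_t), rr, ie_fixed, external_peep)
                ie = ie_fixed
            elif objective == "elastic":
                ie = 1.0
                power = _total_power_at(mech, float(v_t), rr, ie, external_peep)
            else:
                opt = best_ie_for_vt(
                    mech, float(v_t), v_alv, (space.ie_min, space.ie_max), external_peep
                )
                power, ie = opt.power, opt.ie
        except DegenerateExpirationError:
            continue
        points.append(CurvePoint(v_t=float(v_t), rr=rr, ie=ie, power=power))

    if not points:
        raise NoFeasiblePointError("every point of the search space is degenerate or infeasible")

    def score(p: CurvePoint) -> float:
        return p.power.total if objective == "total" else p.power.elastic

    best = min(points, key=score)
    best_value = score(best)
    # Deterministic tie-break: smallest V_T, then smallest I:E, among near-ties.
    for p in points:
        if score(p) <= best_value * (1.0 + _TIE_TOLERANCE):
            if (p.v_t, p.ie) < (best.v_t, best.ie):
                best = p
    return OptimizationResult(
        vt_star=best.v_t,
        rr_star=best.rr,
        ie_star=best.ie,
        power_star=best.power,
        objective=objective,
        curve=tuple(points),
    )


def curve_points_frame(points: Sequence[CurvePoint], vt_star: float | None) -> pd.DataFrame:
    """Tabulate curve points with the CSV column layout."""
    frame = pd.DataFrame(
        {
            "v_t_L": [p.v_t for p in points],
            "rr_per_min": [p.rr for p in points],
            "ie": [p.ie for p in points],
            "mp_elastic": [p.power.elastic for p in points],
            "mp_resistive": [p.power.resistive for p in points],
            "mp_ipeep": [p.power.ipeep for p in points],
            "mp_total": [p.power.total for p in points],
        }
    )
    frame["is_minimum"] = (
        frame["v_t_L"] == vt_star if vt_star is not None else False
    )
    return frame


def power_curve(
    mech: RespiratoryMechanics,
    v_alv_list: Iterable[float],
    space: SearchSpace | None = None,
    objective: Objective = "total",
    external_peep: float = 0.0,
    ie_fixed: float | None = None,
) -> pd.DataFrame:
    """Power-versus-tidal-volume curves, one per alveolar minute ventilation.

    Returns a long-format DataFrame with a ``v_alv_L_per_min`` column, the
    per-point optimal I:E, all power components, and ``is_minimum`` marking
    each curve's arg-min point.
    """
    v_alv_values = list(v_alv_list)
    if not v_alv_values:
        raise InvalidParameterError("v_alv_list must not be empty")
    frames = []
    for v_alv in v_alv_values:
        result = minimize_total_power(
            mech, v_alv, space, objective=objective, external_peep=external_peep,
            ie_fixed=ie_fixed,
        )
        frame = result.curve_frame()
        frame.insert(0, "v_alv_L_per_min", v_alv)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def recommend_settings(
    mech: RespiratoryMechanics,
    v_alv: float,
    target_peep: float = 0.0,
    ie: float = 1.0,
) -> SettingsRecommendation:
    """Elastic-power-minimizing ventilator settings.

    Four steps: (1) tidal volume twice the anatomic dead space; (2) the
    respiratory rate that delivers the requested alveolar minute
    ventilation at that volume; (3) start from the clinically targeted
    external PEEP; (4) lower the external PEEP by the intrinsic-PEEP
    build-up these settings produce, so the end-expiratory pressure the
    patient actually sees stays at the target.  The external PEEP is
    clamped at zero — if the build-up exceeds the target, the note records
    that it cannot be fully compensated.  The I:E default of 1 balances
    peak inspiratory and expiratory flows; elastic power itself is
    I:E-independent.
    """
    if target_peep < 0:
        raise InvalidParameterError(f"target_peep must be >= 0 mbar, got {target_peep}")
    vt = optimal_vt_elastic(mech.dead_space)
    rr = rate_from_alveolar_ventilation(v_alv, vt, mech.dead_space)
    pattern = VentilationPattern(
        tidal_volume=vt, respiratory_rate=rr, ie_ratio=ie, external_peep=target_peep
    )
    buildup = intrinsic_peep(mech, pattern) - target_peep
    external = target_peep - buildup
    notes = "tidal volume set to twice the anatomic dead space; rate from alveolar-ventilation constraint"
    if external < 0:
        external = 0.0
        notes += (
            "; intrinsic-PEEP build-up exceeds the target PEEP and cannot be fully "
            "compensated — external PEEP clamped at 0"
        )
    return SettingsRecommendation(
        vt=vt,
        rr=rr,
        ie=ie,
        external_peep=external,
        ipeep_buildup=buildup,
        notes=notes,
    )


def flatness_metric(result: OptimizationResult, fraction: float = 0.2) -> float:
    """Relative excess of total power at vt_star x (1 -/+ fraction).

    Quantifies how flat the total-power curve is around its minimum: the
    larger of the two relative increases at 0.8 x and 1.2 x the optimal
    tidal volume (points taken from the stored curve, nearest grid match).
    A small value means tidal volume is poorly identified by the minimum.
    """
    if not result.curve:
        raise InvalidParameterError("result has an empty curve")
    vts = np.array([p.v_t for p in result.curve])
    totals = np.array([p.power.total for p in result.curve])
    reference = result.power_star.total
    excesses = []
    for target in (result.vt_star * (1 - fraction), result.vt_star * (1 + fraction)):
        idx = int(np.argmin(np.abs(vts - target)))
        excesses.append((totals[idx] - reference) / reference)
    return float(max(excesses))
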