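"""Brute-force time-domain oracle for the single-compartment model.

This module verifies the closed-form intrinsic-PEEP and mechanical-power
expressions without using them: it steps a constant-flow inspiration and a
passive exponential expiration breath by breath until the end-expiratory
volume stops changing, then integrates airway pressure x flow numerically
over one inspiration.

The expiration update is the exact exponential decay per time step (not
forward Euler), so the only truncation error left in the steady-state
intrinsic PEEP is the finite breath count controlled by ``tol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, PrecisionError
from .mechanics import MBAR_L_TO_J, RespiratoryMechanics, VentilationPattern

__all__ = [
    "BreathTrace",
    "SteadyStateReport",
    "simulate_to_steady_state",
    "work_per_breath",
    "breath_trace",
]

#: Default breath cap before the simulation is declared non-convergent.
DEFAULT_BREATH_CAP = 10_000


@dataclass(frozen=True)
class BreathTrace:
    """Sampled volume/flow/pressure waveforms of simulated breaths.

    Arrays share one monotone time grid.  ``volume_above_frc`` is the volume
    above the relaxed (zero-airway-pressure) volume; with external PEEP the
    end-expiratory equilibrium volume is PEEP/E, not zero.  Flow is positive
    during inspiration.  ``airway_pressure`` is pressure at the airway
    opening: E v + R V' during inspiration, the held PEEP during expiration.
    """

    time: np.ndarray
    volume_above_frc: np.ndarray
    flow: np.ndarray
    airway_pressure: np.ndarray
    breath_index: np.ndarray


@dataclass(frozen=True)
class SteadyStateReport:
    """Outcome of a breath-by-breath run to steady state."""

    ipeep_sim: float
    work_per_breath: float
    n_breaths_to_converge: int
    residual: float
    trace: BreathTrace | None = field(default=None, repr=False)


def _equilibrium_volume(mech: RespiratoryMechanics, peep: float) -> float:
    """Volume above FRC at which the relaxed system holds the external PEEP."""
    return peep / mech.elastance


def simulate_to_steady_state(
    mech: RespiratoryMechanics,
    pattern: VentilationPattern,
    dt: float | None = None,
    tol: float = 1e-10,
    max_breaths: int = DEFAULT_BREATH_CAP,
    record_trace: bool = False,
    exact_breaths: int | None = None,
) -> SteadyStateReport:
    """Run breaths until the end-expiratory volume converges.

    Starting from the external-PEEP equilibrium volume (empty above
    baseline), each cycle delivers V_T at constant flow over t_in, then lets
    the compartment empty passively toward equilibrium for t_ex using the
    exact per-step exponential update.  Residual volumes of successive
    breaths accumulate exactly the geometric series that the closed-form
    intrinsic-PEEP expression sums; this simulation realizes the series
    term by term.

    Parameters
    ----------
    dt
        Sample interval, s; defaults to min(t_in, tau)/1000 (t_in/1000 when
        R = 0).  Must not exceed t_in/100 nor tau/100.
    tol
        Relative change of end-expiratory volume between consecutive breaths
        below which steady state is declared.
    record_trace
        Keep the full waveform of every simulated breath (memory grows with
        breath count; meant for plotting/export, not for convergence runs).
    exact_breaths
        If given, run exactly this many breaths and skip the convergence
        test; the report then describes the state after that partial sum of
        the residual-volume series.

    Returns
    -------
    SteadyStateReport
        ``ipeep_sim = PEEP + E (v_ee - PEEP/E)`` with v_ee the converged
        end-expiratory volume above FRC; ``work_per_breath`` in J from
        :func:`work_per_breath` at the converged state.

    Raises
    ------
    ConvergenceError
        If ``max_breaths`` cycles do not reach ``tol``.
    PrecisionError
        If ``dt`` violates the resolution preconditions.
    """
    if tol <= 0:
        raise PrecisionError(f"tol must be > 0, got {tol}")
    if exact_breaths is not None:
        if exact_breaths < 1:
            raise ValueError(f"exact_breaths must be >= 1, got {exact_breaths}")
        max_breaths = exact_breaths
    tau = mech.time_constant
    t_in = pattern.inspiratory_time
    t_ex = pattern.expiratory_time
    if dt is None:
        dt = (t_in if tau == 0.0 else min(t_in, tau)) / 1000.0
    if dt > t_in / 100.0 or (tau > 0.0 and dt > tau / 100.0):
        raise PrecisionError(
            f"dt = {dt:.3g} s too coarse: need dt <= t_in/100 = {t_in / 100.0:.3g} s"
            + (f" and dt <= tau/100 = {tau / 100.0:.3g} s" if tau > 0 else "")
        )

    peep = pattern.external_peep
    v_eq = _equilibrium_volume(mech, peep)
    flow_in = pattern.inspiratory_flow

    # Per-step exact decay factor for expiration; number of whole steps plus
    # a fractional remainder so each phase lasts exactly t_ex.
    n_ex = max(int(math.ceil(t_ex / dt)), 1)
    n_in = max(int(math.ceil(t_in / dt)), 1)

    times: list[np.ndarray] = []
    volumes: list[np.ndarray] = []
    flows: list[np.ndarray] = []
    pressures: list[np.ndarray] = []
    breath_ids: list[np.ndarray] = []

    # v measured above the PEEP equilibrium volume; starts empty.
    v = 0.0
    t0 = 0.0
    n_converged = 0
    residual = math.inf
    for breath in range(1, max_breaths + 1):
        v_start = v
        if record_trace:
            t_grid = np.linspace(0.0, t_in, n_in + 1)
            vol = v_start + flow_in * t_grid
            paw = mech.elastance * (vol + v_eq) + mech.resistance * flow_in
            times.append(t0 + t_grid)
            volumes.append(vol + v_eq)
            flows.append(np.full_like(t_grid, flow_in))
            pressures.append(paw)
            breath_ids.append(np.full(t_grid.shape, breath, dtype=int))
        v = v_start + pattern.tidal_volume
        t0 += t_in

        if tau == 0.0:
            if record_trace:
                times.append(np.array([t0, t0 + t_ex]))
                volumes.append(np.array([v_eq, v_eq]))
                flows.append(np.array([0.0, 0.0]))
                pressures.append(np.array([peep, peep]))
                breath_ids.append(np.array([breath, breath]))
            v_end = 0.0
        else:
            if record_trace:
                t_grid = np.linspace(0.0, t_ex, n_ex + 1)
                vol = v * np.exp(-t_grid / tau)
                times.append(t0 + t_grid)
                volumes.append(vol + v_eq)
                flows.append(-vol / tau)
                pressures.append(np.full_like(t_grid, peep))
                breath_ids.append(np.full(t_grid.shape, breath, dtype=int))
            # Exact exponential update applied step by step (whole steps plus
            # the fractional remainder), equivalent to exp(-t_ex/tau) overall.
            step_decay = math.exp(-dt / tau)
            remainder = t_ex - (n_ex - 1) * dt
            v_end = v * step_decay ** (n_ex - 1) * math.exp(-remainder / tau)
        t0 += t_ex

        residual = abs(v_end - v_start) / max(abs(v_end), 1e-300)
        v = v_end
        n_converged = breath
        if exact_breaths is None and residual < tol:
            break
    else:
        if exact_breaths is None:
            raise ConvergenceError(
                f"end-expiratory volume not converged to tol={tol:g} within {max_breaths} "
                f"breaths (last residual {residual:.3g})"
            )

    ipeep_sim = peep + mech.elastance * v
    work = work_per_breath(mech, pattern, ipeep_sim, dt=dt)

    trace = None
    if record_trace:
        trace = BreathTrace(
            time=np.concatenate(times),
            volume_above_frc=np.concatenate(volumes),
            flow=np.concatenate(flows),
            airway_pressure=np.concatenate(pressures),
            breath_index=np.concatenate(breath_ids),
        )
    return SteadyStateReport(
        ipeep_sim=ipeep_sim,
        work_per_breath=work,
        n_breaths_to_converge=n_converged,
        residual=residual,
        trace=trace,
    )


def work_per_breath(
    mech: RespiratoryMechanics,
    pattern: VentilationPattern,
    ipeep_state: float,
    dt: float | None = None,
    method: str = "trapezoid",
    strict: bool = False,
) -> float:
    """Inspiratory work of one steady-state breath by numeric p-dV integration, J.

    Airway pressure during constant-flow inspiration is
    ``p(t) = ipeep_state + E V' t + R V'``; the integral of p x flow over
    t_in is evaluated on a uniform grid with the trapezoidal (default) or
    midpoint rule and converted from mbar·L to J.

    ``ipeep_state`` is the end-expiratory (baseline) pressure the breath
    starts from, normally the converged value of
    :func:`simulate_to_steady_state`.

    Raises
    ------
    PrecisionError
        If ``dt > t_in/100``: warned-about precision loss, escalated to an
        error when ``strict`` is set.  (The non-strict path still refuses dt
        coarser than t_in/10.)
    """
    t_in = pattern.inspiratory_time
    if dt is None:
        dt = t_in / 1000.0
    if dt > t_in / 100.0:
        message = f"dt = {dt:.3g} s coarser than t_in/100 = {t_in / 100.0:.3g} s"
        if strict or dt > t_in / 10.0:
            raise PrecisionError(message)
        import warnings

        warnings.warn(message, stacklevel=2)

    n = max(int(math.ceil(t_in / dt)), 2)
    flow = pattern.inspiratory_flow
    if method == "trapezoid":
        t = np.linspace(0.0, t_in, n + 1)
        p = ipeep_state + mech.elastance * flow * t + mech.resistance * flow
        work_mbar_l = float(np.trapezoid(p * flow, t))
    elif method == "midpoint":
        edges = np.linspace(0.0, t_in, n + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        p = ipeep_state + mech.elastance * flow * mid + mech.resistance * flow
        work_mbar_l = float(np.sum(p * flow) * (t_in / n))
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return MBAR_L_TO_J * work_mbar_l


def breath_trace(
    mech: RespiratoryMechanics,
    pattern: VentilationPattern,
    n_breaths: int,
    dt: float | None = None,
) -> BreathTrace:
    """Simulate exactly ``n_breaths`` from empty and return the full waveform."""
    report = simulate_to_steady_state(
        mech,
        pattern,
        dt=dt,
        record_trace=True,
        exact_breaths=n_breaths,
    )
    assert report.trace is not None
    return report.trace
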