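# Methods

## Model and assumptions

The respiratory system is treated as a single linear compartment: constant
elastance *E* (lung plus chest wall) in series with a constant resistance
*R* (airway plus endotracheal/tracheostomy tube). Ventilation is
volume-controlled with constant inspiratory flow V̇ = V_T/t_in; expiration
is passive, with the ventilator holding airway pressure at the external
PEEP, so the compartment empties exponentially toward the PEEP-equilibrium
volume with time constant τ = R/E.

Assumptions this entails, and their limits:

- **Linearity.** Elastance does not depend on volume and resistance does
  not depend on flow. Real tubes are Rohrer-like (flow-dependent) and ARDS
  lungs stiffen at high volume; both effects are out of scope, so results
  at large tidal volumes (where the total-power optimum lies) should be
  read as model statements, not bedside predictions.
- **Passive patient.** No spontaneous effort; pressure-controlled
  waveforms are not simulated (the elastic power is waveform-independent,
  so the elastic-optimum results carry over to PCV unchanged).
- **Periodic steady state.** Intrinsic PEEP is the limit of the
  residual-volume geometric series; the simulator confirms convergence is
  geometric with ratio exp(−t_ex/τ).

Work per breath decomposes into elastic (½E·V_T²), resistive (R·V̇·V_T)
and intrinsic-PEEP (iPEEP·V_T) parts, in mbar·L; power is work × rate with
the single unit conversion 0.1 J per mbar·L applied exactly once, in the
power functions. Package-wide units: L, mbar, mbar/L/s, mbar/L, s, 1/min,
J/min. No implicit conversions anywhere; validation happens at the type
boundary (`RespiratoryMechanics`, `VentilationPattern`).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| elastance E | mbar/L | 10 (normal), 20 (stiff/ARDS-like) | sets elastic power and τ |
| airway resistance | mbar/L/s | 1 | adult airway contribution |
| tube resistance | mbar/L/s | 7 (8-mm ETT), 12 (7-mm ETT) | dominates R in non-obstructed patients |
| dead space V_D | L | 0.2 | adult anatomic dead space; ≈2.2 mL/kg |
| alveolar ventilation V̇_alv | L/min | 10 | the clinical constraint the optimization respects |
| external PEEP | mbar | 0 | does not move the arg-min; nonzero values supported |
| I:E bounds | — | [0.1, 4.0] | interior optimum exists: small r is punished by the flow (resistive) cost, large r by iPEEP build-up |
| V_T grid | L | [V_D + 0.01, 2.0], 1-mL step | covers the clinical axis range and resolves the optimum to the mL |

## Optimization

For each grid tidal volume the rate follows from
rr = V̇_alv/(V_T − V_D) and the I:E ratio is optimized by a 64-point
log-spaced bracketing scan followed by bounded scalar minimization
(`scipy.optimize.minimize_scalar`, xatol 1e-10) within the bracket; if the
scan minimum sits on a bound the result is flagged bound-limited rather
than silently accepted. The elastic objective is timing-independent, so it
is evaluated at I:E = 1 without a scalar search. A fixed-I:E mode exists
as a configuration switch because per-point-optimal I:E is a modelling
choice, not a physical necessity; with the default per-point policy the
total-power arg-min for the normal-lung example resolves to 994 mL on the
1-mL grid. Ties within 1e-9 relative power break to the smallest tidal
volume, then the smallest I:E — determinism plus clinical conservatism.
With R = 0 the timing is genuinely indifferent and I:E = 1 is returned,
flagged as such (unit I:E also balances peak inspiratory and expiratory
flow). The whole pipeline contains no randomness: identical inputs give
identical results to the bit.

Closed forms: substituting the rate constraint into the elastic power
gives an objective ∝ V_T²/(V_T − V_D), stationary exactly at V_T = 2·V_D;
with V_D ≈ 2.2 mL/kg this is the 4.4 mL/kg rule. Both are computed
symbol-free at run time and cross-checked against grid searches in the
tests and the acceptance script.

The settings recommendation applies the elastic optimum: V_T = 2·V_D, the
constraint rate, I:E = 1, and external PEEP reduced by the predicted
intrinsic-PEEP build-up at those settings so the effective end-expiratory
pressure stays at the clinical target; the reduction is clamped at zero
(never negative PEEP) with an explanatory note when the build-up exceeds
the target.

## Numerical choices

- **Intrinsic PEEP.** x/(1−x) with x = exp(−t_ex/τ) is evaluated as
  1/expm1(t_ex/τ), accurate for both large and small t_ex/τ. If
  1 − x < 1e-15 the settings are declared degenerate
  (`DegenerateExpirationError`) instead of returning a non-physical huge
  pressure. R = 0 is the analytic limit iPEEP = PEEP, not a division.
- **Resistive-term identity.** The closed-form factor rr(1+r)/(60r)·R and
  the flow form R·(V_T/t_in)·V_T are held to 1e-12 relative agreement in
  tests.
- **Simulator.** Expiration advances by the exact per-step exponential
  decay (never forward Euler), so the steady-state iPEEP error is pure
  breath-count truncation, controlled by the convergence tolerance
  (default 1e-10 relative change in end-expiratory volume per breath,
  breath cap 10 000). Default dt = min(t_in, τ)/1000; dt coarser than
  t_in/100 or τ/100 is rejected. Inspiratory work is trapezoidal p·V̇
  integration; the integrand is linear in time for constant flow, so
  trapezoid is exact up to rounding and the midpoint cross-check agrees to
  well under 1e-6.
- **Flatness metric.** Reported as the relative power excess at
  0.8× and 1.2× the optimal tidal volume (larger of the two), taken from
  the stored curve; for the normal-lung example it is ≈3 %, which is what
  makes total power a poor tuning target.

## What the tests show — and what they do not

The simulator is an independent oracle: it realizes the residual-volume
series term by term and integrates p·dV numerically, using neither the
geometric-series sum nor the closed-form power expression. Agreement
(iPEEP to 1e-6 relative, power to 1e-3 across a 5×5×5 parameter sweep)
verifies the algebra and its implementation — it does **not** validate the
linear single-compartment model against real patients, nonlinear tube
behaviour, spontaneous effort, or measurement noise, none of which are
modelled. The printed clinical parameter sets (normal vs stiff lung, 8-mm
vs 7-mm tube) are illustrative scenarios, not a patient population.

## Known limitations

- No nonlinear elastance, flow-dependent resistance, two-compartment or
  viscoelastic mechanics, or decelerating-flow VCV waveforms.
- The recommendation recipe treats intrinsic-PEEP build-up as exactly
  compensable by lowering external PEEP; in patients with expiratory flow
  limitation this equivalence can fail.
- Outputs are desk calculations for a given parameter set; nothing here is
  a bedside device or a substitute for clinical judgement.
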