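# ventpower

Mechanical power of controlled mechanical ventilation: a single-compartment
model of the ventilated respiratory system, the decomposition of power into
elastic, resistive and intrinsic-PEEP components, and the ventilator
settings that minimize power at a fixed alveolar minute ventilation.

Written for respiratory physiologists, intensivists and ventilator
engineers who want a tested, scriptable implementation of the power
calculus behind lung-protective ventilation — rather than a spreadsheet or
a one-off script.

## The model

The respiratory system is a linear RC compartment: constant elastance *E*
(lung + chest wall, mbar/L) filled through a constant resistance *R*
(airways + endotracheal tube, mbar/L/s), ventilated in volume-controlled
mode with constant inspiratory flow and passive expiration against an
external PEEP. The expiratory time constant is τ = *R*/*E*.

Incomplete exhalation leaves residual volume that accumulates over breaths
as a geometric series, giving the steady-state intrinsic PEEP

    iPEEP = PEEP + E·V_T · exp(−t_ex/τ) / (1 − exp(−t_ex/τ)),

and the total mechanical power (J/min, with rr in 1/min, r = t_in/t_ex)

    MP = 0.1·rr·{ V_T²·[ E/2 + rr·(1+r)/(60·r)·R ] + iPEEP·V_T },

the three terms being the elastic, resistive and intrinsic-PEEP work per
breath times the rate. Tidal volume and rate are not free: holding the
alveolar minute ventilation V̇_alv fixed ties them through

    rr = V̇_alv / (V_T − V_D),

with V_D the anatomic dead space. Minimizing only the elastic component
0.1·rr·V_T²·E/2 under this constraint has a closed-form optimum at
**V_T = 2·V_D** (≈ 4.4 mL/kg body weight, since V_D ≈ 2.2 mL/kg in
adults) — independent of elastance, minute ventilation and I:E ratio.
Minimizing the *total* power instead pushes the optimum to much larger,
clinically questionable tidal volumes, because the resistive and iPEEP
terms fall monotonically with V_T; the package computes both optima and
the full power-vs-volume curves, plus a breath-by-breath time-domain
simulator that verifies the closed forms independently.

## Worked example

A normal lung (E = 10 mbar/L, V_D = 200 mL) with an 8-mm endotracheal tube
(R = 1 + 7 mbar/L/s), alveolar ventilation 10 L/min, PEEP 0:

```sh
ventpower optimize --elastance 10 --airway-resistance 1 --tube-resistance 7 \
    --dead-space 0.2 --alveolar-ventilation 10 --out out/
```

prints

```
arg-min: V_T = 0.994 L (994.0 mL), rr = 12.5945 /min, I:E = 1.30286, total power = 10.9291 J/min
flatness (power excess at +/-20% V_T): 3.24326%
```

— the *total*-power minimum sits near one litre, far above lung-protective
tidal volumes, and the curve is so flat (±20 % of V_T changes power by
only ~3 %) that total power cannot usefully guide the setting. The
elastic-only objective (`--objective elastic`) instead returns exactly
400 mL = 2·V_D. The settings recipe built on that optimum:

```sh
ventpower recommend --elastance 10 --airway-resistance 1 --tube-resistance 7 \
    --dead-space 0.2 --alveolar-ventilation 10 --peep 5 --body-weight 70 --out out/
```

```
recommend: V_T = 400.0 mL, rr = 50.0 /min, I:E = 1.0, external PEEP = 1.41898 mbar (intrinsic build-up 3.58102 mbar)
```

i.e. tidal volume twice the dead space, the rate that preserves the
alveolar ventilation, I:E near unity, and the external PEEP lowered by the
predicted intrinsic-PEEP build-up so the end-expiratory pressure the
patient sees stays at the 5-mbar target. `ventpower curve` writes the
power-vs-volume tables (optionally one CSV per elastance/tube panel) and
`ventpower simulate` runs the time-domain oracle and reports how closely
it matches the closed forms. The same functionality is available as a
library (`ventpower.minimize_total_power`, `ventpower.recommend_settings`,
`ventpower.simulate_to_steady_state`, ...).

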