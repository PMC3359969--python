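# confspread

Kinetic Monte Carlo simulation and analysis of **conformational spread** in
the bacterial flagellar motor switch.

The direction of rotation of the *E. coli* flagellar motor is set by the
C-ring, a closed ring of ~34 identical FliM protomers. Each protomer has a
mechanical conformation — *active* (clockwise, CW) or *inactive*
(counter-clockwise, CCW) — and can bind one molecule of the signalling
protein CheY-P. Nearest-neighbour coupling favours alike conformations, so a
domain of the minority conformation nucleated by a single flip can spread
around the ring and switch the whole motor. This package is for biophysicists
and systems biologists who want to simulate that model, reproduce its
switching statistics, and test its ultrasensitivity.

## Model

Each protomer occupies one of four states `AB ↔ AN ↔ IN ↔ IB` (A/I =
active/inactive, B/N = bound/unbound). Site free energies (k_BT, relative to
IN):

    g(IN) = 0            g(AN) = E_A⁰
    g(IB) = E_C + E_A⁰   g(AB) = E_C + E_A⁰ − E_A¹

with `E_C = −ln(c/c₀.₅)` the chemical free energy of CheY-P binding at
relative concentration `c/c₀.₅`, `E_A⁰`/`E_A¹` the activation energies of an
unliganded/liganded protomer, and the free energy lowered by the coupling
`E_J` for each neighbour in the same conformation. In the symmetric model
(`E_A⁰ = E_A¹`) the landscape at `c = c₀.₅` is invariant under the joint
exchange (active, bound) ↔ (inactive, unbound): `c₀.₅` is simultaneously the
concentration of half occupancy and of neutral bias. For asymmetric energies
the neutral-bias concentration is solved numerically (transfer matrix +
root finding).

Rates obey detailed balance with load-sharing factors: conformational flips
at `k = ω_a·exp(−λ_a ΔG)` (forward) and `ω_a·exp((1−λ_a) ΔG)` (reverse) with
`ω_a = 10⁴ s⁻¹`, `λ_a = ½`; binding at the mass-action rate
`k_on = ω_b·c/c₀.₅` (`ω_b = 10 s⁻¹`, `λ_b = 0`, conformation-independent)
with conformation dependence carried by the off-rates. The event-driven
simulation keeps one pending flip time and one pending binding time per
protomer, executes the earliest, and redraws the affected exponential waiting
times (`t − t₀ = −ln u / k`).

The analysis layer extracts locked-state intervals (entry at one full-lock
level, 0 or N active, to entry at the opposite level), switch times (last
sample at the departing level to first at the opposite), domain counts,
CW bias, Hill coefficients (slope of `log[Y/(1−Y)]` vs `log(c/c₀.₅)`), and
Lorentzian power-spectrum fits. Exact equilibrium references (4^N
enumeration, a 2×2 transfer matrix, and a closed-form domain-count
distribution) verify the simulator by detailed balance.

## Worked example

```python
from confspread import (ModelParams, SimConfig, simulate,
                        extract_intervals, cw_bias, domain_occupancy)

params = ModelParams(ea0=0.65, ea1=0.65, ej=4.15, c_rel=1.0, n_protomers=34)
traj = simulate(params, SimConfig(duration=120.0, seed=42))
ivs = extract_intervals(traj)
print(f"events simulated : {traj.n_events}")
print(f"CW bias          : {cw_bias(traj):.3f}")
print(f"locked intervals : n={len(ivs.locked_intervals)}, mean={ivs.mean_locked:.3f} s")
print(f"switch times     : n={ivs.n_switches}, mean={ivs.mean_switch*1e3:.2f} ms")
print("domain occupancy :", {k: f"{100*v:.2f}%" for k, v in sorted(domain_occupancy(traj).items())})
```

prints

```
events simulated : 1811389
CW bias          : 0.443
locked intervals : n=162, mean=0.736 s
switch times     : n=162, mean=17.72 ms
domain occupancy : {1: '87.47%', 2: '12.29%', 4: '0.24%', 6: '0.00%'}
```

At these experimentally matched energies (`E_A = 0.65 k_BT`,
`E_J = 4.15 k_BT`) the 34-protomer ring sits fully locked most of the time,
dwells ~0.74 s per locked state, and completes each reversal in ~18 ms —
a stable switch that still flips in milliseconds. A concentration sweep
(`confspread hill` or `trace_analysis.sensitivity_curve`) gives a Hill
coefficient near 9.5, i.e. the ~10-fold ultrasensitivity measured for the
motor.

A command-line front end mirrors the library:

```sh
confspread simulate --n 34 --duration 60 --seed 1 --out traj.csv
confspread analyze traj.csv
confspread sweep --ea0 0.55,0.65 --ea1 0.65 --ej 4.15 --out sweep.csv
confspread ringsize --sizes 10,34,60,100 --out sizes.csv
confspread c05 --ea0 0.55 --ea1 0.75 --ej 4.15
```

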