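# Methods

## Model

A closed ring of `N` identical protomers (default 34, the FliM copy number
of the C-ring). Protomer `i` carries a mechanical conformation
`a_i ∈ {inactive, active}` (CCW/CW) and an occupancy `b_i ∈ {unbound,
bound}` (one CheY-P site). The total free energy of a configuration, in
k_BT, is

    G = Σ_i g(a_i, b_i) − E_J · #{i : a_i = a_{i+1 mod N}}

with site energies (relative to inactive/unbound)

    g(IN) = 0            g(AN) = E_A⁰
    g(IB) = E_C + E_A⁰   g(AB) = E_C + E_A⁰ − E_A¹

and `E_C = −ln(c_rel)`, `c_rel = c/c₀.₅`. Two conventions are built into this
table and are worth stating explicitly, because alternatives differing by a
shift of the binding reference produce the same equilibrium under a rescaled
concentration unit but *different dynamics* at a given `ω_b`:

* the conformational gap is `+E_A⁰` for an unliganded and `−E_A¹` for a
  liganded protomer;
* binding to the inactive conformation costs `E_A⁰` more than binding to the
  active one, so that in the symmetric model (`E_A⁰ = E_A¹ = E_A`) the
  landscape at `c_rel = 1` is invariant under the joint exchange
  (active, bound) ↔ (inactive, unbound). `c₀.₅` is then simultaneously the
  concentration of 50% occupancy and of neutral bias, which is the defining
  property of the half-maximal concentration in this model family. The
  package's reproduction of the reference switching statistics (locked-state
  and switch-time means over the whole explored energy grid) confirms this
  choice; the alternative reference (equivalent to replacing `ω_b` by
  `ω_b·e^{−E_A}`) misses those statistics by ~40%.

### Rate constants

All rates satisfy detailed balance against `G`, so the stationary law of the
process is exactly Boltzmann — this is what makes the exact equilibrium
oracles possible.

* Conformational flips: with `ΔG` the free-energy change of toggling `a_i`
  (site term `±E_A⁰` / `∓E_A¹` plus coupling `E_J·(2·n_alike − 2)`,
  `n_alike ∈ {0,1,2}` the neighbours currently sharing `a_i`),
  `k(I→A) = ω_a·exp(−λ_a ΔG_IA)` and `k(A→I) = ω_a·exp((1−λ_a) ΔG_IA)`.
  Defaults `ω_a = 10⁴ s⁻¹` (typical protein conformational rate) and
  `λ_a = ½` (barrier splits evenly; no information favouring another split).
* Binding: `k_on = ω_b·c_rel` for both conformations (`λ_b = 0`: the
  association rate is conformation-independent and mass-action in `c`);
  detailed balance then forces `k_off(inactive) = ω_b·e^{+E_A⁰}` and
  `k_off(active) = ω_b·e^{−E_A¹}`. Default `ω_b = 10 s⁻¹` (measured CheY-P
  binding scale). Only `λ_b = 0` is supported; a non-zero `λ_b` would need a
  convention for how `E_C` enters the off-rate that cannot be fixed from the
  constraints above.

## Event-driven simulation

Each protomer holds two pending absolute event times: `A_i` (next flip) and
`B_i` (next binding toggle). The loop pops the earliest of the 2N times,
applies the toggle, and redraws fresh exponential waiting times
(`t − t₀ = −ln u / k`, `u` uniform on (0,1], +∞ for zero rates) for every
process whose rate changed: `A_i`, `B_i` always; `A_{i−1}`, `A_{i+1}`
additionally after a flip (their coupling terms changed; their binding rates
did not). Redrawing rather than rescaling pending times is statistically
exact by memorylessness. The state starts fully active and fully bound and
is point-sampled every `Δt = 0.1 ms` into three summary series: number
active, number bound, and domain count (maintained incrementally as the
number of unlike neighbour pairs; a coherent ring counts as one domain).
The inner loop is numba-compiled (~10⁶–10⁷ events/s); a 34-ring at the
best-fit condition generates ≈1.5·10⁴ events per simulated second.

Determinism: one seeded RNG stream drives the whole run; identical
parameters and seed give bit-identical trajectories, and multiplying `ω_a`
and `ω_b` jointly by a power of two while rescaling `duration` and `Δt`
reproduces the identical event sequence (asserted in tests).

Burn-in defaults to zero: the initial fully-locked state is a typical locked
state at neutral bias, and interval extraction discards everything before
the first locked-state entry anyway. A `burn_in` option trims samples for
off-neutral runs if desired.

## Equilibrium references

* **Enumeration** (N ≤ 12): direct Boltzmann sum over all 4^N
  configurations; yields one-site marginals and the domain-count
  distribution.
* **Transfer matrix** (any N): occupancy summed per site into weights
  `w(a) = Σ_b e^{−g(a,b)}`; `Z = tr(T^N)` for the symmetric 2×2 matrix
  `T[a,b] = √(w(a)w(b))·e^{E_J·[a=b]}`. Eigenvalues are rescaled by the
  spectral radius before the N-th power, so N = 100 is stable.
* **Domain-count distribution** (any N, closed form): the number of ring
  configurations with `m` active sites and `b = 2j` boundaries is
  `(N/j)·C(m−1, j−1)·C(N−m−1, j−1)`, weighted by
  `e^{E_J(N−b)}·w_A^m·w_I^{N−m}`; computed in log space. The simulated
  per-sample domain occupancy converges to this distribution, which is the
  strongest single check that the event loop samples the correct stationary
  law (it is sensitive to rare states at the 10⁻⁴ level).

`c₀.₅(asymmetric)` is the root of mean activity = ½ on log concentration
(Brent's method on the transfer matrix, relative tolerance 10⁻⁶; mean
activity is monotone in `c`, so the root is unique). The symmetric case
returns 1 exactly. The deterministic equilibrium criterion is preferred over
re-solving on simulated CW bias because the two nearly coincide in the
coherent-switching regime and the former is reproducible; a
simulation-refined solve can be layered on top by the caller if needed.

## Trajectory analysis

* **Locked intervals / switch times.** Full-lock levels are exactly 0 and N
  active protomers on the `Δt` grid — no thresholds or filtering. An entry
  into a side is the first sample at its level after the most recent entry
  into the opposite side; a locked interval runs entry-to-opposite-entry
  (so consecutive intervals tile the record), and the switch time of a
  transition is last-departure-to-opposite-entry. Resolution error per
  interval is ≤ 2Δt.
* **CW bias** = fraction of samples with a majority-active ring; exact ties
  at N/2 count one half (unbiased under the model symmetry).
* **Hill coefficient**: OLS slope of `logit(Y)` on `ln(c/c₀.₅)` over points
  with `Y ∈ [0.15, 0.85]` (the sensitive region; saturated points carry no
  slope information). The default concentration grid is chosen adaptively:
  the sensitive region spans `±1.7/h` in `ln c`, so the grid half-width is
  `1.7/h_eq` (clipped to [0.05, 1]) with `h_eq` the deterministic
  equilibrium steepness `d logit(mean activity)/d ln c` from the transfer
  matrix — a pilot value, not a substitute for the simulated fit.
* **Dwell-time fits**: exponential by maximum likelihood (sample mean) with
  a KS goodness-of-fit p-value and, as a secondary output, the log-linear
  histogram slope (the classic graphical estimator); gamma by maximum
  likelihood with location fixed at zero.
* **Power spectra**: Bartlett average of non-overlapping Hann segments of
  the mean-removed activity trace, averaged into ~30 logarithmic frequency
  bins, then a least-squares Lorentzian fit `S₀/(1+(f/f_c)²)` in log-log
  space. An *interior peak* (the signature of a hidden multi-step cycle
  rather than single-nucleation switching) is a binned value exceeding both
  neighbours by 2 standard errors and the fitted curve by 5, with the bin
  standard error `√2·S/√(m·n_seg)` (the √2 absorbs Hann-window bin
  correlation) and bins with fewer than 50 effective periodogram samples
  excluded as unstable. These margins were set against negative controls
  (21 independent ring runs across biases, a synthetic random telegraph)
  and a positive control (an oscillatory trace), all kept in the test
  suite.

## Synthetic/reference conditions used by tests and the acceptance script

The study conditions are: the best-fit energies (`E_A = 0.65`,
`E_J = 4.15 k_BT`, N = 34), the classic high-cooperativity point
(`E_A = 1`, `E_J = 4 k_BT`), ring sizes {10, 34, 60, 100}, neutral bias
unless stated, `Δt = 0.1 ms`. Run lengths are chosen so each statistic
resolves to a few percent on one CPU: 300 s for interval means at the
best-fit point (~400 intervals), 1800 s at the classic point (~950
intervals, and enough samples to resolve the 0.4% four-domain state),
100–300 s for ring-size runs, and 7–11 concentrations × 50–150 s for Hill
fits. At these scales every reported mean carries a 2–8% standard error;
the Hill slope carries ~5%.

## Known limitations

* Locked-state intervals are *not* strictly exponential under the
  entry-to-entry definition: ~9–15% of intervals are short "mid-transit
  touch" events in which the activity trace grazes a full-lock level during
  a wander and reaches the opposite side within tens of milliseconds. The
  exponential law describes the body and tail well (log-linear fits look
  straight, and the power spectra are Lorentzian), but a KS test at a few
  hundred intervals per side rejects strict exponentiality — a genuine
  property of the model plus interval definition, not a numerical artifact
  (the same short mode is visible by direct inspection of raw traces).
* The multi-domain occupancies beyond two domains are rare-state
  probabilities (~0.4% for four domains at the classic point); the package's
  simulated values match the closed-form Boltzmann distribution to Monte
  Carlo error, and that exact value is the reference the tests assert.
* Only `λ_b = 0` binding is implemented (see above); torque generation,
  CheY phosphorylation dynamics upstream of `c`, and per-protomer
  heterogeneity are out of scope.
* The simulator is optimised for rings up to a few hundred protomers; the
  O(N) event search is negligible at that scale but would want a heap for
  much larger assemblies.
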