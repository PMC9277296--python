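# Methods

This note records the models implemented by the package, the numerical and
design choices behind them, what the synthetic populations do and do not
emulate, and the known limitations.

## Scalar memory model

A cell's bistable memory is the cubic normal form `dx/dt = ηx − x³ + u`
(dimensionless state and time). Everything in `memory_model` is closed-form:
roots come from the trigonometric/Cardano solution of the depressed cubic
(deterministic, no iteration; one Newton polish step on the single-root
branch), multiplicity from the discriminant `4η³ − 27u²` with a relative
tolerance of 1e−12, and stability from the sign of `η − 3x²` at each root
with a fold tolerance of 1e−9. Exact tangency is measure-zero in floating
point, so the fold label exists mainly for analytically constructed inputs
(e.g. η = 3, u = 2).

Basin membership is by sign of `x`; a state that lands exactly on 0 keeps
its previous label. This hysteretic tie rule gives monostable cells (η ≤ 0),
which decay toward the origin at zero input, a well-defined group at all
times.

## Population simulator

`simulate` integrates all N cells with fixed-step RK4 (default dt = 1e−3,
appropriate for O(1) dynamics) and a shared input updated every committed
step from the quantized ratio error. The group count is tracked as an
integer, so error samples are the exact values `r_d − k/N`; with an even
split target this makes "error is zero" exact in floating point, and all
zero tests elsewhere use the half-quantum threshold `1/(2N)`.

One refinement departs from plain fixed-step integration: when more than one
cell crosses zero inside a step, the step is redone as two half-steps
(recursively, floored at dt/2²⁰) with the controller re-evaluated in
between. The event-driven theory assumes events are isolated and feedback
reacts between them; without refinement, crossings clustering near `e = 0`
can straddle a step and produce sequences the discrete error maps forbid
(e.g. an event "at zero" under the shutdown relay). With it, every run's
event log replays exactly through the maps, which the test suite asserts for
all controllers.

Event timestamps are the midpoint of the sub-interval containing the
crossing; simultaneous crossings at the refinement floor are logged in
cell-index order. The population size is constant in this layer; division
and removal live in the chamber model.

The "N(m, v)" notation of the reference experiments is read as mean and
**variance** (presets use variance 4 → std 2); both `variance=` and `std=`
are accepted in distribution specs.

## Controllers

The relays are memoryless; the PI carries an integrator advanced by forward
Euler with the anti-windup reset (integrator zeroed when the error is zero
or changes sign) applied *before* the accumulation of the current step, so
"reset then accumulate" is deterministic. Sign-change detection compares
signs rather than the product of consecutive errors, which underflows for
subnormal error pairs. Outputs saturate at ±ū. In closed loop the comparison
"error equals zero" uses the half-quantum tolerance; the shutdown relay's
dead zone defaults to 0 and is configurable where actuation stress matters.

## Residual error bound

`residual_bound` evaluates `e_r0 = P[η ≤ 0]` and
`e_ru = max{0, p − r_d, p − (1 − r_d)}` with `p = P[η > η̂(ū)]` from the
analytic CDF (uniform, normal) or a seeded Monte-Carlo CDF estimate (default
10⁶ draws) for custom distributions. The bound is an N → ∞ statement
assuming the worst case in which every unswitchable cell starts in the group
with the smaller target share; the test suite checks it against worst-case
simulations with a finite-sample slack of three binomial standard deviations
plus one quantum.

## Toggle-switch chamber

The agent-based layer models a capacity-limited, well-mixed pool of *E.
coli* cells, each a six-state ODE: two mRNAs, the repressors LacI and TetR,
and internal aTc/IPTG relaxing to the chamber concentrations by asymmetric
first-order membrane exchange. Transcription is basal plus Hill-repressed,
with the effective repressor attenuated by its bound inducer (aTc
sequesters TetR, IPTG sequesters LacI). Kinetic defaults are the published
parameter set of the Lugagne et al. (2017) inducible toggle switch that this
layer models; at zero input they give two attractors (LacI ≈ 660 vs 18
a.u.; TetR ≈ 864 vs 63 a.u.), and saturating aTc (60 ng/ml) or IPTG
(0.5 mM) flips a cell in roughly an hour, the bottleneck being the ~60 min
protein dilution timescale. Phenotype classification compares LacI and TetR
normalized by their high-state levels, with ties keeping the previous label.

Units are minutes, a.u. for mRNA/protein, ng/ml for aTc, mM for IPTG.
Integration is vectorized RK4 at dt = 0.5 min (the dynamics are smooth and
non-stiff at these rates).

### Population dynamics

Each cell advances a division clock at a phenotype-dependent rate (default
1/42 min⁻¹, matching the protein dilution rate; per-cell ±10% uniform
jitter) and divides when it elapses; the daughter inherits the mother's
concentrations. Cells above capacity are removed uniformly at random,
emulating flush-out from a microfluidic trap; after the chamber is full the
sampled population size is constant. A 50% growth penalty on the LacI-high
phenotype is expressed by halving its division rate (the protein dilution
rate in the ODEs is kept nominal — a deliberate simplification; the ratio
dynamics, which is what this layer studies, are governed by the division
asymmetry).

### Heterogeneity — what the well-mixed chamber must add

Two per-cell heterogeneity sources are on by default, and they are not
cosmetic. A shared input applied to identical, uniformly exposed cells
switches them in lockstep: the ~60 min response lag exceeds any feasible
feedback reaction, so every corrective pulse commits essentially the whole
population and the closed loop degenerates into full-range relaxation
oscillations of the ratio. Ratiometric control by a common input works
precisely because cells respond at different times. The spatial system this
layer emulates gets that spread from inducer diffusion gradients across the
packed trap and from stochastic kinetics; the well-mixed surrogate models it
as:

* **production-rate variability** — heritable lognormal multipliers
  (CV = 0.2, the standard cell-to-cell variability level for this circuit)
  on the four production rates, spreading switching lags over roughly
  20–130 min;
* **exposure attenuation** — a lognormal factor (log-sd 1.0, median 1) on
  the external inducer concentration each cell sees, redrawn for the
  daughter at division as cells rearrange in the trap. This is the dominant
  desynchronizer: each pulse moves mostly the most-exposed cohort.

Multiplicative biochemical noise (Euler–Maruyama, σ = 0.05 on production
terms) is also on by default, matching the stochastic regime of the
emulated experiments; it contributes short-term decorrelation but is too
weak (steady-state CV of a few percent) to desynchronize switching on its
own. With these defaults the relay-controlled chamber holds `r_B` near the
target with oscillations of about ±0.1 and a steady mean error of ~0.01
even under the 50% growth penalty.

### Actuation and constraints

The measured ratio is sampled every 5 min; input changes take effect 1 min
later (inducer transport from reservoir to chamber); T-junction switches are
separated by at least 15 min (osmotic-stress limit). The T-junction injects
one inducer at a time at its maximum (mutual exclusivity, paired with the
shutdown relay); the dial-a-wave mixer injects a convex combination
(`u_aTc/U_aTc + u_IPTG/U_IPTG = 1`), driven by one PI per inducer channel
acting on the A- and B-side errors with the channel outputs normalized by
their maxima and projected onto the convex constraint. All constraint values
are configuration knobs.

### Fluctuation scaling

At steady state the ratio fluctuates mainly because divisions and flush-out
move the group counts by ±1 at a rate proportional to capacity, while the
step size is 1/capacity — a random walk with restoring feedback whose
stationary std scales like `capacity^{-1/2}` (a trap of side ℓ holds ∝ ℓ²
cells, so fluctuations scale like 1/ℓ). `fluctuation_scan` measures this by
repeated closed-loop runs; quadrupling the capacity should roughly halve the
std. The measured ratio sits somewhat below the ideal factor 2 because the
control-loop oscillation contributes a capacity-independent floor.

### Problem sizes

Default study sizes, chosen for single-CPU desk-scale runs: normal-form
experiments use N = 400 cells (dt 1e−3, horizons 1–3 time units);
growth-penalty chamber runs use capacity 200 for 2000 min with the steady
state read from the final 50% of samples; the fluctuation scan uses
capacities {50, 200} with 20 replicates of 1500 min each.

## Known limitations

* The chamber is non-spatial: no cell geometry, mechanics, diffusion fields
  or position-dependent flush; exposure attenuation is a statistical
  surrogate for all of these, calibrated qualitatively (partial switching
  per pulse), not against any measured gradient.
* The consortium PI loop carries a steady bias of ~0.08 in `r_B`: the toggle
  responds asymmetrically to balanced inducer mixtures, and because
  stochastic zero crossings of the error keep triggering the anti-windup
  reset, the integrator cannot accumulate enough action to remove a bias
  smaller than the fluctuation amplitude. The relay/T-junction loop does not
  show this.
* Event-map equivalence is exact for the population simulator by
  construction (refined stepping); the chamber layer samples the ratio at
  5-min intervals and makes no per-event claims.
* Convergence of the closed-loop laws is demonstrated empirically (property
  tests over seeded runs), not proved; the discrete error maps are the
  analytical backbone.
* Stochastic chemical kinetics of the normal-form layer, reporter
  maturation, and time-varying population size in the analytic bounds are
  out of scope.
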