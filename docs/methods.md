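# Methods

## The circuits and their nondimensional models

The object of study is a two-gene relaxation oscillator: an activator **A**
drives transcription of its own gene and of a repressor gene **R**, and
**R** closes a negative feedback on **A**.  How that negative feedback is
implemented at the activator promoter is the design variable:

* **Design I — competition.**  A and R multimers bind the activator
  promoter mutually exclusively, so the two occupancy terms are *summed*
  in the regulation denominator.
* **Design II — post-translational inhibition.**  R never touches the
  promoter; it catalyses degradation of A.
* **Design III — non-competition.**  Each factor has its own site and the
  occupancy factors *multiply*; relative to Design I the denominator gains
  a σx²y² cross term, which is what ultimately confines the activator
  amplitude.

With x and y the activator/repressor concentrations scaled by their
DNA-binding constants, time scaled by the repressor degradation rate
(τ = t·δ_R), and Δ = δ_A/δ_R, the families are

    dx/dτ = Δ [ β·f(x, y) − x·L(y) ]          (activator)
    dy/dτ = Δγ·g(x) − y                        (repressor)

    f_I   = (1+αx²)/(1+x²+σy²)        L = 1
    f_II  = (1+αx²)/(1+x²)            L = 1+σ′y
    f_III = (1+αx²)/[(1+x²)(1+σy²)]   L = 1
    g     = (1+αxⁿ)/(1+xⁿ)            (shared by Designs I–III)

α is the fold-activation of the bound promoter (default 50), β and γ the
transcription–translation strengths of the two genes, σ the repressor's
DNA-binding affinity relative to the activator's (fixed at 1 in every
comparative analysis, with σ′ = 1 for Design II).  β and γ absorb the
*activator's* degradation rate, which is why Δ multiplies both production
terms: the repressor nullcline is y = Δγ·g(x) and moves with Δ as well as
γ, while for Δ ≫ 1 the activator remains the fast variable.  This
placement of Δ is load-bearing — it is what produces oscillations at the
printed parameter combinations (β ≈ 0.08–1.6, γ ≈ 0.01–0.08 at Δ ≈ 10)
and the damped-band onset β_c = 0.225 — and the package treats it as part
of the model definition, not a tunable.

Three extensions reuse the same machinery: **GENERALIZED_III** frees the
Hill exponents (n-mer activator, m-mer repressor) in the non-competitive
form; **ATKINSON_COMP** is the competition form with n = m = 4, the
effective model of a construct in which each factor forms a DNA loop from
two bound dimers and the two loops exclude each other; **SMOLEN** routes
*both* genes through one competitively regulated promoter with a monomer
repressor by default,

    dx/dτ = Δ[β(1+αx²)/(1+x²+σy) − x],   dy/dτ = Δγ(1+αx²)/(1+x²+σy) − y.

Exponents are restricted to integers (multimer degrees); Designs I–III are
structurally fixed at n = m = 2 and ATKINSON_COMP at n = m = 4 — asking
for anything else is an error, not a warning.

Periods are reported in units of 1/δ_R; `to_hours(P, delta_R)` converts
(e.g. a characteristic period of ≈2 at δ_R = 0.02 h⁻¹ is ≈100 h — slow
repressor turnover buys oscillations at the price of multi-day periods).

## Equilibria and stability

For every gene-circuit family the repressor nullcline is known in closed
form (for the Smolen family it is the positive root of a quadratic), so
fixed points are bracketed on the 1-D reduction F(x) = ẋ(x, y_y(x)) over a
log-spaced grid (4000 points spanning the box), polished by Newton
iteration with the analytic Jacobian to residual < 1e-9, and merged at
1e-6 separation.  The search box is derived from the model itself
(x* ≤ αβ, y* ≤ Δγα, with a 10× margin): production saturates, so no
equilibrium can escape it.  This reduction cannot lose the three-crossing
multistable states that organise the competitive design's saddle-node
exits.  Generic planar systems (the normal-form oracles in the test
suite) fall back to multi-start Newton seeded from a regular grid.

Stability classes come from the Jacobian eigenvalues (node / focus /
saddle, stable / unstable).  A *damped* region is where the stable point
is a focus; `damped_onset` bisects the complexification boundary to 1e-4
relative — chosen to match the three significant figures of the β_c it
reproduces.  When several coexisting stable states disagree about their
class the conflict is raised, never silently resolved.

## Trajectory classification

The compiled Dormand–Prince 5(4) integrator (adaptive step, PI control,
cubic-Hermite sampling on a uniform output grid) exists purely for
throughput: parameter sweeps evaluate tens of thousands of trajectories
and per-call overhead of a generic ODE driver dominates at that scale.
scipy's RK45 integrates the generic oracle systems and cross-checks the
kernel in the tests (amplitudes agree to ~1e-3).  Output steps are
min(0.05, period/50), with the period estimated from the focus frequency;
states are clipped at zero (undershoot is at integration-tolerance level).

A trajectory is *sustained* when, after discarding the first half of the
window, at least 8 successive activator maxima agree in height and
spacing to 1% (peak times and heights refined by local quadratic
interpolation — at 50 samples per period the raw sample grid alone
quantises spacings by ~2%); *damped* when the peak train decays **and**
the envelope actually shrinks (halves within the window); *steady* when
the tail is flat; otherwise the window doubles, up to a cap of 2000 time
units (long enough for the near-onset periods of order 100 that the
saddle-node routes produce).

Two guards matter near bifurcations, where finite-window classification
is genuinely ill-posed:

* **No stable equilibrium ⇒ never steady/damped.**  A bounded planar flow
  without a stable equilibrium cannot settle (Poincaré–Bendixson), so an
  apparently decaying peak train there is a slow transient — e.g. the
  amplitude overshoot while landing on a relaxation cycle — and the
  window is extended instead.
* **Stable equilibrium present ⇒ confirm sustained.**  Just inside a
  damped band the focus ringing can decay by far less than 1% per period
  and mimic a cycle; a "sustained" verdict with a coexisting stable state
  is accepted only once its amplitude is stationary (±2%) across a window
  doubling, and reclassified damped if it collapses.

The waveform statistic `spikiness` is π·amplitude/(period·max|dx/dτ|):
exactly 1 for a sinusoid, →0 for relaxation waveforms whose rise is a
jump between slow branches.  A duty-cycle measure (peak width at half
maximum over period) was tried first and discarded: the competitive
design's cycle just past its saddle-node onset dwells on the *high*
branch (the saddle-node ghost sits there), giving a square-ish wave with
duty ≈ 0.44 that a FWHM measure scores *more* sinusoidal than the
genuinely smooth small cycle of the non-competitive design.  The slope
statistic orders the two as the dynamics warrant (≈0.07 vs ≈0.27 at
α = 50, Δ = 11, β = 1.58, γ = 0.079); 0.35 is a descriptive threshold for
"pulse-like", never used in verdicts.

## Bifurcation scans and transition classification

`scan_control` follows the attractor in both directions along the grid
(each integration starts from the previous attractor's final state, so
coexistence windows are visible as forward/backward disagreement), and
cells whose both passes fail are re-tried from the standard start before
being accepted as non-oscillatory.  Undecided cells stay undecided —
events are classified across them, never through them.

At a verdict change the machinery bisects two different boundaries:

* the **cycle edge** (sustained verdict, attractor-continued, 1e-4
  relative);
* the **equilibrium-stability edge** (existence of a stable fixed point,
  3e-6 relative) when a stable state exists on the steady side.

If the equilibrium count changes by ±2 across the stability edge the
event is a saddle-node fold; with an unchanged count it is an eigenvalue
(Hopf) crossing.  Evidence then decides the kind:

* **snic** — fold coinciding with cycle death, period following
  T = T₀ + C·(μ−μ_c)^p with p = −0.5 ± 0.1.  The regular part T₀ (the
  time a relaxation cycle spends away from the bottleneck) is profiled
  over [0, 0.9·min T]; without it even the textbook saddle-node-on-circle
  law fits to a much shallower exponent.  Periods are measured at probes
  0.3%–10% of a grid step inside the fold, where the divergence is
  actually visible.
* **hopf_super** — stable focus adjacent, cycle amplitude growing from
  zero with exponent 0.5 ± 0.15, fitted at probes 3%–100% of a grid step
  inside the edge (closer probes sit inside the critical-slowing region,
  where finite windows underestimate the asymptotic amplitude).
* **hopf_sub** — eigenvalue crossing with a finite-amplitude cycle at
  onset (amplitude at the nearest probe above 30% of the band's maximum).
  Width-based hysteresis (cycle edge beyond the stability edge) is
  recorded as evidence but not used to decide: near-Hopf ringing biases
  the cycle-edge bisection by ~0.5% in either direction, the same order
  as genuine coexistence windows here.
* anything conflicting is reported as **ambiguous** with the full
  evidence attached.

Both closed-form oracles validate the pipeline end to end: the planar
normal form ṙ = μr − r³ is classified supercritical Hopf at μ = 0 with
amplitude exponent ≈ 0.44, and the regularised saddle-node-on-circle
system (θ̇ = μ − sinθ) as snic at μ = 1 with period exponent ≈ −0.50 and
the period matching 2π/√(μ²−1) to 1%.

### A fine structure the figure-level analysis cannot see

At γ = 0.01 the non-competitive design's low-β frontier (onset ≈ 0.076,
the "frontier around β ≈ 0.1") is a saddle-node *loop*, not a pure SNIC:
the fold at β = 0.075568 sits slightly off the cycle, the cycle dies at a
homoclinic ≈0.1% below it, and the period saturates near ~10 (growing
from ~2.5 deep in the band — long, but logarithmically divergent rather
than as an inverse square root; measured exponents are −0.15 to −0.33
depending on the probe window).  The pure −1/2 law is exhibited by the
same model a little away in parameter space: at the γ = 0.005
cross-section of the same frontier (−0.46) and at the competitive
design's γ = 0.05 exit (−0.54).  SNIC and SNL are adjacent unfoldings of
the same codim-2 structure and are indistinguishable at figure
resolution; the acceptance test for the −0.5 exponent at γ = 0.01 is
left failing rather than loosened, as a faithful record of this
discrepancy.

## Period maps

`sweep_2d` classifies every cell of a log-spaced (β, γ) grid.  Cells
whose unique equilibrium is a stable node are settled from the
eigenvalues alone; everything else is integrated.  The default window is
β ∈ [10⁻², 10¹], γ ∈ [10⁻³, 10⁰] at 60×60 — the axis window is the
package's own choice, bracketing all printed (β, γ) pairs with a decade
of margin, so oscillatory *fractions* are comparisons on this window,
not absolute figures.  The Smolen family oscillates on a thin ridge
(γ ≈ 10β² at Δ = 4) in a different corner of parameter space, so its
default window is shifted to β ∈ [10⁻¹, 10²], γ ∈ [10⁻², 10¹].
Undecided cells are flagged and counted; maps with more than 1% of them
are rejected rather than summarised.  Cells are independent, so results
are identical under any evaluation order; rebuilding a map reproduces it
bit for bit (the provenance hash covers design, parameters and grids).

## Stochastic counterpart

Each design maps onto a four-channel jump process at the propensity level
(production channels Ω·Δ·βf and Ω·Δγ·g evaluated at counts/Ω, loss
channels Δ·X·L and Y), simulated exactly with the Gillespie direct method
in a compiled kernel, seeded and bit-reproducible.  The propensity-level
description (rather than explicit promoter-state chains) is the direct
stochastic counterpart of the ODEs being compared; explicit promoter
states are a documented extension point.  Ω converts concentration to
copy number; the Ω → ∞ ensemble mean is the deterministic trajectory
(verified at Ω = 10²–10⁴, with the Ω = 10⁴ ensemble mean within 5% of
the ODE over a period), and the default Ω = 500 puts a concentration of
1 at 500 molecules.

Peak calling on stochastic traces smooths with a moving average of 5% of
the expected period and requires a prominence of 25% of the trace's
interquartile range, since raw jump noise manufactures maxima.  For the
noise-induced-oscillation comparison each design is parked just *outside*
its own oscillatory region at γ = 0.05 — the competitive design 1% past
its saddle-node exit (an excitable steady state), the others 1% below
their Hopf entries (damped foci) — a placement the code verifies against
the deterministic verdict before simulating.  Intrinsic noise then drives
peak trains in all designs, with inter-peak interval CV and tail index
(P95/P50) largest for the competitive design (excitable excursions at
noise-determined intervals) and smallest for the non-competitive one
(coherent ringing at the focus frequency), the post-translational design
in between.

## Problem sizes

The analysis scripts default to 40×40 maps (≈40 s each), 60-point scans,
and 50-run SSA ensembles at Ω = 500.  The test suite uses 10×24-cell to
24×24-cell maps, 51–70-point scans, and two disjoint 40-run SSA seed sets
at Ω = 200 over 150 time units; these sizes are the package's choices for
a fast default run, and every qualitative comparison they support was
spot-checked unchanged at the larger sizes.  The acceptance script uses a
120-point eigenvalue scan (t1), a 16×16 map (t2) and a 40-point verdict
scan (t3), all bisected to 0.1% where a boundary is reported.

## Known limitations

* Verdicts near bifurcation boundaries are finite-window statements;
  boundaries are resolved to ~0.1% of the control parameter, and the
  SNIC/SNL distinction above shows what lives below that resolution.
* Unstable limit cycles are not continued (subcriticality is inferred
  from onset amplitude, with hysteresis width recorded as evidence); no
  Floquet machinery; no codim-2 continuation.
* The stochastic model adds no extrinsic noise, no explicit promoter
  states, and no mRNA stage; likewise the deterministic models are the
  two-variable protein-only reductions (translation slaved to
  transcription), which is the level at which the designs are compared.
* The synthetic-data generator (the SSA module) emulates intrinsic
  copy-number noise only; passing the noise tests says nothing about
  real-circuit extrinsic variability, growth-rate coupling, or parameter
  drift.
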