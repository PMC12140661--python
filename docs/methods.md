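# Methods

## Model

The plant is the Kirschner–Panetta tumour–immune system over effector
cells *x*, tumour cells *y* and IL-2 *z* (time in days, concentrations
in the model's cell/IL-2 units; no absolute unit is defined for *z*, so
"reached zero" thresholds are configurable rather than unit-derived).
Default parameters are the standard literature set: c = 0.05 (top of
the admissible range 0 ≤ c ≤ 0.05, the conventional stress case),
μ₂ = 0.03, p₁ = 0.1245, g₁ = 2·10⁷, g₂ = 10⁵, r₂ = 0.18, b = 10⁻⁹,
a = 1, μ₃ = 10, p₂ = 5, g₃ = 10³.  r₂ = 0 is admitted so that
pure-clearance test scenarios with closed-form channels can be built;
all other rates must be strictly positive.  The vector field performs
no clipping of negative states — admissibility is enforced only through
the Michaelis–Menten denominators, and negativity is reported as a
closed-loop diagnostic, keeping the mathematical object faithful.

## Controller

Backstepping with costate target x*(y) = (α/a)(g₂+y)(r₂(1−by)+k₁) and
error e = αx − x*.  dx*/dt is always evaluated analytically through the
polynomial form (2Ay+B)·dy/dt — exact cancellation is the point of the
construction, so numerical differentiation is never used.

Three variants:

* **published** — the published law verbatim.  Its algebra is
  self-consistent only at α = 1: the printed closed-loop tumour rate
  carries a 1/α on the k₁y term where direct substitution gives none,
  and the Lyapunov cross terms cancel only at α = 1.  This variant
  therefore hard-requires α = 1.
* **general_alpha** — a re-derivation valid for all α > 0: u₁ is chosen
  so that de/dt = a·y²/(g₂+y) − α·k₂·e, which with the exact
  dy/dt = −k₁y − (a·y/(g₂+y))·e/α gives
  dV/dt = −k₁y² − k₂e² − k₃z² for V = e²/(2α) + y²/2 + z²/2.
  Coincides with the published law at α = 1 (verified term-by-term in
  the tests).
* **robust_nominal** — the same law evaluated with the controller's
  nominal parameter belief while the plant uses the true set.

Gain presets are reconstructions (the source experiments do not print
their gains), pinned by two published anchors: the post-therapy
effector level 27 000 cells/mL equals the costate limit
(g₂/a)(r₂+k₁) at α = 1, k₁ = 0.09, and IL-2 clearance within 40 days
requires k₃ ≥ ln(7000)/40 ≈ 0.22.  Hence `steady_therapy`
(α=1, k₁=0.09, k₂=1, k₃=0.25) and `fast_eradication`
(α=1, k₁=0.25, k₂=1, k₃=0.5), the latter giving tumour eradication and
u₂ decay within 50 days.  Control inputs may go negative transiently;
an optional clip-at-zero flag exists but is off by default, since the
design imposes no positivity constraint.

## Numerics

* Integer order: classical RK4 on a fixed grid (default step 0.01 d),
  with the feedback law re-evaluated at every stage; an adaptive
  Dormand–Prince option delegates to scipy.  Divergence is declared
  when any state magnitude exceeds 10¹⁵.
* Fractional order: Adams–Bashforth–Moulton predictor–corrector for the
  Caputo derivative on a uniform grid (default step 0.05 d over the
  150-day horizon, keeping the O(N²) memory sums cheap), full memory by
  default, standard integer-order initial condition at t₀.  Optional
  short-memory truncation freezes an expired node's contribution at its
  boundary weight; at q = 1 all history weights are constant, so
  truncation provably cannot change the result (up to summation
  order, a few ulp), while for q < 1 it is the usual short-memory
  approximation.
* Mittag-Leffler oracle E_q(s) = Σ sⁿ/Γ(qn+1): compensated power series
  for s ≥ −2, and for s < −2 (where the alternating series cancels
  catastrophically) the completely-monotone spectral integral evaluated
  with adaptive quadrature split around its near-pole at r = 1.
  Supported domain |s| ≤ 50, target 10⁻¹⁰ absolute; validated against
  E_½(−x) = eˣ²·erfc(x).
* Lyapunov verification: the recorded V channel is differentiated with
  a 4th-order central stencil (a 2nd-order stencil leaves ~7·10⁻⁵
  relative residual at h = 0.01, an order-of-magnitude artefact, while
  the 5-point stencil reaches ~5·10⁻⁹, far below the 10⁻⁶ check
  tolerance).  Fractional runs are checked for monotone nonincrease of
  V only: a pointwise Caputo-derivative check of V would require a
  separate fractional-derivative estimator and is out of scope.
* The 1/α Lyapunov weight is attached to the *e* component, matching
  the scalar definition of V; the matrix form printed elsewhere (weight
  on the first component) is taken as a typographical slip.  λ₃ and λ₄
  are computed in closed form: λ₃ = min(k₁,k₂,k₃), λ₄ = max eigenvalue
  of M = diag(1, 1/α, 1).

## Closed-loop experiments

Scenario presets: `nominal` (200 d, steady-therapy gains), `fast`
(100 d, fast-eradication gains), `fractional` (q = 0.98, 150 d, step
0.05 d, fast-eradication gains); all start from
x(0) = 10 000, y(0) = 12 000, z(0) = 7 000.  Eradication time is the
*sustained* first passage of |channel| below an absolute threshold
(default 1 model unit; a 1%-of-initial mode is available) — a
continuous model never reaches exactly zero.  Settling time is entry
into a ±2% band around the final value (mean of the last 5% of the
horizon).  Discrete-measurement mode holds the inputs between samples
(zero-order hold), integer order only; note the open-loop IL-2 channel
grows at ≈ p₂·x/g₃ ≈ 200/day at the therapeutic operating point, so
sampling intervals beyond ~0.03 d destabilise the sampled loop — the
hold-consistency checks use Δt ≤ 0.02 d.

### Uncertainty sweeps

Robustness is exercised as parameter mismatch: the plant's parameters
are scaled by (1±ρ) (or with random per-parameter signs, seeded) while
the controller keeps its nominal belief.  The default uncertainty set
is the eight tumour/effector kinetic parameters
(c, μ₂, p₁, g₁, g₂, r₂, b, a).  The IL-2 pharmacology (p₂, g₃, μ₃) is
excluded by default on analytical grounds: the feedback cancels the
production term p₂·x·z/(g₃+y) ≈ 200·z *exactly*, so a relative error ρ
there leaves a residual proportional to z with gain of order 200ρ —
orders of magnitude above any clinically sensible k₃ — and the loop
diverges for inflation (transient window while g₃ ≲ y) and regrows in
the tail for deflation (+ρμ₃ − k₃ > 0).  This is a genuine structural
property, not a numerical artefact: a bounded-perturbation (BIBO)
analysis does not cover state-proportional perturbations of that size,
so those three parameters must be treated as calibrated, not swept.
With the kinetic uncertainty set, the inflate sweep at ρ = 0.1…1.0 is
bounded at every level, the tumour is suppressed below 1% of its
initial burden, and the tail of ‖(y,e,z)‖ grows roughly linearly in ρ,
the numerical counterpart of the ultimate bound.

### Fractional tail and the eradication threshold

The Caputo loop converges asymptotically with an algebraic tail:
linear fractional relaxation decays like t^(−q)/Γ(1−q) rather than
exponentially.  At q = 0.98 the tumour channel passes ~15 cells at
80 d and ~7.7 at 150 d (step-size robust), and its sustained crossing
of the absolute threshold 1 occurs near 1128 d.  On a 12 000-cell axis
this tail is visually indistinguishable from zero from ~30 d onward,
which is what a "reaches zero near 80 d" figure reading captures; under
the 1%-of-initial criterion (120 cells) eradication occurs near 25 d.
The acceptance script reports the honestly measured absolute-threshold
crossing from an extended-horizon run rather than a threshold chosen to
flatter the claim.  Effector settling in the fractional loop is fast
(≈ 8.7 d into the 2% band) because x tracks the costate target, whose
transient is governed by the integer-like early-time response.

## Gain tuning

The tuning MDP is episodic: an action is a gain triple (k₁,k₂,k₃) in a
positive box (default (0.01, 1]³), an episode is a short closed-loop
run (5 d at step 0.1 — 50 steps, keeping hundreds of episodes at desk
scale), the observation is a log-compressed 10-point subsample of
(u₁, u₂, y), and the per-step reward compares the applied input with
the reference input of a nominal episode run with the base gains.  The
piecewise reward is implemented verbatim: +σ₁|u−u_ref| inside the
deadband ε, −σ₂|u−u_ref| outside, with the boundary |dev| = ε on the
penalty branch (strict `<`).  As printed, the in-band branch rewards
*larger* deviations, contradicting the stated intent of rewarding
proximity; a `corrected` mode returning σ₁(ε−|dev|) in-band is provided
but verbatim remains the default.  The condition is read on |u−u_ref|:
a signed reading would reward arbitrarily negative deviations.

Optimizers: a soft actor-critic (twin critics, replay buffer,
reparameterised tanh-Gaussian policy, fixed entropy temperature,
two 64-unit hidden layers, Adam at 3·10⁻³) implemented directly in
numpy with manual backpropagation, operating on the one-step episodic
MDP (terminal transitions, so critic targets are the episode returns,
normalised online); and a seeded cross-entropy method (population 16,
25% elites) as a derivative-free fallback.  Both are deterministic
given a seed, never leave the action box, and agree on a 1-D convex
surrogate; acceptance for the tuner is property-based (reproducibility
and improvement), never exact-value, since network-scale
hyperparameters are not printed anywhere authoritative.

## What the scenarios do and do not show

The presets are deterministic replicas of the published experimental
conditions (initial state, parameter table, horizons); there is no
measurement noise, no inter-patient variability, and the perturbation
model is time-invariant parameter mismatch rather than exogenous
time-varying disturbance.  Passing tests therefore demonstrate the
controller's mathematical properties under the model, not clinical
performance: the model has no pharmacokinetics, no positivity
constraint on inputs, and tumour/effector levels below one cell-unit
are a numerical idealisation.

## Problem sizes

Default runs: 20 001 grid points (200 d at 0.01 d) for the nominal
integer loop, 10 001 for the fast loop, 3 001 fractional steps (150 d
at 0.05 d), a 10-level sweep of 100-day runs, and tuner budgets of
~200 episodes of 50 steps; the whole test suite and the acceptance
script each complete in well under a minute of CPU except the
extended-horizon fractional run (~20 s).
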