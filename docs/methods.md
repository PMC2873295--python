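# Methods

This note documents the models, algorithms, defaults and numerical choices
in `autoassay`, what the virtual instrument does and does not emulate, and
the limits of what the in-silico tests demonstrate.

## Parameter spaces and designs

Assay conditions live in a bounded, ordered `ParameterSpace`.  Each axis
carries a scaling — `linear`, `log` (base-10; requires a positive lower
bound) or an arbitrary strictly monotone callable, checked by probing on a
65-point grid — applied *before* normalization, so that "distance" in the
unit cube reflects a-priori sensitivity (e.g. decade-spanning
concentrations).  All modelling, distance bookkeeping and optimization
happen in the normalized cube; conditions are stored in natural units, and
normalize/denormalize are exact mutual inverses on in-bounds values
(custom scalings are inverted by bisection to 1e-14).

Space-filling designs are **maximin Latin hypercubes**: 50 seeded LHS
draws (scipy `qmc.LatinHypercube`) are scored by minimum pairwise
Euclidean distance and the best is kept.  This is seedable, cheap, and
covers the full allowed range; the test suite verifies it beats the median
of 1000 uniform-random designs.  Factorial designs are full cross products
with deterministic ordering (replicates outermost, later axes fastest), so
that measurement logs are stable and joinable; `cross_design` crosses an
existing design with levels of one new axis (e.g. several substrate
concentrations per space-filling point).  Condition ids follow
`round:serial` so identities survive the whole closed loop.

## Kriging response surfaces

Responses y over normalized points X are modelled as a GP with constant
mean μ (the grand mean), unit-variance anisotropic Matérn-5/2 kernel with
per-axis length scales ℓ, and a ridge/noise term λ ("smoothing"):

* **Smoothing by GCV.**  GCV(λ) = n‖(I−A)y‖²/tr(I−A)² with
  A = K(K+λI)⁻¹, evaluated for a whole log-spaced grid (10⁻¹⁰ … 10⁴, 57
  points) from one symmetric eigendecomposition of K, then refined locally
  by bounded scalar minimization in log λ.  On noise-free smooth data GCV
  collapses λ to the bottom of the grid and the surface interpolates
  (training-point error < 1e-3 in the tests); on pure noise it grows λ
  until the surface shrinks to the grand mean (prediction variance ≤ 10%
  of the sample variance in the tests).
* **Length scales by profile marginal likelihood.**  Nelder–Mead on
  log ℓ (clipped to e^±4, start at unit length scales, `adaptive` simplex
  for d > 2) minimizing the profile negative log marginal likelihood, with
  λ and the signal variance profiled out analytically.  GCV was evaluated
  for this role and rejected: λ and ℓ trade off into a single effective
  smoothing bandwidth, so the profile-GCV surface is flat along a ridge in
  ℓ and the selected length scale is arbitrary, while the marginal
  likelihood recovers the generating length scale of GP draws (within a
  factor of 3 in ≥ 80% of seeded replicates in the tests).  The *final*
  smoothing at the chosen length scales is the GCV choice.
* **Predictive spread.**  σ² is the standard Kriging plug-in estimate
  ỹᵀ(K+λI)⁻¹ỹ/n and se²(x) = σ²·(1 − k(x)ᵀ(K+λI)⁻¹k(x)) — the
  uncertainty of the *signal*, not of a future noisy observation, which is
  what an acquisition rule should use.  Replicated points are handled
  exactly; a 1e-10 jitter guarantees factorizability at λ → 0.
* **Optima** are located by multistart L-BFGS-B on the predictive mean
  over the unit cube (default 20 uniform starts plus the best training
  point), deterministic for a fixed seed.  Maximization negates the
  objective.

A fitted model persists to JSON (hyperparameters + training table) and
re-factorizes on load; `slice_grid` exports two-axis mean/se grids for
surface plots.

## Batch optimization campaign

`run_campaign` drives the closed loop: measure an `initial_n`-point
space-filling design (default 20), fit the surface, record its optimum;
then for each refinement round propose `batch_n` points (default 19),
measure, refit, record.  Five rounds total by default, i.e. 96
measurements.

Proposals are drawn from a pool of `1000·d` uniform candidates with
probability ∝ exp(−E/T), where E is the lower confidence bound
mean − k·se (sign-reversed for maximization) with k = 1.96 by default.
The temperature default is adaptive — the interquartile range of the pool
energies — making the weighting scale-free; a constant override is
available.  Draws are without replacement within a batch, and each
accepted point joins the exclusion set before the next draw.

The minimum normalized distance to all existing and previously accepted
points is `min_dist0 · shrink^(j−1)` in refinement round j (defaults 0.25
and 2/3).  A violating candidate is *repaired*: 500 draws from an
isotropic normal centred on it (σ = the round's min-dist), clipped to the
cube; the feasible draw closest to the original is taken, or — if none is
feasible — the draw farthest from its nearest neighbour (flagged
`fallback` in the log).  Every measurement row records its acceptance
path (`initial` / `boltzmann` / `repair` / `fallback`).

`nearest_k_mean` computes the per-iteration quality diagnostic: the mean
response of the k measurements (default use: 5) closest to that round's
optimum estimate, ties broken by measurement order.  With a noise-free
concave objective the sequence is non-decreasing round over round; on the
virtual enzyme with the exploration bonus k = 1.96 a mid-campaign dip of a
few percent can occur, but the final round never falls below round 1 in
the test conditions.

If the evaluator raises, the campaign aborts with the partial log attached
to the exception — nothing measured is lost.

## Diprotic pH kinetics

The rate law (rapid-equilibrium solution of the three-protonation-state
scheme) and its consequences — MM reduction, apparent constants
K_m,app = K_M·f_E/f_ES and V_max,app, the closed-form optimum pH for
α = β = 0 — are given in the module docstring and README.  The
implementation is verified against an independent linear-algebra solve of
the equilibrium species system across random parameter sets.

Units are the field's mixed convention: substrate and K_M in mM,
dissociation constants and c_H in M, activity in mU.  They are kept as
given; the rate law is dimensionless in the ratios where it must be.

**Multistart fit.**  Weighted least squares over the 8 parameters;
V_max, K_M and the four dissociation constants are optimized as logs
(positivity and conditioning), α and β linearly with a ≥ 0 bound.  Starts:
the guess itself first, then n_starts − 1 copies with each parameter
multiplied by an independent log-uniform factor in [10⁻³, 10³] ("a random
number between 10⁻³ and 10³" is only meaningful log-uniformly for a
multiplicative six-decade perturbation).  Each start runs scipy
`least_squares` (trust-region reflective, max 1000 evaluations);
*converged* means the solver's success flag — an additional relative
gradient-norm cut was considered and dropped, because fits that terminate
on `ftol`/`xtol` with essentially zero cost would be discarded by any
fixed gradient threshold.  The best SSR among converged starts wins, so
the result is never worse than the guess.  Asymptotic standard errors come
from the Jacobian mapped back to natural units.

**Per-pH Michaelis–Menten fits** use log-parameter least squares from
three deterministic starts, with asymptotic SEs from the exact
natural-parameter Jacobian.  The covariance uses the *true* inverse of
JᵀJ, not a pseudo-inverse: in the non-saturating (effectively first-order)
regime JᵀJ is near-singular and a pseudo-inverse would silently truncate
exactly the unidentifiable direction, hiding its variance.  The
`identifiable` flag is False when se(K_m)/K_m exceeds the threshold
(default 3); in the first-order regime the flag is realization-dependent —
a finite noisy sample can by chance mimic saturation curvature — so tests
assert it on a non-saturating realization and as the majority outcome.

## Microplate arithmetic

* **Volume planning:** volume = target·end_volume/stock (or a fixed
  volume), water fills to the end volume (default 225 µl) exactly.  A
  nonzero volume below the minimum pipettable (default 3 µl, configurable
  per stock) raises a precision error naming the component; overfull
  mixtures and per-stock maxima raise infeasibility errors.
* **Two-buffer pH system:** a strictly monotone PCHIP spline maps
  basic-stock fraction → pH; the inverse is computed by bisection on the
  spline itself, so forward∘inverse is identity to 1e-12.  Because the
  measured 16-point calibration behind the real system is not available as
  a table, `synthetic_buffer_calibration` generates a synthetic stand-in
  from charge balance of an equimolar MES (pKa 6.15) / TRIS (pKa 8.06)
  two-stock system adjusted to pH 4.75 and 9.2 — reproducing the nearly
  linear mid-range such buffers show.
* **Slope extraction:** OLS over trace points inside an OD/time window
  (defaults: min OD = blank + 0.05, max OD = 2.5), reported per minute.
  The minimum-OD rule exists because depleted-substrate floors bias the
  full-window slope low (demonstrated in the tests).
* **Activities:** mU is defined as nmol NADH consumed per minute in the
  well, so act_total = |slope|/ε · V_well; ε comes from a free-intercept
  standard-curve regression (the intercept is the plate blank).  Per-mg
  normalization divides by bradford_coeff·A_BF·V_lysate and is omitted,
  with a warning, when the protein amount is missing or non-positive.

## The virtual laboratory

The simulator generates what the plate reader would see:
A340(t) = blank + ε·max(0, NADH₀ − r·t) + photometric noise, with the
consumption rate r combining the enzyme (v/V_well) and a pH-dependent
spontaneous-oxidation background, flooring at the blank when NADH is
depleted.  Defaults: ε = 0.62 A340/mM, blank = 0.04, NADH₀ = 0.625 mM,
V_well = 225 µl, 30 cycles at 60 s.

* **Ground-truth enzyme.**  The reference diprotic constants
  (K_M 0.53 mM, K₁ᴱ 1.9e-6, K₂ᴱ 4.4e-9, K₁ᴱˢ 2.2e-6, K₂ᴱˢ 9.6e-9 M,
  α 0.16, β 0) with a per-well V_max of 2.5 mU.  The per-well scale is
  deliberate: 0.625 mM NADH in 225 µl is ~140 nmol, so a per-well rate
  must stay in the few-nmol/min range to give measurable 30-minute traces;
  2.5 nmol/min is plausible for ~0.2 µg lysate protein per well.
  Parameter-recovery studies that need the full reference V_max (1.1e4 mU)
  operate on rate data directly and are unaffected.
* **Background oxidation:** constant 1e-5 A340/min above pH 5.5, growing
  by 4e-5 per pH unit below it (continuous at the knee).  The magnitudes
  are chosen once so the background stays below 10% of the enzymatic
  signal everywhere on the 8 pH × 6 PEP grid, consistent with blank-well
  controls being small; `measure_design` subtracts the expected background
  from the slope, as a blank correction would.
* **Effector axes** (KCl, fructose 1,6-bisphosphate) have no mechanistic
  model; they are emulated as smooth multiplicative bumps
  floor + (1−floor)·exp(−(log1p(c) − log1p(c_opt))²/2w²), peaking exactly
  at c_opt with decline at high concentration — the rise-and-fall shape
  seen in measured activity surfaces.  This makes the simulator's true
  optimum known analytically, which is what the closed-loop tests need.
* **Noise:** independent log-normal multipliers (CV default 2%) on the
  dispensed substrate/effector concentrations, i.i.d. Gaussian photometric
  noise (default 0.003 A340) per reading.  All randomness flows from
  explicit seeds; repeated runs are bit-identical.

**What the simulator does not emulate:** the coupling enzyme (LDH) is
treated as instantaneous (it is used in large excess precisely to make
this a good approximation) — no coupling lag; no well-to-well crosstalk,
evaporation, temperature drift, or pipetting carry-over; pH is dispensed
exactly (buffer-fraction errors are not propagated).  Consequently,
passing closed-loop tests demonstrates the *algorithms* — design spread,
surrogate quality, acquisition behaviour, estimator consistency — under
realistic signal shapes and noise levels, not robustness to every
instrument pathology.

## Problem sizes and test design

The simulation studies use the workflow's native sizes: 20 + 4×19
campaign rounds over a 3-D space, the 96-well pH × PEP factorial, 200
multistart fits for noise-free recovery (5000 remains the default for
noisy field use), 10 campaign seeds, 50 GP-draw replicates, 10⁴
distributional draws.  At these sizes the full suite runs in about half a
minute.

## Known limitations

* The GP is stationary with a constant mean; strongly trending responses
  near boundaries inflate the plug-in σ² slightly.
* The acquisition handles box bounds only, and candidate pooling scales
  poorly beyond ~10 dimensions (as does any space-filling design there).
* The closed-form optimum pH requires α = β = 0; with active ionized forms
  use the numeric grid (the virtual lab's `true_optimum_condition` does).
* β sits on the boundary of its parameter space when the true value is 0,
  so its asymptotic SE is only indicative; tests treat β in absolute
  terms.
* Substrate (PEP/ADP) protonation is outside the model; at pH well below
  5 the diprotic form is known to be an incomplete description of real
  PYK data.
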