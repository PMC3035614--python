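# Methods

## Models

One consumer population split into juveniles (`C_J`) and adults (`C_A`),
coupled to logistic resources by linear (mass-action) trophic interactions.
Maturation and reproduction are both proportional to food intake: the
juvenile maturation flux `Σ b_J a_J R_J C_J` leaves the juvenile class and
enters the adult class, and the adult intake `Σ b_A a_A R_A C_A` enters the
juvenile class as reproduction. Death rates `d_J`, `d_A` are constant.
Time is measured in units of the resource growth rate (baseline `r = 1`),
abundances in units of carrying capacity.

Three variants of multiple resource use:

* **Additional resources** — `n_J`/`n_A` resources per stage. Any resource
  may be an allochthonous subsidy: its logistic term is replaced by donor
  control `I − l R`, so its standing stock is set by external input, not
  self-renewal. A subsidized resource with `I = 0` is structurally absent
  and is excluded from coexistence-positivity requirements.
* **Multiple habitats** — `n_J`/`n_A` identical habitats with one resource
  each. Colonization is random, so each maturation flow is divided evenly
  (`1/n_A`) over adult habitats and each reproduction flow evenly (`1/n_J`)
  over juvenile habitats. Habitat counts may be non-integer in the
  analytic (symmetric mean-field) branch. Per-habitat carrying-capacity
  overrides introduce productivity heterogeneity.
* **Interstage sharing** — one resource per stage, but stage `h` consumes
  resource `i` at rate `a_hi ≥ 0` (own-resource rates positive).

State ordering is fixed: juvenile-habitat resources, adult-habitat
resources, juvenile classes, adult classes.

## Equilibrium analysis

At coexistence the resource rows give `R* = K(1 − aC*/r)` (joint form
`R_J* = K_J(1 − (a_JJ C_J + a_AJ C_A)/r_J)` for the sharing model;
`R* = I/(l + aC)` for subsidies). Substituting into `dC_A/dt = 0` and
`d(C_J+C_A)/dt = 0` gives the adult and juvenile ZNGIs. For stage-specific
diets both are upward-convex quadratics through the origin,

```
d_A C_A = C_J (p − q C_J),      d_J C_J = C_A (σ − τ C_A),
```

with `p = Σ b_J a_J K_J`, `q = Σ b_J a_J K_J a_J / r_J`,
`σ = Σ b_A a_A K_A − d_A`, `τ = Σ b_A a_A K_A a_A / r_A` (each weighted by
the habitat-number ratio `n_J/n_A` in the multiple-habitats model).
Composing the two and dividing out the trivial root yields the cubic with

```
Λ1 = −τ q²,   Λ2 = 2 τ p q,   Λ3 = −(τ p² + q σ d_A),   Λ4 = p σ d_A − d_J d_A².
```

For the sharing model the isoclines are quadratic-over-linear rationals;
denominators are cleared and the cubic assembled by polynomial arithmetic.
With subsidized resources the isoclines are non-polynomial and equilibria
are instead located by dense sign-change bracketing of the isocline
composition plus bisection — the same routine doubles as the independent
oracle against which the cubic route is tested.

The ASS condition is: positive cubic discriminant (three distinct real
roots) and all three roots mapping to positive abundances. Two options
qualify it:

* `require_resource_positivity` (default on): also demand every resource
  positive. With it off, candidates whose mapped resource abundance is
  negative still count; these shadow states in which a resource has been
  excluded by apparent competition. Only this weaker, classical
  sign-condition count restores the three-candidate region of the sharing
  model when both cross-feeding rates greatly exceed the own-resource
  rates (the stages have then effectively exchanged their major
  resources); the excluded-resource character of those candidates is the
  reason the strict count does not.
* `depletion` ("joint" default): the sharing model's resource equilibria
  either account for both consumer stages (consistent with the ODEs) or
  only the own stage (`"own-stage"`, the classical approximation).

**Counting equilibria is necessary, not sufficient, for bistability.** A
structural feature of food-proportional stage transitions: at any interior
equilibrium the consumer 2×2 Jacobian block (resources held fixed) has
determinant exactly zero, so local stability is decided entirely by the
weak resource-coupling corrections. At the plotting baselines
(`r = 1, a = 0.1, b = 0.5, d = 0.1`) the juvenile-dominated equilibrium is
a weakly unstable focus (leading real part ≈ +0.05) and trajectories from
its neighbourhood escape to the adult-dominated attractor: three roots, one
attractor. Genuine two-attractor dynamics appear at higher stage
mortalities and asymmetric productivities; the `examples` module records
reference points (found by seeded random search, stability margins ≥ 0.1)
at which the full saddle structure — two stable interior states separated
by an unstable middle equilibrium — is realized and reproducible from
coarse initial grids. All dynamical demonstrations anchor there; the
analytic region maps use the plotting baselines.

Stability is classified from the eigenvalues of a central finite-difference
Jacobian (relative step 1e-7; cross-checked against symbolic Jacobians
during development): `unstable`, `stable-node`/`stable-focus`, or
`non-hyperbolic` when the largest real part is within 1e-6 of zero. For
non-integer habitat counts the symmetric mean-field Jacobian is used, which
cannot see transverse (habitat-asymmetric) modes. Real roots closer than
1e-7 (relative) are merged and flagged — an exact double root splits by
~`sqrt(eps)` ≈ 1.5e-8 in floating point, so a tighter tolerance would never
recognize a fold.

## Dynamics and attractor census

Integration uses LSODA (`rtol 1e-8`, `atol 1e-10`). Negative excursions of
a logistic state are dynamically explosive, so the integrand evaluates
fluxes on the clipped state and adds a linear restoring term for
undershoots; reported trajectories are clipped at zero.

`find_attractor` integrates a 2000-time-unit transient, then measures a
500-unit window (1001 samples). Runs with scaled oscillation amplitude
below 1e-4 are fixed points (converged when half-window means agree to
1e-3 relative); oscillatory runs are periodic orbits, averaged over an
integer number of periods (upward mean-crossings of the dominant
component) to remove partial-period bias, and converged when the amplitude
is stationary across half-windows. Persistent drift doubles the transient
(twice) before flagging non-convergence. States averaging below 1e-6 are
extinct; a run with no consumer mass is a boundary attractor.
`count_attractors` clusters time-averaged states greedily at 1e-2 relative
/ 1e-6 absolute tolerance; non-converged runs are excluded.

Attractor identity is by time average, not phase: alternative states are
distinguished by which stage or habitat dominates on average, whether the
attractor is a point or a cycle. Both occur: near the plotting baselines
coexisting attractors are typically cycles; at the reference points they
are fixed points.

Default initial conditions: resources at their consumer-free equilibrium,
consumer totals on a log-spaced grid over `[1e-2, 2·max K]`. Censuses used
for analytic/dynamic consistency additionally seed near every analytic
equilibrium (consumers ×1.01, so unstable equilibria shed) and — for the
multiple-habitats model — in habitat-depleted configurations, because the
juvenile-dominated and symmetry-broken basins are easily missed by
symmetric grids in eight dimensions.

## Scans and the heterogeneity search

`scan_ass_region` evaluates the ASS test over a rectangular grid
(analytic mode: the cubic condition; simulation mode: an attractor census
per cell). Per-cell failures are recorded, not fatal; near-degenerate
discriminants (`|Δ| < 1e-12 × scale⁴`) are flagged as boundary cells and
excluded from area fractions. Default grids: 60×60 analytic, 20×20
simulation (tests and the acceptance script use 7–13 points per axis,
which resolves every qualitative feature asserted).

`heterogeneous_multistability_search` takes a homogeneous 2+2-habitat base,
applies juvenile carrying capacities `(K_J + δ, K_J − δ)` — total juvenile
productivity is held fixed to isolate heterogeneity from total availability
— and censuses attractors from probes aimed at the adult-dominated basin
and at each habitat-depleted configuration. At the recorded search base
this finds one adult-dominated state and two mirrored juvenile-dominated
states (one habitat's resource grazed out, its juvenile class dominant),
all stable fixed points, for offsets up to ≈30% of `K_J`; the homogeneous
base itself already sustains the mirror pair as symmetry-broken states.

## Verification and known limitations

* Dual-route check: cubic roots vs dense isocline intersection agree to
  1e-6 (relative) on 100 random parameter sets per scenario; scenario
  reductions (single habitat, zero cross-feeding) recover the baseline
  cubic exactly; resource relabeling leaves the sharing diagnosis
  invariant.
* Analytic condition vs brute-force census, at 50 random well-conditioned
  points per scenario (fixtures ±30% around the reference sets; points
  near folds or with stability margins < 0.02 excluded): full agreement
  for the additional-resources and sharing models; 88–92% for the
  multiple-habitats model. The shortfall is intrinsic to the symmetric
  reduction — it can neither detect symmetry-broken attractors (censuses
  find three attractors where the symmetric cubic has one root) nor
  guarantee transversal stability (three roots, one attractor) — and is
  reported, not hidden.
* The synthetic parameter generator perturbs every rate multiplicatively
  (uniform, ±50% by default) around a scenario baseline through one seeded
  generator. It emulates parameter uncertainty only: no process or
  observation noise, no nonlinear functional responses, no individual
  growth — so passing tests speak to the model family as specified, not to
  data from real stage-structured populations.
* Cycle means carry O(amp·period/window) residual bias when the period
  estimate fails (fewer than three mean-crossings); such runs fall back to
  plain window means. Strongly enriched corners of parameter space produce
  large-amplitude relaxation cycles with consumer minima near the
  extinction floor; censuses there are not reliable and are outside every
  asserted result.
* No global continuation: region maps are boolean grids, and fold curves
  are resolved only to grid resolution.
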