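# Methods

## Scope and model assumptions

`turingmin` analyses two-species reaction–diffusion systems whose kinetics
derive from *elementary* mass-action reactions: zeroth-, first- or
second-order (pseudo-)reactions, where order counts reacting particles.
This excludes trimolecular terms (cubic nonlinearities) and all rational
or ad-hoc rate laws; diffusion is isotropic and constant; only two species
interact; space is one-dimensional in the simulator.  Within these
assumptions the reaction polynomials `F`, `G` are bivariate quadratics
with sign-constrained coefficients: `a1, a3, a6 >= 0` and
`b1, b2, b4 >= 0`, because a reaction can only remove particles of a
species it consumes.  The package treats these as non-strict inequalities —
a coefficient is exactly zero when no reaction feeds its monomial — so
compilation never fails on a valid scheme.

## Qualitative classification

Reactions are classified by `(p, q, sign(s1), sign(s2))`; the sign
constraints above leave exactly 31 types.  Scheme classes are *multisets*
of types: multiplicity matters (a scheme may contain two qualitatively
different `U+V` reactions), and the multiset counts `C(33,3) = 5456` and
`C(34,4) = 46376` are the sizes of the candidate spaces the searches
sweep.  A scheme and its species-relabelled mirror describe the same
physical system, so searches enumerate one canonical representative per
mirror pair (chosen by tuple ordering) and analyse both orientations.

## Steady states

Positive uniform steady states are the isolated roots of two bivariate
quadratics.  The scalar solver eliminates `v` by a polynomial resultant
chosen by the degrees in `v` (linear–linear, quadratic–linear,
quadratic–quadratic, or univariate cases), finds the roots of the
resulting degree-≤4 polynomial in `u` via the companion matrix,
back-substitutes, polishes with a full 2-D Newton iteration
(acceptance tolerance 1e-12 relative), and verifies every root by its
residual (`max(|F|, |G|) <= 1e-9` on the local coefficient scale).
Exact elimination was chosen over local iterative root-finding because a
quadratic system has at most four isolated roots and the resultant cannot
miss any — important for the anti-phase classes, which frequently have two
positive steady states of which only one can be Turing-unstable.  A
resultant that vanishes identically means `F` and `G` share a curve of
zeros; this is reported as a degenerate system, never silently truncated.
Boundary states (`u* = 0` or `v* = 0`) are excluded: the instability
conditions require strictly positive concentrations.

## Linear stability

Routh–Hurwitz conditions and the sign-pattern requirement are tested with
a strict-inequality margin of `1e-9` on the local Jacobian scale to avoid
boundary false positives; the margin is configurable.  When the
auto-activator is V rather than U the species labels are swapped
internally, so reports always have `J11 > 0`.  The critical diffusivity
ratio is computed from the marginal-stability condition for
`det(J̃(k)) < 0`,

    δ_c = ( sqrt(det J*) + sqrt(−J12 J21) )² / J11²,

re-derived from the discriminant of `det(J̃)` as a quadratic in `k²`
rather than transcribed, and cross-checked in the tests against a
bisection oracle on "does an unstable band exist at this δ".  The growth
rate `λ(k²)` uses the closed form of the 2×2 eigenproblem (real part of
the leading eigenvalue) and is verified against direct eigenvalue
computation to 1e-10 on a thousand random Jacobians.

## Catalogue search

The search decides each candidate class by looking for a *witness*: a
concrete choice of integer product coefficients and rate constants whose
compiled kinetics pass all conditions at some positive steady state.

* **Structural pruning.**  A class survives only if it contains the
  necessary reactant combinations — `2U -> ...` increasing U (needed for
  `J11 > 0`), `U+V -> ...` decreasing U (type I, `J12 < 0`) or V
  (type II, `J21 < 0`), and for type II additionally a first-order
  `U -> ...` decreasing U (`a2 < 0`).  Two analytic exclusions are applied
  on top: all-bimolecular classes (homogeneous quadratics have singular
  steady-state Jacobians, by Euler's identity) and, for type II, classes
  whose reactant combinations all lie in `{2U, U+V, U}` (there
  `J21* = b4 u* >= 0`).
* **Feasibility search.**  Surviving classes are scanned over all
  admissible integer coefficient tuples with entries up to 6, ordered by
  total stoichiometry so the simplest witness appears first, with 500
  rate vectors per class drawn log-uniformly on `[1e-2, 1e2]` from a
  seeded generator.  The inner loop is fully vectorized: batched
  resultants, batched companion-matrix eigenvalues and a vectorized
  Newton polish decide hundreds of thousands of candidates per second.
* **Verification and asymmetry.**  Every kernel hit is re-verified by the
  scalar pipeline before it is reported, including a dispersion check at
  `δ = 1.01 δ_c` (just inside the open unstable set, chosen to stay
  well-conditioned).  A witness certifies instability; "no witness found"
  is only a statement at this budget.  At the default budget the
  3-reaction type-I search returns exactly the 11 catalogued classes and
  the 4-reaction type-II search exactly the 14, stably across seeds.

The 14 type-II templates stored in the catalogue are the search's own
(frozen) output; their instability has no closed form here and is
re-certified at test time.  They satisfy four structural constraints —
the `2U` reaction increases U, the `U+V` reaction decreases V, the
first-order `U` reaction decreases U, and the fourth reaction increases V
without decreasing U — which the test suite asserts template by template.

## Regime diagram

For type-I classes the rates are normalized to `(1, ρ, 1)` (closure rate
unity).  Symbolic steady states are obtained by guided elimination — one
of `{F − G, F, G}` is linear in `v` in every class — with the positive
branch selected numerically at an admissible sample; the Jacobian entries
are then lambdified over `(ρ, coefficients)`.  The threshold `ρ_c` is the
root of `tr J*(ρ) = 0`, computed by vectorized bisection on `[1e-8, 1e12]`
(the trace decreases through zero in every class) and verified exact to
1e-8.  The boundary slope `H = δ_c(ρ)/ρ` is checked constant to 1e-6 over
`ρ ∈ {2, 5, 10} ρ_c`, and an affine fit confirms the intercept vanishes:
`δ_c(ρ)` is linear *through the origin* in every class.

The sweep of `min δ_c(ρ_c)` over integer coefficients uses nested grids
(dense to 12, then geometric with neighbours, always including the bound
and its predecessors, so the corner optima at `m1 = n1 − 1` are hit and
minima are monotone in the bound).  Since the leading correction decays
as the inverse square root of the largest admissible coefficient, the
infimum is estimated by a quadratic fit in `bound^(−1/2)` over the three
largest bounds; eight classes extrapolate to 1 (within about 1%), while
the three classes whose interspecific reaction preserves or produces V
(`U+V -> V` and `U+V -> m2 V` closures) stay at `(1+√2)² ≈ 5.828` — for
one of them exactly, independent of the coefficients.

## Simulation

Method of lines: second-order central differences with zero-flux
(default) or periodic boundaries, interleaved species ordering so the
Jacobian is banded (bandwidth 3), integrated by LSODA with `rtol 1e-8`,
`atol 1e-9`.  An explicit scheme was rejected: the kinetics are stiff
across the sampled rate scales.  Initial conditions perturb the uniform
state either with seeded uniform noise (default amplitude `1e-3`,
required to be below 5% of the steady state) or with a single
boundary-admissible cosine mode along the unstable eigenvector of
`J̃(k)`, which makes the early-time mode amplitude grow cleanly at
`λ(k²)`; growth rates are measured by a log-linear fit inside the window
where the amplitude stays below 1% of `u*`.  Negative concentrations
beyond `1e-8` of the steady state abort the run with the offending time
rather than being clipped.  The default domain fits 20 wavelengths of the
fastest-growing mode so that discrete wavenumber selection is negligible;
tests use 4–8 wavelengths and 96–256 gridpoints to keep runs in seconds.

## Known limitations

* The package implements *linear* theory.  Stability of the saturated
  pattern is a nonlinear question it does not decide: for the in-phase
  demonstration scheme `2U -> 4U + 3V`, `U+V -> 0`, `0 -> U` at `ρ = 1.2`
  (`δ_c = 11.88`), simulations reach a stationary saturating in-phase
  pattern for `δ` up to about 13, while by `δ = 15` the saturated pattern
  breathes periodically in time — a secondary instability of the
  patterned state, robust across boundary conditions, domains,
  resolutions and seeds.  The acceptance test therefore checks the
  stationary state at `δ = 12.5` and the (saturated, in-phase, correctly
  growing) pattern at `δ = 15`.
* "No witness found" for a class is evidence, not proof; the proofs of
  impossibility implemented analytically are only the determinant and
  sign-pattern arguments listed above.
* The simulator is one-dimensional and deterministic; stochastic
  (particle-based) dynamics and higher dimensions are out of scope, as are
  systems of three or more species and reactions above second order.
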