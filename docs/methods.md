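# Methods

## The model

`cleaverep` studies the population dynamics of information-coding
heteropolymers (proto-RNA-like chains) that replicate by non-enzymatic,
bidirectional templated polymerization under day/night cycling, in a
chemostat with monomer feed `m0` and uniform dilution `δ`. Chain breakup
creates new primers, so cleavage — counterintuitively — drives
proliferation. Two model variants are implemented.

All lengths and monomer-type concentrations are renormalized by the
minimal hybridization (primer) length, l0 = 1.

### Random cleavage

Fragments of a single master sequence (total concentration `c`) and of
its complement (`c̄`) mutually template each other. With `M`, `M̄` the
monomer-in-chain densities and `m = m0 − M − M̄` the free monomers:

    dM/dt = r·m·min(c, c̄) − δ·M
    dc/dt = β0·M − δ·c            (and the barred twins)

`r` is the effective elongation rate constant, `β0` the spontaneous
scission rate per bond. The symmetric steady state has mean chain length
⟨L⟩ = M/c = δ/β0 = r·m*/δ, free-monomer level m* = δ²/(β0·r) and
c = c̄ = (β0·m0/δ − δ/r)/2; chains persist exactly when β0·m0·r > δ²
(equivalently m0 > m*).

### Catalyzed cleavage

The master sequence diverges into substrates `a` and catalysts `b`
(hammerhead-ribozyme-like: `b̄` cleaves `a` at one site, `b` cleaves
`ā`), producing left/right fragments `aL`, `aR`. `aL` can only regrow
into `a`; `aR` matures into `b` with probability φ = b̄/(ā+b̄) (its first
template sets its fate) at a rate slowed by the asymmetry factor λ ≥ 1,
else into `a`. Pairing imbalance between the families enters through
χ = min(a+b, ā+b̄)/(a+b) ≤ 1. The ten concentrations
(a, b, aL, aR, M and barred twins) obey

    daL/dt = β·φ·a − r·m·χ·aL − δ·aL
    daR/dt = β·φ·a − r·m·χ·(1−φ)·aR − r·m·χ·(φ/λ)·aR − δ·aR
    db/dt  = β0·M·φ̄ + r·m·χ·(φ/λ)·aR − δ·b
    da/dt  = β0·M·(1−φ̄) + r·m·χ·aL + r·m·χ·(1−φ)·aR − β·φ·a − δ·a
    dM/dt  = r·m·χ·c − δ·M,     c = a + b + aL + aR

with the barred equations obtained by swapping every barred/unbarred
pair and (β, φ, χ) → (β̄, φ̄, χ̄). The chain-number balance
dc/dt = β0·M + β·φ·a − δ·c holds identically (asserted as a machine-
precision property test). With b = aL = aR = 0 the system reduces
exactly to the random-cleavage model.

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| `m0` | feed monomer concentration | l0-mer concentration | 100 |
| `delta` | dilution rate | 1/time | 1 |
| `r` | elongation rate constant | 1/(conc·time) | 1 |
| `beta0` | random cleavage rate per bond | 1/time | 0.015 |
| `beta`, `beta_bar` | catalyzed cleavage rates | 1/time | 10 (β̄ = β) |
| `lam` | elongation asymmetry λ | — | 2 |

`beta0`, `delta`, `lam` and the three reference values β ∈ {6, 10, 18}
are the conditions of the reference analysis. `r` and `m0` are not fixed
by those conditions; the defaults r = 1, m0 = 100 satisfy the survival
condition (β0·m0·r = 1.5 > δ² = 1) and every existence-window and
threshold result below is verified to be independent of them (they drop
out of the reduced steady-state equations as long as the feed is far
above threshold). Basin geometry and the seeding threshold do depend on
them; outputs always record the values used.

## Fixed points and the semi-analytic reduction

With β = β̄ the mirror-symmetric subspace (a = ā, …, M = M̄) is forward-
invariant and contains every fixed point of interest, so root-finding
works on the reduced 5-variable system. At a symmetric steady state all
concentration fractions are explicit functions of the catalyst fraction
φ = b/(a+b) and the scaled monomer level u = r·m/δ:

    a/c  = (1 − εu)/(Bφ),            ε = β0/δ, B = β/δ
    aL/c = Bφ(a/c)/(u+1)
    aR/c = Bφ(a/c)/(u(1−φ+φ/λ)+1)
    b/c  = εuφ + (uφ/λ)(aR/c)

leaving two consistency conditions (fractions sum to 1; φ is the
catalyst fraction it presumes). The module scans φ ∈ (0, 1) — with
logarithmic enrichment near φ = 1, where the cooperative branch
accumulates as β0/δ → 0 — brackets u per φ, pairs branches across
neighbouring φ by proximity in log u, and refines each sign change by a
2-D Newton solve followed by polishing on the reduced system. This
enumerates *all* interior fixed points (the cooperative state and the
saddles) deterministically; it replaces any closed-form parametric
characterization of the branch and doubles as the cold-start for
continuation, which otherwise chains Newton solves from neighbouring
parameter values.

Numerical conventions:

- Residual acceptance is scale-aware: ‖RHS‖ < 1e-10 · max(1, δ·max|x|),
  because at concentration scales ~1e4 the production term r·m·c and the
  dilution term δ·M cancel to a floating-point floor far above an
  absolute 1e-10.
- Jacobians are central differences with step h = 1e-7·max(1, |x_i|).
  Fixed points of interest are symmetric with c = c̄, where χ = χ̄ = 1,
  so the min() kink is inactive at the points being classified.
- Stability: the non-cooperative (single-type) points are
  transcritical-marginal — the invasion eigenvalue of the absent chain
  type is exactly zero and decay is quadratic (ḃ ≈ −δ·b²/c < 0), so
  they are attracting but not hyperbolic. Boundary points are therefore
  classified stable when no eigenvalue real part exceeds +1e-5·δ, while
  interior points must be strictly hyperbolic (all real parts below
  −1e-5·δ) to count as the stable cooperative state. The spectrum of
  the full 10-variable Jacobian (stability against symmetry-breaking
  perturbations) is computed and reported alongside; at the reference
  conditions the cooperative point is stable in the full space too.

## Existence window and disappearance threshold

The β-window with a stable cooperative point is found by locating one
interior β (asymptotic-bound candidates, a hint from a previous call,
or a log-grid scan), then marching each edge outward with continuation
seeding and bisecting to 1e-4·δ. Because the window drifts to lower β
and narrows to sub-percent width as β0/δ approaches its critical value,
a hint-chained dense sweep across the previously known range backs up
the point candidates before the window is declared empty; the interior
seed is refreshed at the window midpoint after each call so chained
calls never go stale.

The critical β0/δ (at fixed λ) is an outer march-plus-bisection on the
window-nonempty predicate, to 1e-3 relative precision. At λ = 2 it
lands at 0.0558. The asymptotic bounds 4λ < β/δ < (λ−1)δ/(4β0) (valid
for β0/δ ≪ 1/λ) are exposed separately; the numeric edges converge onto
them as β0/δ → 0 (relative deviation of the lower edge: 11% at 0.015,
0.8% at 1e-3, 0.07% at 1e-4 — the small-β0 checks raise m0 so the feed
stays far above threshold, 2e4 and 2e5 respectively).

## Dynamics and basins

Trajectories integrate the full 10-variable system with LSODA
(rtol 1e-9, atol 1e-12) and an early-exit event at ‖RHS‖ < 1e-8;
reported states are clamped to the non-negative orthant while solver
internals are left unclamped to keep the vector field smooth. Endpoints
are matched to fixed points within a scale-aware per-coordinate
relative distance of 1e-3 (scales floored at 1e-3·m0) with
‖RHS‖ < 1e-6. Because the pure states are approached algebraically
(the marginal eigenvalue), classification doubles the horizon from
200/δ up to 5 times when undecided; the quiet tail costs little.

Phase-portrait grids seed mirror-symmetric states with aL = aR = 0 and
M = M̄ = (a0+b0)·δ/β0 — chains start at the random-model mean length,
i.e. on the physically reached slow manifold (an alternative initial
length can be passed). The minimal seeding ratio starts from the pure
b/b̄ fixed point, adds a = ā = ε·b, and bisects ε in log space to two
significant figures. At the reference conditions ε* = 0.022. The
default bracket is (1e-6, 0.1): the cooperative basin along this slice
is a *band* — seeding with ε ≳ 0.2–0.3 (e.g. an equal a/b mixture)
overshoots into the pure-a basin, so the bracket top must stay inside
the band. Symmetric seeding (both strands at once) keeps the dynamics
on the invariant subspace; the threshold is insensitive (<1%) to
whether the seeded chains also carry their share of M.

## Fitness and evolution

Fitness is m*/m*coop, the free-monomer level of the non-cooperative
steady state divided by that of the stable cooperative state, and
exactly 1 when no cooperative state exists: the state that depresses
monomers furthest competitively excludes the rest. Since
m*coop/m* < 1/2 inside the window, cooperative fitness always exceeds
2 (6.83 at the reference β = 10).

The Metropolis walk treats fitness as negative energy: multiplicative
uniform proposals λ′ = λ·e^η, β′ = β·e^η (η ~ U(−0.1, 0.1),
independent), reflection of λ at its floor of 1 in log space,
acceptance min(1, exp(ΔF/T)). Temperature, proposal scale and step
count are not dictated by the model; the defaults T = 0.05 (fitness
units), scale 0.1 and 500 steps are small enough to follow the narrow
ridge and large enough to cross flat patches, and a proposal leaving
the cooperative region is *not* rejected outright — fitness falls to 1
there, matching the ecology (the population persists by random
cleavage). A single seeded generator drives each run; the seed is
recorded in every output row.

## What the tests show (and what they do not)

The suite checks: the machine-precision structural identities of the
right-hand sides; closed-form against long-time integration for the
random model (20 random viable parameter sets, rel. 1e-6); the
three-regime fixed-point census at β ∈ {6, 10, 18}; dynamical return
of the cooperative point from 1% perturbations; monotonicity and the
1/2 bound of the stable branch; window/bound convergence; the
disappearance threshold and its r, m0-independence; the fitness
dichotomy (exactly 1 outside, >2 inside, 50 parameter sets each); the
seeding threshold band; and ridge climbing in ≥90% of 20 seeded
Metropolis runs (500 steps each). Problem sizes throughout are the
reference ones above; portraits in tests use small (3×3) grids since
basin classification cost is dominated by the slow algebraic approach
to the pure states.

No sequence information is modelled: chains are concentration pools,
hybridization is implicit in the effective rates, and complexes of
more than two chains, night-phase binding kinetics, template-poisoning
dynamics and finite-length effects are outside the model. Fixed-point
analysis assumes β = β̄ (the asymmetric case is integrable but not
analysed for steady states). Conclusions about basins (phase portraits,
seeding thresholds) are specific to the r = 1, m0 = 100 defaults.
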