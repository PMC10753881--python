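# Methods

## Model

Particles are hard spheres of diameter σ (the length unit) decorated with
`N_p` attractive patches at fixed body-frame unit vectors. Patch `α` on
species `i` carries a color; a symmetric boolean interaction matrix
ϒ states which colors may bond. Two particles interact through the
Kern–Frenkel potential: hard core for r < σ, and a square well of depth ε
(the energy unit) for σ ≤ r ≤ σ(1+δ) that is switched on only when a
ϒ-compatible patch pair is mutually aligned — both patch axes within the
angular half-width θ_max of the center line, i.e.
cos(v̂_α·r̂) ≥ cos θ_max simultaneously for both patches. Defaults follow
the regime where tetrahedral patchy particles nucleate well: δ = 0.2,
cos θ_max = 0.98. (Some sources quote the same number as "θ_max = 0.98";
this package uses cos θ_max = 0.98 everywhere.) Temperatures are in ε/k_B,
pressures in ε/σ³.

The narrow aperture has a structural consequence used throughout: two
particles cannot both sit inside one patch's cone without overlapping
(2·σ·sin θ_max < σ for cos θ_max = 0.98 over the well range), so a patch can
bond at most one partner and a pair can form at most one bond. Energies are
therefore −ε times the number of bonded pairs; the bond-graph builder still
asserts one-bond-per-patch on every configuration it sees.

## Azeotropy design rules

The probability `X_α^(i)` that patch α of species i is unbonded obeys the
law of mass action

    X_α^(i) = 1 / (1 + ρ Σ_j x^(j) Σ_{γ∈Γ(j)} ϒ[c(α), c(γ)] Δ X_γ^(j))

with ρ the total number density, x^(j) mole fractions, and Δ the bond
integral (below; all bonds share one Δ). A sufficient condition for
azeotropy is that all N_s·N_p equations collapse to one scalar equation,
`X = 1/(1 + c X)` with `c = ρ Δ w`:

| rule            | requirement (per patch, counting color slots)           | azeotrope        | weight w    |
|-----------------|----------------------------------------------------------|------------------|-------------|
| exclusivity     | exactly one partner in the whole system                  | equimolar        | m/N_s (m=1) |
| multiplicity n  | one partner on species 2 **or** n partners on species 1  | (1/(n+1), n/(n+1)) | n/(n+1)  |
| fully connected | exactly one partner on every species                     | every composition | 1          |

Partners are counted over patch *slots*: a color repeated k times on a
species contributes k, exactly as it enters the mass action sum. The scalar
quadratic `cX² + X − 1 = 0` has exactly one root in (0, 1], taken as
`X = 2/(1 + √(1+4c))`.

A counting argument fixes feasibility of the multiplicity rule: every
species-1 color must appear exactly n times, so `N_p ≡ 0 (mod n)`. For four
tetrahedral patches this makes the 1:3 ratio impossible — the generator
raises an explicit infeasibility error, and the checker reports the
violation for any matrix claiming it.

### The N2c8s2 design

The minimal two-species, eight-color cubic-diamond design satisfies bond
exclusivity, so the equimolar mixture is azeotropic. Its matrix is a
symmetric permutation with trace 2. The requirement that each pure
component can only chain (effective valence two, hence no liquid–gas
transition of the pure components) forces the matching structure uniquely
up to color relabeling: two self-complementary colors on one species, one
intra-species color pair on the other, and two cross-species pairs. The
package stores it as {0–0, 1–1, 2–6, 3–7, 4–5} with species 0 carrying
colors 0–3. Every thermodynamic quantity is invariant under color
relabeling (tested), so the labeling is a gauge choice.

## Wertheim free energy

Helmholtz free energy per particle in k_BT units:

    βf = Σ_i x_i ln(ρ x_i V_i) − 1            (ideal; V_i ≡ σ³)
       + φ(4 − 3φ)/(1 − φ)²                   (Carnahan–Starling, φ = ρπσ³/6)
       + Σ_i x_i Σ_α [ln X_α^(i) − X_α^(i)/2 + 1/2]   (bonding, at mass balance)

The thermal volume V_i is set to σ³ for all species: a composition-
independent additive constant that cancels from every coexistence
construction. The bond integral is

    Δ = (e^{ε/k_BT} − 1) · p² · 4π ∫_σ^{σ(1+δ)} g_HS(r) r² dr,   p = (1 − cos θ_max)/2,

with g_HS expanded around contact: `g_HS(r) ≈ g_σ + g'_σ (r − σ)`,
`g_σ = (1 − φ/2)/(1 − φ)³` and `σ g'_σ = −(9/2) φ(1+φ)/(1−φ)³` (the slope
reproduces the exact low-density limit −(9/2)φ). The expansion order (0 or
1) is an argument of `bond_integral`; order 1 is the default. The δ = 0
Kern–Frenkel bonding volume in the same approximation is
`V_b = (π/3)[(σ+δσ)³ − σ³](1 − cos θ_max)²`, cross-checked in the tests by
brute-force pose sampling.

When all X are equal the bonding term reduces to `N_p(ln X − X/2 + 1/2)`,
formally a one-component fluid. The exact one-component reference for the
equimolar exclusivity mixture carries the mole-fraction weight: a
four-patch single species with bond strength Δ/2 (not Δ) reproduces f_bond
to machine precision.

The mass balance is solved by damped fixed-point iteration (damping 0.5,
started from X = 1) followed by a Newton polish on
`R(X) = X(1 + WX) − 1 = 0`; converged residuals are below 1e−12 at every
state point used. The damped map is strongly contractive precisely in the
strong-bonding regime (its local derivative is ≈ (1 − (1−X*))/2 → 0), so
low temperatures are cheap.

## Phase equilibrium

### Fixed (T, P): common tangent

g(x) = min_ρ [a(ρ,x) + P/ρ] is computed by scanning ρ on a log grid over
[1e−6, 1.1] σ⁻³, refining every bracketed minimum by Brent, and polishing
the physical minima on the mechanical condition P(ρ) = P (so the reported
density reproduces the input pressure to ~1e−10). All local minima are
returned; two minima signal the two-phase region. dg/dx uses the envelope
theorem (∂a/∂x at the minimizing ρ).

Coexistence pairs solve equal slope + equal intercept of g(x) (equal
chemical potentials of both species) by a two-unknown root find seeded
from the lower convex hull of g sampled at Δx = 0.005. The lens of a
negative azeotrope has a characteristic structure: above the lens-minimum
pressure there are *two* tangent pairs, one on each side of the stable
liquid near x = 1/2, mirror images of each other; as P decreases to the
lens minimum both pairs pinch onto the azeotropic composition, and below
it the stable envelope is convex (single phase). Tie lines therefore
connect dew and bubble points on the same side and are never symmetric
about x = 1/2 except at the azeotrope itself.

The azeotrope locator makes no symmetry assumption: at fixed x the
equal-depth two-minimum construction yields a candidate (P, ρ_gas, ρ_liq);
it is a true coexistence exactly where the two phases also agree on the
exchange chemical potential ∂a/∂x. The azeotropic composition is the root
of that mismatch, bracketed over x ∈ [0.35, 0.65].

### Isochoric route

With molar densities ρ_i as coordinates and the Helmholtz energy density
Ψ(ρ⃗) = ρ a as potential, μ_i = ∂Ψ/∂ρ_i, P = −Ψ + Σρ_iμ_i, and stability
is governed by the Hessian H = ∂²Ψ/∂ρ_i∂ρ_j. Differentiating the
coexistence equalities along an isotherm gives, for a binary,

    [ρ′ᵀ; ρ″ᵀ] m = (1, 1),   dρ′/dP = H′⁻¹ m,   dρ″/dP = H″⁻¹ m,

integrated with a midpoint predictor and geometric step control; every
accepted step is Newton-projected back onto (μ′ = μ″, P′ = P″ = P) using
the analytic Jacobian built from the same Hessians. The linear system is
singular where ρ″ ∝ ρ′ — a vertical tie line — so the tracer stalls at the
azeotrope by construction; the azeotropic (x, P) is then recovered by
fitting both branches near the stall to parabolas `P = P_az + A_b(x − x_az)²`
with a shared vertex. It also stalls when det H collapses toward a
critical point (termination threshold 1e−8 of the starting magnitude,
step floor 1e−10 in P).

Numerical derivatives of Ψ are split: the ideal part (T ln ρ_i gradient,
T/ρ_i diagonal Hessian) is analytic; only the excess (hard-sphere +
bonding) part is differenced. For binaries the excess Hessian is computed
in (ρ, x) coordinates and mapped back exactly. This matters: near an
azeotropic composition at strong bonding the composition curvature of f is
large and varies on the scale of X* itself, and per-density stencils
sample it inconsistently between matrix entries, destroying the exact
cancellation in ρ̂ᵀHρ̂; the (ρ, x) stencil (steps: 2e−4·ρ in density, 1e−4
in composition) keeps all entries consistent, which is verified against
the independent pressure derivative.

Critical points solve det H = 0 together with the vanishing cubic form of
Ψ along the Hessian's null direction (Newton from a det-sign-change
bracket). `section_critical_temperature` bisection-locates the highest T
at which a fixed-composition ray loses stability; on the azeotropic
section this is the mixture's critical temperature, and it decreases
monotonically toward the pure components, where the chain-forming species
have no transition at all.

## Monte Carlo

State: positions, unit quaternions, per-particle lab-frame patch caches,
species labels, cubic periodic box. The inner loops are numba kernels;
seeded runs are bit-reproducible.

Moves (defaults: 80% rototranslation with max displacement 0.1σ and max
rotation 0.1 rad, 10% AVB-B, 10% AVB-U; N trial moves per sweep):

* **AVB-B**: choose target i, then j uniformly among non-partners, then a
  uniformly random pair (α free on i, γ on j) among the n_pair compatible
  ones; propose j's pose uniformly on the bonded manifold (direction in
  the cone of α, r³ uniform in the shell, orientation = align γ, spin
  uniformly). Proposal density 1/(n_pair V_b); acceptance
  min[1, e^{−βΔU} (N_out/(N_in+1)) (n_pair V_b / V_out)].
* **AVB-U**: choose a bonded partner, re-pose it uniformly in the box,
  rejecting proposals that land bonded to the target; acceptance
  min[1, e^{−βΔU} (N_in/(N−N_in)) (V_out / n_pair V_b)], with n_pair
  counted with the broken bond discounted, so the pair is exactly
  detailed-balanced. V_out = V − n_pair·V_b.

The two-particle bonded fraction reproduces the analytic two-state value
`V_b e^{βε}/(V − V_b + V_b e^{βε})` at three temperatures, which pins both
the bonding-volume convention and the acceptance bookkeeping.

The Gibbs ensemble adds, per sweep, one volume-exchange move (uniform in
ln(V₁/V₂), max step 0.02) and N/10 transfer attempts (particle chosen
uniformly in the source box, inserted at a uniform pose). Total volume and
per-species counts are conserved exactly and audited after every run.
Volume moves that would shrink a box below twice the interaction range
are rejected. Particle flow between boxes proceeds through weakly bonded
states (direct removal of a fully bonded liquid particle costs ~4ε), so
coexistence runs are started from a pre-equilibrated bonded liquid plus a
dilute gas box; the run lengths used in the tests (2×10⁵ pre-equilibration
+ 2×10⁵ Gibbs sweeps at N = 152) exchange tens of thousands of particles
between the boxes, enough for the branches to drift measurably if the
initialization were off.

Neighbor searches are flat O(N²)/O(N) kernels; at the package's desk
scales (N ≤ 512) these beat cell lists after constant factors.

## Crystal detector

A particle is cubic-diamond-like when it has exactly four neighbors within
the well range and every bond is staggered: the minimal dihedral angle
between the other neighbors of the two bonded particles, about the bond
axis, exceeds 30° (ideal cubic diamond 60°; hexagonal diamond has an
eclipsed bond at 0°). Bonds whose partner has fewer than two further
neighbors are unclassifiable and disqualify. Neighbors come from the
distance criterion, which coincides with the bond network inside a
crystal but keeps the detector independent of coloring. This simplified
dihedral classifier is validated against constructed cubic and hexagonal
lattices only; it is not claimed equivalent to full local bond-order
analysis.

## Fixtures (synthetic data)

* `generate_rule_matrix` builds random involutions (exclusivity), per-patch
  color cliques (fully connected), or the counted slot structure of the
  multiplicity rule, and *verifies each output with the corresponding
  checker before returning it*.
* `build_diamond_seed` places the cubic-diamond lattice at bond distance
  σ(1+δ/2) and solves species (chains along [110], alternating between
  chain columns) and orientations (unit-propagation + minimum-remaining-
  values over the 24 proper cube rotations) against the interaction
  matrix, then verifies full valence-4 bonding with the energy routine.
  The two-species coloring has period two conventional cells along [1̄10],
  so periodic seeds need an even cell count; odd counts raise. The
  hexagonal seed is a free-standing ideal-lonsdaleite cluster with patches
  aligned to the local bond directions — geometric ground truth for the
  detector (the design itself cannot fully bond the hexagonal polytype;
  that is the point of the design).
* `random_gas` inserts sequentially with rejection and allocates species
  counts by largest remainder.

What the fixtures do **not** emulate: polydispersity, flexible or
DNA-mediated bonds with sequence-dependent strengths, hydrodynamics, and
gravity. Passing tests therefore validate the statistical mechanics of the
idealized Kern–Frenkel mixture, not quantitative agreement with any
specific colloidal experiment.

## Problem sizes and tolerances

Theory: mass-balance residual < 1e−12 (tolerance 1e−13 in the solver);
coexistence-manifold projections to 1e−9; azeotrope located to < 1e−4 in
composition at T = 0.07 and 0.08. Simulation sizes in the test suite:
N = 64–160, 10³–2×10⁵ sweeps (growth smoke test at T = 0.095, inside the
assembly window around T ≈ 0.1); the library handles N = 500+ and 10⁶+
sweeps through the same entry points. The acceptance script is fully
deterministic (the seed only feeds the generic RNG interface).

## Known limitations

Equal bond strengths and equal diameters throughout (the rules generalize,
the code does not); first-order Wertheim theory (no rings/loops, no bond
cooperativity), which overestimates the coexistence-region width; no
crystal free energies (crystallization is only observed in the
simulator); nucleation quantification at the scale of hundreds of
millions of sweeps is out of scope.
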