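# azeopatch

Engineering **azeotropy** into multicomponent patchy-particle mixtures.

Multicomponent colloidal mixtures are attractive building blocks for
inverse self-assembly — more species means fewer competing structures —
but every added component is an extra thermodynamic degree of freedom:
coexisting phases generally differ in composition, so a nucleating crystal
can starve one species and stall. At an *azeotropic* composition the
mixture demixes like an effective one-component fluid: gas, liquid and
growing crystal all share the parent composition. This package implements
the design rules that pin azeotropic points into patchy-particle
interaction matrices, the thermodynamic machinery to map the resulting
phase diagrams, and a Monte Carlo engine to cross-validate the theory —
worked end-to-end for the minimal two-species cubic-diamond design
(*N2c8s2*: 2 species, 8 patch colors, 2 self-complementary colors).

## What is inside

* **`interactions`** — Kern–Frenkel patchy particles (hard core σ, square
  well ε over σ ≤ r ≤ σ(1+δ), angular width cos θ_max per patch), patch
  colors, and the symmetric boolean interaction matrix ϒ; `build_n2c8s2()`
  constructs the cubic-diamond binary design (δ = 0.2, cos θ_max = 0.98).
* **`design_rules`** — the three sufficient azeotropy rules on ϒ (bond
  exclusivity → equimolar azeotrope; bond multiplicity *n* → azeotrope at
  x = (1/(n+1), n/(n+1)); fully connected → azeotropic at every
  composition) and the reduced scalar law of mass action
  `X = 1/(1 + ρΔw·X)` for the common unbonded probability.
* **`wertheim`** — multicomponent first-order thermodynamic perturbation
  theory: bond integral Δ = V_b(e^{βε} − 1)⟨g_HS⟩, mass-balance solver,
  Helmholtz/Gibbs free energies, common-tangent coexistence, azeotrope
  location.
* **`isochoric`** — Helmholtz energy density Ψ(ρ₁, ρ₂), its Hessian,
  binodal tracing by integrating dρ′/dP, dρ″/dP with Newton projection
  onto the coexistence manifold, and critical points from det H = 0 plus
  the cubic stability condition.
* **`mcsim`** — NVT and Gibbs-ensemble Monte Carlo with rototranslation
  and aggregation-volume-bias (AVB) moves (numba kernels, bit-reproducible
  under a seed), bond/cluster analysis, and a staggered-vs-eclipsed
  dihedral detector for cubic vs hexagonal diamond.
* **`fixtures`** — checker-verified generators: random rule-satisfying
  matrices, fully bonded cubic-diamond seed lattices (species and
  orientations solved by constraint propagation), hexagonal reference
  clusters, random gases.
* **`azeopatch` CLI** — `design check`, `wertheim freeenergy|binodal`,
  `binodal trace`, `sim nvt|gibbs`, `fixtures …`.

## Worked example

```python
import numpy as np
from azeopatch.interactions import build_n2c8s2
from azeopatch import design_rules, wertheim

mix = build_n2c8s2()                       # 2 species, 8 colors, trace(Y) = 2
report = design_rules.check_bond_exclusivity(mix)
print(report.satisfied, report.predicted_azeotrope)
# True [0.5 0.5]                           -> azeotrope expected at x = 1/2

# law of mass action at T = 0.08, rho = 0.3 sigma^-3, equimolar
state = wertheim.ThermoState(0.08, 0.3, [0.5, 0.5])
delta = wertheim.bond_integral(mix.kf, 0.08, 0.3)
X = wertheim.solve_mass_balance(mix, state, delta)
print(round(delta, 2), X.values.ravel().round(6))
# 114.05 [0.214308 0.214308 ... 0.214308]  -> all patches equally (un)bonded

# the azeotrope of the T = 0.07 isotherm, located with no symmetry assumed
x_az, P_az, rho_gas, rho_liq = wertheim.find_azeotrope(mix, 0.07)
print(round(x_az, 4), f"{P_az:.3e}", f"{rho_gas:.2e}", round(rho_liq, 3))
# 0.5 7.632e-06 1.15e-04 0.451
```

All eight unbonded-patch probabilities collapse onto one value — the
algebraic signature of azeotropy — and the coexistence lens at T = 0.07
closes at x = 0.5 at its pressure minimum (a negative azeotrope): a
mixture prepared at equal composition phase-separates into gas and liquid
that are both equimolar, which is exactly what lets the cubic diamond
(an equimolar crystal) grow to completion. Pure components (x = 0 or 1)
can only chain through their two intra-species colors and have no
liquid–gas transition at all.

From the shell:

```bash
azeopatch design check n2c8s2 --rule exclusivity
azeopatch wertheim freeenergy n2c8s2 --T 0.08 --rho 0.3 --x 0.5
azeopatch sim gibbs n2c8s2 --T 0.08 --rho 0.13 --N 128 --sweeps 200000 \
    --seed 1 --out run1
```

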