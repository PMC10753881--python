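"""Azeotropy design rules for interaction matrices.

A mixture is azeotropic when the mass-balance (law of mass action) equations
for all unbonded-patch probabilities ``X_alpha^(i)`` collapse onto a single
scalar equation, so every patch in the system is bonded with the same
probability and the mixture demixes like an effective one-component fluid.
Three sufficient rules on the interaction matrix achieve this:

* **bond exclusivity** - every patch has exactly one bonding partner among
  all patches of all species; azeotrope at the equimolar composition.
* **bond multiplicity** - in a binary mixture, each patch bonds either to
  exactly one patch of species 2 or to exactly ``n`` patches of species 1;
  azeotrope at ``x = (1/(n+1), n/(n+1))``.
* **fully connected** - each patch has exactly one partner on *every*
  species; the mixture is azeotropic at every composition.

Partners are counted over patch *slots*: a color that appears on several
slots of a species counts with multiplicity, exactly as it enters the law of
mass action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interactions import MixtureSpec

__all__ = [
    "RuleReport",
    "partner_count_table",
    "check_bond_exclusivity",
    "check_bond_multiplicity",
    "check_fully_connected",
    "solve_azeotropic_x",
]


@dataclass(frozen=True)
class RuleReport:
    """Outcome of a design-rule check.

    predicted_azeotrope is the composition at which the rule guarantees an
    azeotrope (uniform for exclusivity, skewed for multiplicity); it is
    ``None`` for the fully connected rule, which instead sets
    ``always_azeotropic`` because every composition is azeotropic.
    """

    rule: str
    satisfied: bool
    predicted_azeotrope: np.ndarray | None = None
    multiplicity_n: int | None = None
    partners_m: int = 1
    always_azeotropic: bool = False
    details: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.predicted_azeotrope is not None:
            x = np.asarray(self.predicted_azeotrope, dtype=float)
            object.__setattr__(self, "predicted_azeotrope", x)
            if abs(x.sum() - 1.0) > 1e-12:
                raise ValueError("predicted azeotrope composition must sum to 1")

    @property
    def n_species(self) -> int | None:
        if self.predicted_azeotrope is None:
            return None
        return len(self.predicted_azeotrope)


def partner_count_table(mixture: MixtureSpec) -> np.ndarray:
    """Per-patch partner counts, shape (N_s, N_p, N_s).

    ``table[i, a, j]`` is the number of patch slots on species ``j`` whose
    color is compatible with patch ``a`` of species ``i`` (slot multiplicity
    included) -- the combinatorial weight entering the law of mass action.
    """
    colors = mixture.patch_color_table()
    ups = mixture.matrix.entries
    n_s, n_p = colors.shape
    table = np.zeros((n_s, n_p, n_s), dtype=int)
    for i in range(n_s):
        for a in range(n_p):
            c = colors[i, a]
            for j in range(n_s):
                table[i, a, j] = int(ups[c, colors[j]].sum())
    return table


def _patch_details(table: np.ndarray) -> list:
    n_s, n_p, _ = table.shape
    return [
        {
            "species": i,
            "patch": a,
            "partners_per_species": table[i, a].tolist(),
            "partners_total": int(table[i, a].sum()),
        }
        for i in range(n_s)
        for a in range(n_p)
    ]


def check_bond_exclusivity(mixture: MixtureSpec) -> RuleReport:
    """Every patch has exactly one bonding partner in the whole system."""
    table = partner_count_table(mixture)
    satisfied = bool((table.sum(axis=2) == 1).all())
    n_s = mixture.n_species
    return RuleReport(
        rule="exclusivity",
        satisfied=satisfied,
        predicted_azeotrope=np.full(n_s, 1.0 / n_s) if satisfied else None,
        details=_patch_details(table),
    )


def check_bond_multiplicity(mixture: MixtureSpec, n: int) -> RuleReport:
    """Binary rule: each patch bonds to exactly one patch of species 2, or to
    exactly ``n`` patches of species 1 (never both)."""
    if mixture.n_species != 2:
        raise ValueError("the bond multiplicity rule is defined for binary mixtures")
    if n < 1:
        raise ValueError("multiplicity n must be >= 1")
    table = partner_count_table(mixture)
    k1 = table[:, :, 0]
    k2 = table[:, :, 1]
    ok = ((k1 == n) & (k2 == 0)) | ((k1 == 0) & (k2 == 1))
    satisfied = bool(ok.all())
    x = np.array([1.0 / (n + 1), n / (n + 1.0)])
    return RuleReport(
        rule="multiplicity",
        satisfied=satisfied,
        predicted_azeotrope=x if satisfied else None,
        multiplicity_n=n,
        details=_patch_details(table),
    )


def check_fully_connected(mixture: MixtureSpec) -> RuleReport:
    """Each patch has exactly one bonding partner on every species."""
    table = partner_count_table(mixture)
    satisfied = bool((table == 1).all())
    return RuleReport(
        rule="fully_connected",
        satisfied=satisfied,
        always_azeotropic=satisfied,
        details=_patch_details(table),
    )


def solve_azeotropic_x(rule: RuleReport, phi: float, delta_bond: float) -> float:
    """Physical root of the rule's reduced scalar mass-balance equation.

    At the rule's azeotropic composition all mass-balance equations reduce to
    ``X = 1 / (1 + c * X)`` with ``c = rho * Delta * w`` and weight

    * exclusivity (m partners per patch): ``w = m / N_s``,
    * multiplicity n (binary): ``w = n / (n + 1)``,
    * fully connected: ``w = 1``.

    The quadratic ``c X^2 + X - 1 = 0`` has exactly one root in (0, 1],
    returned here; ``X = 1`` when ``phi = 0`` or ``Delta = 0``.
    """
    if not rule.satisfied:
        raise ValueError("rule is not satisfied; no azeotropic reduction applies")
    if phi < 0 or delta_bond < 0:
        raise ValueError("phi and delta_bond must be nonnegative")
    rho = 6.0 * phi / np.pi
    if rule.rule == "exclusivity":
        w = rule.partners_m / rule.n_species
    elif rule.rule == "multiplicity":
        n = rule.multiplicity_n
        w = n / (n + 1.0)
    elif rule.rule == "fully_connected":
        w = 1.0
    else:
        raise ValueError(f"unknown rule {rule.rule!r}")
    c = rho * delta_bond * w
    if c == 0.0:
        return 1.0
    x = 2.0 / (1.0 + np.sqrt(1.0 + 4.0 * c))
    if not (0.0 < x <= 1.0):
        raise RuntimeError(f"no physical root in (0, 1]: got {x}")
    return float(x)
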