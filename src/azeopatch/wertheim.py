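"""Multicomponent Wertheim first-order perturbation theory (TPT1).

The Helmholtz free energy per particle (in units of k_B T) of a mixture of
equal-diameter patchy particles is

    beta f = beta f_ideal + beta f_HS + beta f_bond

with the Carnahan-Starling hard-sphere excess term, and the bonding term
evaluated at the solution of the law of mass action

    X_a^(i) = 1 / (1 + rho * sum_j x^(j) sum_{g in Gamma(j)}
                       Upsilon[c(a), c(g)] * Delta * X_g^(j))

where ``X_a^(i)`` is the probability that patch ``a`` of species ``i`` is
unbonded and ``Delta`` is the bond integral

    Delta = V_b * (exp(eps/k_B T) - 1) * <g_HS>

with the Kern-Frenkel bonding volume ``V_b`` and the hard-sphere radial
distribution function approximated by its (optionally linear) expansion
around the contact value.  Assumptions: one bond per patch, no closed
bonding loops, all bonds of equal strength and volume, equal diameters.

Units: temperature in eps/k_B, density in sigma^-3, pressure in eps/sigma^3,
free energies per particle either in k_B T (``beta_f``) or in eps (``a``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .interactions import KernFrenkelParams, MixtureSpec, bonding_volume

__all__ = [
    "PHI_MAX",
    "ThermoState",
    "BondProbabilities",
    "FreeEnergyBreakdown",
    "GibbsResult",
    "contact_value",
    "contact_slope",
    "bond_integral",
    "solve_mass_balance",
    "helmholtz_free_energy",
    "free_energy_kT",
    "pressure",
    "gibbs_free_energy",
    "common_tangent",
    "fixed_x_coexistence",
    "find_azeotrope",
]

#: close-packing bound on the packing fraction
PHI_MAX = 0.7405

V_SPHERE = np.pi / 6.0  # particle volume for sigma = 1

# module tolerances (overridable)
MASS_BALANCE_TOL = 1e-13
MASS_BALANCE_MAX_ITER = 100_000
RHO_SCAN = np.logspace(-6, np.log10(1.1), 80)


@dataclass(frozen=True)
class ThermoState:
    """A thermodynamic state point (T, rho, x)."""

    temperature: float
    density: float
    composition: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.composition, dtype=float)
        object.__setattr__(self, "composition", x)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.density < 0:
            raise ValueError("density must be nonnegative")
        if not (0 <= self.packing_fraction < PHI_MAX):
            raise ValueError(f"packing fraction {self.packing_fraction:.4f} out of [0, {PHI_MAX})")
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-12:
            raise ValueError("composition must be nonnegative and sum to 1")

    @property
    def packing_fraction(self) -> float:
        return self.density * V_SPHERE


@dataclass(frozen=True)
class BondProbabilities:
    """Unbonded-patch probabilities X_a^(i), shape (N_s, N_p)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise ValueError("bond probabilities must lie in (0, 1]")

    @property
    def spread(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Helmholtz free energy per particle, split by contribution (k_B T units)."""

    f_ideal: float
    f_hs: float
    f_bond: float

    @property
    def f_total(self) -> float:
        return self.f_ideal + self.f_hs + self.f_bond


@dataclass(frozen=True)
class GibbsResult:
    """Gibbs free energy per particle at fixed (T, P, x) and its minimizer."""

    g: float
    rho: float
    minima: tuple  # all (rho, g) local minima found; >1 signals a two-phase region


# -- hard-sphere structure -------------------------------------------------


def contact_value(phi: float) -> float:
    """Carnahan-Starling contact value g_HS(sigma)."""
    return (1.0 - 0.5 * phi) / (1.0 - phi) ** 3


def contact_slope(phi: float) -> float:
    """sigma * dg_HS/dr at contact, consistent with the exact low-density
    limit -(9/2) phi."""
    return -4.5 * phi * (1.0 + phi) / (1.0 - phi) ** 3


def bond_integral(
    kf: KernFrenkelParams, T: float, rho: float, order: int = 1
) -> float:
    """Bond integral Delta (units sigma^3).

    Delta = (e^{eps/T} - 1) * p^2 * 4 pi Int_sigma^{sigma+delta} g_HS(r) r^2 dr
    with p = (1 - cos theta_max)/2 the per-patch angular acceptance and
    g_HS(r) expanded around contact to the given order (0: constant contact
    value, 1: linear in r - sigma).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if order not in (0, 1):
        raise ValueError("expansion order must be 0 or 1")
    phi = rho * V_SPHERE
    s = kf.sigma
    w = kf.delta * s
    g0 = contact_value(phi)
    p = 0.5 * (1.0 - kf.cos_theta_max)
    mayer = np.expm1(kf.epsilon / T)
    # shell moments: I0 = Int r^2 dr, I1 = Int (r - sigma) r^2 dr
    i0 = ((s + w) ** 3 - s**3) / 3.0
    shell = 4.0 * np.pi * g0 * i0
    if order == 1:
        g1 = contact_slope(phi) / s
        i1 = ((s + w) ** 4 - s**4) / 4.0 - s * i0
        shell += 4.0 * np.pi * g1 * i1
    return float(mayer * p * p * shell)


# -- law of mass action ----------------------------------------------------


def _coupling_matrix(mixture: MixtureSpec, rho: float, x, delta_bond: float) -> np.ndarray:
    """W[(i,a),(j,g)] = rho * x_j * Delta * Upsilon[c(i,a), c(j,g)]."""
    colors = mixture.patch_color_table()
    n_s, n_p = colors.shape
    ups = mixture.matrix.entries[colors.reshape(-1)[:, None], colors.reshape(-1)[None, :]]
    xj = np.repeat(np.asarray(x, dtype=float), n_p)
    return rho * delta_bond * ups * xj[None, :]


def solve_mass_balance(
    mixture: MixtureSpec,
    state: ThermoState,
    delta_bond: float | None = None,
) -> BondProbabilities:
    """Solve the coupled N_s x N_p mass-balance equations.

    Damped fixed-point iteration (damping 0.5) from X = 1 followed by a
    Newton polish; the returned solution has residual norm < 1e-12.  If
    ``delta_bond`` is omitted it is computed from the mixture's potential at
    the state's (T, rho).
    """
    if delta_bond is None:
        delta_bond = bond_integral(mixture.kf, state.temperature, state.density)
    n_s, n_p = mixture.n_species, mixture.n_patches
    w = _coupling_matrix(mixture, state.density, state.composition, delta_bond)
    x_vec = np.ones(n_s * n_p)
    damping = 0.5
    for it in range(MASS_BALANCE_MAX_ITER):
        target = 1.0 / (1.0 + w @ x_vec)
        step = target - x_vec
        x_vec = x_vec + damping * step
        if np.max(np.abs(step)) < 1e-10:
            break
    # Newton polish on R(X) = X * (1 + W X) - 1 = 0
    for _ in range(50):
        wx = w @ x_vec
        res = x_vec * (1.0 + wx) - 1.0
        if np.linalg.norm(res) < MASS_BALANCE_TOL:
            break
        jac = np.diag(1.0 + wx) + x_vec[:, None] * w
        x_vec = x_vec - np.linalg.solve(jac, res)
        x_vec = np.clip(x_vec, 1e-15, 1.0)
    res = np.linalg.norm(x_vec * (1.0 + w @ x_vec) - 1.0)
    if res > 1e-12:
        raise RuntimeError(f"mass balance did not converge: residual {res:.3e}")
    return BondProbabilities(x_vec.reshape(n_s, n_p))


# -- free energies ---------------------------------------------------------


def helmholtz_free_energy(
    mixture: MixtureSpec, state: ThermoState, delta_bond: float | None = None
) -> FreeEnergyBreakdown:
    """Ideal + Carnahan-Starling + bonding free energy per particle (k_B T).

    The thermal volume of every species is set to sigma^3, a composition-
    independent additive constant that drops out of all coexistence
    calculations.
    """
    t, rho, x = state.temperature, state.density, state.composition
    phi = state.packing_fraction
    if phi >= PHI_MAX:
        raise ValueError("packing fraction beyond close packing")
    if delta_bond is None:
        delta_bond = bond_integral(mixture.kf, t, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        xlog = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)
    f_ideal = float(np.sum(xlog)) + (np.log(rho) - 1.0 if rho > 0 else 0.0)
    f_hs = phi * (4.0 - 3.0 * phi) / (1.0 - phi) ** 2
    if rho == 0 or delta_bond == 0:
        f_bond = 0.0
    else:
        xa = solve_mass_balance(mixture, state, delta_bond).values
        per_patch = np.log(xa) - 0.5 * xa + 0.5
        f_bond = float(np.sum(x[:, None] * per_patch))
    return FreeEnergyBreakdown(f_ideal=f_ideal, f_hs=f_hs, f_bond=f_bond)


def free_energy_kT(mixture: MixtureSpec, T: float, rho: float, x) -> float:
    """beta*f at (T, rho, x); convenience wrapper."""
    state = ThermoState(T, rho, np.asarray(x, dtype=float))
    return helmholtz_free_energy(mixture, state).f_total


def excess_free_energy_kT(mixture: MixtureSpec, T: float, rho: float, x) -> float:
    """beta*(f_HS + f_bond): the free energy beyond the ideal mixture term.

    Unlike :func:`free_energy_kT` this accepts slightly negative mole
    fractions (analytic continuation), which finite-difference callers need
    when a species density sits close to zero.
    """
    x = np.asarray(x, dtype=float)
    phi = rho * V_SPHERE
    if phi >= PHI_MAX:
        raise ValueError("packing fraction beyond close packing")
    f_hs = phi * (4.0 - 3.0 * phi) / (1.0 - phi) ** 2
    if rho == 0:
        return f_hs
    delta_bond = bond_integral(mixture.kf, T, rho)
    if delta_bond == 0:
        return f_hs
    n_s, n_p = mixture.n_species, mixture.n_patches
    w = _coupling_matrix(mixture, rho, x, delta_bond)
    x_vec = np.ones(n_s * n_p)
    for _ in range(2000):
        target = 1.0 / (1.0 + w @ x_vec)
        step = target - x_vec
        x_vec = x_vec + 0.5 * step
        if np.max(np.abs(step) / np.maximum(x_vec, 1e-300)) < 1e-12:
            break
    for _ in range(50):
        wx = w @ x_vec
        res = x_vec * (1.0 + wx) - 1.0
        if np.linalg.norm(res) < MASS_BALANCE_TOL or not np.all(np.isfinite(res)):
            break
        jac = np.diag(1.0 + wx) + x_vec[:, None] * w
        try:
            x_new = x_vec - np.linalg.solve(jac, res)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(x_new)) or np.any(x_new <= 0):
            break
        x_vec = x_new
    xa = x_vec.reshape(n_s, n_p)
    per_patch = np.log(xa) - 0.5 * xa + 0.5
    return f_hs + float(np.sum(x[:, None] * per_patch))


def _dfex_drho(mixture: MixtureSpec, T: float, rho: float, x) -> float:
    """d(beta f_excess)/d rho at fixed x, central differences + Richardson."""
    h = 1e-6 * max(rho, 1e-2)
    if rho - 2 * h <= 0:
        h = 0.4 * rho

    def fe(r):
        return excess_free_energy_kT(mixture, T, r, x)

    d1 = (fe(rho + h) - fe(rho - h)) / (2 * h)
    d2 = (fe(rho + 0.5 * h) - fe(rho - 0.5 * h)) / h
    return (4.0 * d2 - d1) / 3.0


def pressure(mixture: MixtureSpec, T: float, rho: float, x) -> float:
    """P = rho^2 d f/d rho at fixed composition, in eps/sigma^3.

    The ideal part contributes rho*T analytically; only the excess part is
    differentiated numerically.
    """
    return T * rho + T * rho * rho * _dfex_drho(mixture, T, rho, x)


def gibbs_free_energy(
    mixture: MixtureSpec, T: float, P: float, x, polish: bool = True
) -> GibbsResult:
    """Gibbs free energy per particle g(T, P, x) = min_rho [a(rho, x) + P/rho].

    The density axis is scanned on a log grid to bracket every local minimum
    (two in a two-phase region); each bracket is refined by Brent's method
    and polished on the mechanical-equilibrium condition P(rho) = P so that
    the returned density reproduces the input pressure to ~1e-10.
    """
    if P <= 0:
        raise ValueError("pressure must be positive")
    x = np.asarray(x, dtype=float)

    def h(rho):
        return T * free_energy_kT(mixture, T, rho, x) + P / rho

    grid = RHO_SCAN
    values = np.array([h(r) for r in grid])
    minima = []
    for k in range(1, len(grid) - 1):
        if values[k] <= values[k - 1] and values[k] <= values[k + 1]:
            res = optimize.minimize_scalar(
                h, bracket=(grid[k - 1], grid[k], grid[k + 1]), method="brent",
                options={"xtol": 1e-12},
            )
            rho_m = float(res.x)
            if polish:
                # polish on P(rho) = P inside the bracket
                def dp(r):
                    return pressure(mixture, T, r, x) - P

                try:
                    lo, hi = grid[k - 1], grid[k + 1]
                    if dp(lo) * dp(hi) < 0:
                        rho_m = float(optimize.brentq(dp, lo, hi, xtol=1e-14, rtol=1e-14))
                except ValueError:
                    pass
            minima.append((rho_m, float(h(rho_m))))
    # deduplicate minima that collapsed to the same point
    minima.sort()
    dedup = []
    for rho_m, g_m in minima:
        if not dedup or abs(rho_m - dedup[-1][0]) > 1e-6 * max(1.0, rho_m):
            dedup.append((rho_m, g_m))
    if not dedup:
        raise RuntimeError(f"no Gibbs minimum found in density scan at P={P}, x={x}")
    rho_best, g_best = min(dedup, key=lambda t: t[1])
    return GibbsResult(g=g_best, rho=rho_best, minima=tuple(dedup))


def _g_and_slope(mixture: MixtureSpec, T: float, P: float, x1: float):
    """g(x1) and dg/dx1 for a binary mixture (envelope theorem: the slope is
    the partial of a(rho, x) at the minimizing density)."""
    res = gibbs_free_energy(mixture, T, P, [x1, 1.0 - x1])
    h = 1e-6
    lo, hi = max(x1 - h, 0.0), min(x1 + h, 1.0)
    a_hi = T * free_energy_kT(mixture, T, res.rho, [hi, 1.0 - hi])
    a_lo = T * free_energy_kT(mixture, T, res.rho, [lo, 1.0 - lo])
    return res.g, (a_hi - a_lo) / (hi - lo), res.rho


def common_tangent(
    mixture: MixtureSpec,
    T: float,
    P: float,
    x_grid_step: float = 0.005,
    x_window: tuple = (0.0, 1.0),
):
    """Coexisting composition pair of a binary mixture at fixed (T, P).

    Samples g(x), takes the lower convex hull to bracket a concave gap, then
    solves the two-unknown system (equal slope, equal intercept) -- i.e.
    equal chemical potentials of both species.  Returns ``None`` when g is
    convex on [0, 1] (single phase), else ``(x1, x2, rho1, rho2)``.
    """
    if mixture.n_species != 2:
        raise ValueError("common_tangent requires a binary mixture")
    lo_w = max(x_window[0], x_grid_step)
    hi_w = min(x_window[1], 1.0 - 0.5 * x_grid_step)
    xs = np.arange(lo_w, hi_w, x_grid_step)
    gs = np.array(
        [gibbs_free_energy(mixture, T, P, [x, 1 - x], polish=False).g for x in xs]
    )
    # lower convex hull scan (monotone chain on (x, g))
    hull = []
    for k in range(len(xs)):
        while len(hull) >= 2:
            (xa, ga), (xb, gb) = hull[-2], hull[-1]
            if (gb - ga) * (xs[k] - xb) - (gs[k] - gb) * (xb - xa) >= 0:
                hull.pop()
            else:
                break
        hull.append((xs[k], gs[k]))
    gap = None
    for (xa, _), (xb, _) in zip(hull[:-1], hull[1:]):
        width = xb - xa
        if width > 1.5 * x_grid_step and (gap is None or width > gap[1] - gap[0]):
            gap = (xa, xb)
    if gap is None:
        return None

    def system(v):
        x1, x2 = v
        g1, s1, _ = _g_and_slope(mixture, T, P, x1)
        g2, s2, _ = _g_and_slope(mixture, T, P, x2)
        return [s1 - s2, (g1 - x1 * s1) - (g2 - x2 * s2)]

    sol = optimize.root(system, list(gap), method="hybr", options={"xtol": 1e-12})
    x1, x2 = sorted(sol.x)
    if not sol.success or not (0 < x1 < x2 < 1) or (x2 - x1) < 0.25 * x_grid_step:
        return None
    rho1 = gibbs_free_energy(mixture, T, P, [x1, 1 - x1]).rho
    rho2 = gibbs_free_energy(mixture, T, P, [x2, 1 - x2]).rho
    return float(x1), float(x2), rho1, rho2


def fixed_x_coexistence(mixture: MixtureSpec, T: float, x, P_bracket=(1e-8, 1e-1)):
    """Pressure at which the gas and liquid Gibbs minima are equally deep at
    fixed composition (the effective one-component construction; a true
    coexistence only at an azeotropic composition).

    Returns ``(P, rho_gas, rho_liquid)`` or ``None`` if no double minimum
    exists in the bracket (e.g. above the critical temperature).
    """
    x = np.asarray(x, dtype=float)

    def depth_gap(p):
        res = gibbs_free_energy(mixture, T, p, x)
        if len(res.minima) < 2:
            # single minimum: sign by which branch survives
            rho = res.minima[0][0]
            return -1.0 if rho < 0.15 else 1.0
        (rg, gg), (rl, gl) = res.minima[0], res.minima[-1]
        return gg - gl

    lo, hi = P_bracket
    ps = np.logspace(np.log10(lo), np.log10(hi), 25)
    vals = [depth_gap(p) for p in ps]
    bracket = None
    for k in range(len(ps) - 1):
        if vals[k] < 0 <= vals[k + 1]:
            bracket = (ps[k], ps[k + 1])
            break
    if bracket is None:
        return None
    p_co = optimize.brentq(depth_gap, *bracket, xtol=1e-14, rtol=1e-13)
    res = gibbs_free_energy(mixture, T, p_co, x)
    return float(p_co), res.minima[0][0], res.minima[-1][0]


def _slope_mismatch(mixture: MixtureSpec, T: float, x1: float) -> float | None:
    """Difference of da/dx between the two equal-depth phases at fixed x.

    Vanishes exactly at an azeotropic composition, where the equal-depth
    double minimum is a true coexistence (equal P, equal mu of both species,
    equal composition).
    """
    co = fixed_x_coexistence(mixture, T, [x1, 1.0 - x1])
    if co is None:
        return None
    _, rho_g, rho_l = co
    h = 1e-6

    def dadx(rho):
        a_hi = T * free_energy_kT(mixture, T, rho, [x1 + h, 1 - x1 - h])
        a_lo = T * free_energy_kT(mixture, T, rho, [x1 - h, 1 - x1 + h])
        return (a_hi - a_lo) / (2 * h)

    return dadx(rho_g) - dadx(rho_l)


def find_azeotrope(mixture: MixtureSpec, T: float, x_bracket=(0.35, 0.65)):
    """Locate the azeotropic composition and pressure of a binary mixture.

    At an azeotrope the coexisting phases share the mixture's composition, so
    the equal-depth two-minimum construction at fixed x becomes a true
    coexistence; away from it the two phases disagree on the exchange
    chemical potential da/dx.  The azeotrope is found as the root of that
    mismatch over ``x_bracket``.

    Returns ``(x_az, P_az, rho_gas, rho_liquid)`` or ``None`` when no
    equal-depth construction exists in the bracket (no lens at this T).
    """

    def mm(x1):
        v = _slope_mismatch(mixture, T, x1)
        if v is None:
            raise RuntimeError(f"no two-phase construction at x={x1}, T={T}")
        return v

    lo, hi = x_bracket
    f_lo, f_hi = mm(lo), mm(hi)
    if f_lo * f_hi > 0:
        return None
    x_az = optimize.brentq(mm, lo, hi, xtol=1e-7)
    p_az, rho_g, rho_l = fixed_x_coexistence(mixture, T, [x_az, 1.0 - x_az])
    return float(x_az), float(p_az), rho_g, rho_l
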