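"""Isochoric-thermodynamics binodal tracing.

The fundamental potential is the Helmholtz energy density
``Psi(rho_vec, T) = rho * a(rho, x)`` as a function of the per-species molar
densities ``rho_i`` (units sigma^-3).  Chemical potentials and pressure
follow as ``mu_i = dPsi/drho_i`` and ``P = -Psi + sum_i rho_i mu_i``; local
stability is encoded in the Hessian ``H_ij = d^2 Psi / drho_i drho_j``.

Two phases coexist at equal T when their pressures and all chemical
potentials agree.  Differentiating those equalities along an isothermal
phase boundary gives a linear ODE system for ``d rho'/dP`` and
``d rho''/dP``: with ``m = d mu/dP`` shared by both phases,

    [rho'^T; rho''^T] m = (1, 1),     drho'/dP = H'^-1 m,   drho''/dP = H''^-1 m.

Integrating from one accurately known coexistence pair traces the whole
binodal; every accepted step is Newton-projected back onto the coexistence
manifold.  Critical points satisfy ``det H = 0`` together with the vanishing
of the cubic form along the Hessian's null direction; near them the
integration stiffens and the tracer stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .interactions import MixtureSpec
from .wertheim import excess_free_energy_kT, free_energy_kT

__all__ = [
    "CoexistencePoint",
    "CoexistenceCurve",
    "psi",
    "grad_psi",
    "hessian",
    "pressure_from_psi",
    "trace_binodal",
    "find_critical_point",
    "section_critical_temperature",
    "point_from_common_tangent",
    "azeotrope_from_curve",
]

_H_GRAD = 1e-6  # relative FD step for gradients
_H_HESS = 2e-4  # relative FD step for second derivatives


@dataclass(frozen=True)
class CoexistencePoint:
    """A pair of coexisting phases at one (T, P)."""

    phase_a: np.ndarray  # per-species densities of phase '
    phase_b: np.ndarray  # per-species densities of phase ''
    pressure: float
    temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_a", np.asarray(self.phase_a, dtype=float))
        object.__setattr__(self, "phase_b", np.asarray(self.phase_b, dtype=float))

    def compositions(self):
        xa = self.phase_a / self.phase_a.sum()
        xb = self.phase_b / self.phase_b.sum()
        return xa, xb

    def residual(self, mixture: MixtureSpec) -> float:
        """Max violation of equal-P / equal-mu between the phases."""
        t = self.temperature
        mu_a = grad_psi(self.phase_a, t, mixture)
        mu_b = grad_psi(self.phase_b, t, mixture)
        pa = pressure_from_psi(self.phase_a, t, mixture)
        pb = pressure_from_psi(self.phase_b, t, mixture)
        return float(max(np.max(np.abs(mu_a - mu_b)), abs(pa - pb)))


@dataclass
class CoexistenceCurve:
    """Traced binodal: coexistence points plus critical/azeotropic features."""

    points: list = field(default_factory=list)
    critical_points: list = field(default_factory=list)  # (rho_vec, T, P)
    azeotropes: list = field(default_factory=list)  # (x, T, P)
    termination: str = ""

    def pressures(self) -> np.ndarray:
        return np.array([p.pressure for p in self.points])


# -- the potential and its derivatives ------------------------------------


def _psi_excess(rho: np.ndarray, T: float, mixture: MixtureSpec) -> float:
    """Excess (hard-sphere + bonding) part of Psi; tolerates slightly
    negative species densities by analytic continuation, which the finite
    differences below need near a vanishing species."""
    total = float(np.sum(rho))
    if total <= 0:
        return 0.0
    x = np.asarray(rho, dtype=float) / total
    return total * T * excess_free_energy_kT(mixture, T, total, x)


def psi(rho: np.ndarray, T: float, mixture: MixtureSpec) -> float:
    """Helmholtz energy density Psi (units eps/sigma^3)."""
    rho = np.asarray(rho, dtype=float)
    total = float(rho.sum())
    if total <= 0:
        return 0.0
    ideal = T * float(np.sum(rho * (np.log(rho) - 1.0)))
    return ideal + _psi_excess(rho, T, mixture)


def _directional_steps(rho, i, h):
    e = np.zeros_like(rho)
    e[i] = h
    return e


def grad_psi(rho: np.ndarray, T: float, mixture: MixtureSpec) -> np.ndarray:
    """Chemical potentials mu_i = dPsi/drho_i.

    The ideal-mixture part T ln(rho_i) is analytic; the excess part is
    differentiated by Richardson-extrapolated central differences.
    """
    rho = np.asarray(rho, dtype=float)
    scale = max(rho.sum(), 1e-8)
    out = np.empty(len(rho))
    for i in range(len(rho)):
        h = _H_GRAD * scale
        e = _directional_steps(rho, i, h)
        d1 = (_psi_excess(rho + e, T, mixture) - _psi_excess(rho - e, T, mixture)) / (2 * h)
        d2 = (_psi_excess(rho + 0.5 * e, T, mixture)
              - _psi_excess(rho - 0.5 * e, T, mixture)) / h
        out[i] = T * np.log(rho[i]) + (4.0 * d2 - d1) / 3.0
    return out


def pressure_from_psi(rho: np.ndarray, T: float, mixture: MixtureSpec) -> float:
    """P = -Psi + sum_i rho_i mu_i."""
    rho = np.asarray(rho, dtype=float)
    return float(-psi(rho, T, mixture) + rho @ grad_psi(rho, T, mixture))


def hessian(rho: np.ndarray, T: float, mixture: MixtureSpec) -> np.ndarray:
    """H_ij = d^2 Psi / drho_i drho_j.

    The ideal part contributes the exact diagonal T/rho_i.  For binary
    mixtures the excess part is differentiated in (rho, x) coordinates --
    where the density and composition responses have very different
    stiffness near an azeotropic composition -- and mapped back exactly;
    this keeps the large composition-curvature terms consistent between
    matrix entries.  For more components a plain per-density stencil is
    used.
    """
    rho = np.asarray(rho, dtype=float)
    n = len(rho)
    if n == 2:
        h_ex = _hessian_excess_binary(rho, T, mixture)
    else:
        h_ex = _hessian_excess_generic(rho, T, mixture)
    return 0.5 * (h_ex + h_ex.T) + np.diag(T / rho)


def _hessian_excess_binary(rho, T, mixture):
    total = float(rho.sum())
    x1 = rho[0] / total
    x2 = 1.0 - x1
    hr = _H_HESS * total
    hx = 1e-4

    def phi(r, x):
        return r * T * excess_free_energy_kT(mixture, T, r, np.array([x, 1.0 - x]))

    f0 = phi(total, x1)
    f_r = (phi(total + hr, x1) - phi(total - hr, x1)) / (2 * hr)
    f_rr = (phi(total + hr, x1) - 2 * f0 + phi(total - hr, x1)) / hr**2
    f_x = (phi(total, x1 + hx) - phi(total, x1 - hx)) / (2 * hx)
    f_xx = (phi(total, x1 + hx) - 2 * f0 + phi(total, x1 - hx)) / hx**2
    f_rx = (
        phi(total + hr, x1 + hx)
        - phi(total + hr, x1 - hx)
        - phi(total - hr, x1 + hx)
        + phi(total - hr, x1 - hx)
    ) / (4 * hr * hx)
    _ = f_r  # the gradient path handles first derivatives
    b1, b2 = x2 / total, -x1 / total
    h_mat = np.empty((2, 2))
    h_mat[0, 0] = f_rr + 2 * f_rx * b1 + f_xx * b1 * b1 + f_x * (-2 * x2 / total**2)
    h_mat[1, 1] = f_rr + 2 * f_rx * b2 + f_xx * b2 * b2 + f_x * (2 * x1 / total**2)
    h_mat[0, 1] = h_mat[1, 0] = (
        f_rr + f_rx * (b1 + b2) + f_xx * b1 * b2 + f_x * (x1 - x2) / total**2
    )
    return h_mat


def _hessian_excess_generic(rho, T, mixture):
    n = len(rho)
    scale = max(rho.sum(), 1e-8)
    h = _H_HESS * scale
    f0 = _psi_excess(rho, T, mixture)
    h_mat = np.empty((n, n))
    for i in range(n):
        ei = _directional_steps(rho, i, h)
        h_mat[i, i] = (
            _psi_excess(rho + ei, T, mixture) - 2 * f0 + _psi_excess(rho - ei, T, mixture)
        ) / h**2
        for j in range(i + 1, n):
            ej = _directional_steps(rho, j, h)
            h_mat[i, j] = h_mat[j, i] = (
                _psi_excess(rho + ei + ej, T, mixture)
                - _psi_excess(rho + ei - ej, T, mixture)
                - _psi_excess(rho - ei + ej, T, mixture)
                + _psi_excess(rho - ei - ej, T, mixture)
            ) / (4 * h * h)
    return h_mat


# -- coexistence manifold -------------------------------------------------


def _mu_and_pressure(rho, T, mixture):
    mu = grad_psi(rho, T, mixture)
    return mu, float(-psi(rho, T, mixture) + rho @ mu)


def _project_to_coexistence(rho_a, rho_b, T, P_target, mixture, tol=1e-9, max_iter=40):
    """Newton-correct (rho', rho'') onto equal-mu, P = P_target.

    Uses the analytic Jacobian of the coexistence conditions:
    d mu / d rho = H_Psi and d P / d rho = rho^T H_Psi.
    """
    ra = np.asarray(rho_a, dtype=float).copy()
    rb = np.asarray(rho_b, dtype=float).copy()

    def residual(ra, rb):
        mu_a, pa = _mu_and_pressure(ra, T, mixture)
        mu_b, pb = _mu_and_pressure(rb, T, mixture)
        return np.concatenate([mu_a - mu_b, [pa - P_target, pb - P_target]])

    res = residual(ra, rb)
    scale = max(abs(P_target), 1e-12)
    for _ in range(max_iter):
        if np.max(np.abs(res[:2])) < tol and np.max(np.abs(res[2:])) < tol * max(1.0, scale):
            return ra, rb
        try:
            h_a = hessian(ra, T, mixture)
            h_b = hessian(rb, T, mixture)
        except (ValueError, np.linalg.LinAlgError):
            return None
        jac = np.zeros((4, 4))
        jac[:2, :2] = h_a
        jac[:2, 2:] = -h_b
        jac[2, :2] = ra @ h_a
        jac[3, 2:] = rb @ h_b
        try:
            step = np.linalg.solve(jac, res)
        except np.linalg.LinAlgError:
            return None
        # backtracking line search
        lam, improved = 1.0, False
        norm0 = np.linalg.norm(res / np.array([1.0, 1.0, scale, scale]))
        for _ in range(8):
            ra_new = ra - lam * step[:2]
            rb_new = rb - lam * step[2:]
            if np.all(ra_new > 0) and np.all(rb_new > 0):
                res_new = residual(ra_new, rb_new)
                if np.linalg.norm(res_new / np.array([1.0, 1.0, scale, scale])) < norm0:
                    ra, rb, res = ra_new, rb_new, res_new
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            return None
    return None


def point_from_common_tangent(mixture: MixtureSpec, T: float, pair) -> CoexistencePoint:
    """Convert a wertheim.common_tangent result into a CoexistencePoint."""
    x1, x2, rho1, rho2 = pair
    rho_a = rho1 * np.array([x1, 1 - x1])
    rho_b = rho2 * np.array([x2, 1 - x2])
    p = pressure_from_psi(rho_a, T, mixture)
    proj = _project_to_coexistence(rho_a, rho_b, T, p, mixture, tol=1e-7)
    if proj is not None:
        rho_a, rho_b = proj
        p = pressure_from_psi(rho_a, T, mixture)
    return CoexistencePoint(rho_a, rho_b, p, T)


def _binodal_rhs(rho_a, rho_b, T, mixture):
    """(drho'/dP, drho''/dP) from the isothermal coexistence ODE system."""
    h_a = hessian(rho_a, T, mixture)
    h_b = hessian(rho_b, T, mixture)
    m = np.linalg.solve(np.vstack([rho_a, rho_b]), np.ones(2))
    return np.linalg.solve(h_a, m), np.linalg.solve(h_b, m), h_a, h_b


def trace_binodal(
    start: CoexistencePoint,
    T: float,
    P_range: tuple,
    mixture: MixtureSpec,
    rel_step: float = 0.03,
    max_steps: int = 400,
    det_ratio_floor: float = 1e-8,
    step_floor: float = 1e-10,
) -> CoexistenceCurve:
    """Trace the isothermal binodal from one coexistence pair.

    Integrates d rho/dP for both phases with an adaptive predictor step and a
    Newton projection back onto the coexistence manifold after every step.
    Stops at the edge of ``P_range``, when the Hessian determinant of either
    phase collapses (approach to a critical point), when the step size
    collapses, or when the phases merge in composition (azeotrope).
    """
    if start.residual(mixture) > 1e-7:
        raise ValueError("start point violates the coexistence invariants")
    p_lo, p_hi = min(P_range), max(P_range)
    curve = CoexistenceCurve(points=[start])
    direction = -1.0 if abs(start.pressure - p_lo) > abs(start.pressure - p_hi) else 1.0
    rho_a, rho_b = start.phase_a.copy(), start.phase_b.copy()
    p = start.pressure
    dp = direction * rel_step * p
    det0 = None
    for _ in range(max_steps):
        if abs(dp) < step_floor:
            curve.termination = "step-size collapse"
            break
        try:
            da, db, h_a, h_b = _binodal_rhs(rho_a, rho_b, T, mixture)
        except np.linalg.LinAlgError:
            curve.termination = "singular Hessian"
            break
        det = min(abs(np.linalg.det(h_a)), abs(np.linalg.det(h_b)))
        if det0 is None:
            det0 = det
        if det < det_ratio_floor * det0:
            curve.termination = "critical point (det H collapse)"
            break
        p_new = p + dp
        if p_new < p_lo or p_new > p_hi:
            p_new = np.clip(p_new, p_lo, p_hi)
            dp = p_new - p
            if abs(dp) < step_floor:
                curve.termination = "pressure range exhausted"
                break
        # midpoint predictor
        ra_mid = rho_a + 0.5 * dp * da
        rb_mid = rho_b + 0.5 * dp * db
        try:
            da2, db2, _, _ = _binodal_rhs(ra_mid, rb_mid, T, mixture)
            ra_pred = rho_a + dp * da2
            rb_pred = rho_b + dp * db2
        except (np.linalg.LinAlgError, ValueError):
            dp *= 0.5
            continue
        proj = _project_to_coexistence(ra_pred, rb_pred, T, p_new, mixture, tol=1e-7)
        if proj is None:
            dp *= 0.5
            continue
        rho_a, rho_b = proj
        p = p_new
        point = CoexistencePoint(rho_a.copy(), rho_b.copy(), p, T)
        curve.points.append(point)
        xa, xb = point.compositions()
        if abs(xa[0] - xb[0]) < 1e-4:
            curve.azeotropes.append((0.5 * (xa[0] + xb[0]), T, p))
            curve.termination = "azeotrope (phases merged in composition)"
            break
        dp *= 1.3
        if abs(dp) > rel_step * p:
            dp = direction * rel_step * p
    else:
        curve.termination = curve.termination or "max steps"
    if curve.termination.startswith("critical point"):
        curve.critical_points.append((0.5 * (rho_a + rho_b), T, p))
    if curve.termination == "step-size collapse" and len(curve.points) >= 4:
        # the ODE is singular where the tie line becomes vertical: if the
        # branches have pinched in composition, that stall IS the azeotrope
        xa, xb = curve.points[-1].compositions()
        if abs(xa[0] - xb[0]) < 0.05 and not curve.azeotropes:
            est = azeotrope_from_curve(curve)
            if est is not None:
                curve.azeotropes.append((est[0], T, est[1]))
                curve.termination = "azeotrope (tie line vertical)"
    return curve


def azeotrope_from_curve(curve: CoexistenceCurve, n_last: int = 8):
    """Azeotropic (x, P) from the pinch of a traced binodal.

    Near a negative azeotrope both branches follow P = P_az + A (x - x_az)^2
    with a shared vertex; the vertex is recovered by profiling the composition
    and solving the per-branch curvatures by linear least squares.
    """
    pts = curve.points[-n_last:]
    if len(pts) < 4:
        return None
    x_dew, x_bub, ps = [], [], []
    for p in pts:
        xa, xb = p.compositions()
        dew_first = p.phase_a.sum() < p.phase_b.sum()
        x_dew.append(xa[0] if dew_first else xb[0])
        x_bub.append(xb[0] if dew_first else xa[0])
        ps.append(p.pressure)
    x_dew, x_bub, ps = map(np.array, (x_dew, x_bub, ps))

    def sse(x_az):
        cols = [np.ones(2 * len(ps))]
        d2 = np.concatenate([(x_dew - x_az) ** 2, np.zeros(len(ps))])
        b2 = np.concatenate([np.zeros(len(ps)), (x_bub - x_az) ** 2])
        design = np.column_stack([cols[0], d2, b2])
        target = np.concatenate([ps, ps])
        coef, res, *_ = np.linalg.lstsq(design, target, rcond=None)
        pred = design @ coef
        return float(np.sum((pred - target) ** 2)), coef

    lo = min(x_dew.min(), x_bub.min()) - 0.2
    hi = max(x_dew.max(), x_bub.max()) + 0.2
    res = optimize.minimize_scalar(lambda v: sse(v)[0], bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    x_az = float(res.x)
    p_az = float(sse(x_az)[1][0])
    return x_az, p_az


# -- critical points ------------------------------------------------------


def _null_direction(h_mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(h_mat)
    return v[:, np.argmin(np.abs(w))]


def _cubic_form(rho, T, mixture, u, h_rel=1e-3):
    """Third directional derivative of Psi along u."""
    scale = max(float(np.sum(rho)), 1e-8)
    h = h_rel * scale

    def q(t):
        r = rho + t * u
        return u @ hessian(r, T, mixture) @ u

    return (q(h) - q(-h)) / (2 * h)


def find_critical_point(
    T: float, mixture: MixtureSpec, bracket, n_scan: int = 40
):
    """Critical point inside a density-region bracket at fixed T.

    ``bracket`` is a pair of density vectors; det H is scanned along the
    segment between them for a sign change, then the full two-condition
    system (det H = 0 and vanishing cubic form along the null direction) is
    solved by Newton iteration.  Raises ``ValueError`` when no sign change of
    det H exists in the bracket (e.g. an ideal gas, always stable).
    """
    lo = np.asarray(bracket[0], dtype=float)
    hi = np.asarray(bracket[1], dtype=float)

    def det_at(t):
        return np.linalg.det(hessian(lo + t * (hi - lo), T, mixture))

    ts = np.linspace(0.0, 1.0, n_scan)
    vals = [det_at(t) for t in ts]
    seg = None
    for k in range(n_scan - 1):
        if vals[k] * vals[k + 1] < 0:
            seg = (ts[k], ts[k + 1])
            break
    if seg is None:
        raise ValueError("no det-H sign change in bracket: no critical point found")
    t_root = optimize.brentq(det_at, *seg, xtol=1e-12)
    rho0 = lo + t_root * (hi - lo)

    def system(rho):
        if np.any(np.asarray(rho) <= 0):
            return np.array([1e6, 1e6])
        try:
            h_mat = hessian(rho, T, mixture)
            u = _null_direction(h_mat)
            return np.array([np.linalg.det(h_mat), _cubic_form(rho, T, mixture, u)])
        except ValueError:
            return np.array([1e6, 1e6])

    sol = optimize.root(system, rho0, method="hybr", options={"xtol": 1e-10})
    rho_c = sol.x if sol.success else rho0
    res = system(rho_c)
    if abs(res[0]) > 1e-9 * max(1.0, abs(np.linalg.det(hessian(lo, T, mixture)))):
        raise ValueError(f"critical-point residual too large: det H = {res[0]:.3e}")
    p_c = pressure_from_psi(rho_c, T, mixture)
    return np.asarray(rho_c), float(p_c)


def section_critical_temperature(
    mixture: MixtureSpec,
    x,
    T_bracket=(0.04, 0.12),
    rho_range=(0.02, 0.7),
    n_scan: int = 48,
) -> float:
    """Temperature at which the fixed-composition density section loses
    stability: the largest T for which det H_Psi dips to zero along the ray
    ``rho * x``.  On an azeotropic section this coincides with the mixture's
    critical temperature (the section behaves as a one-component fluid);
    elsewhere it tracks the temperature at which the section first touches
    the spinodal."""
    x = np.asarray(x, dtype=float)
    rhos = np.linspace(*rho_range, n_scan)

    def min_det(T):
        return min(np.linalg.det(hessian(r * x, T, mixture)) for r in rhos)

    lo, hi = T_bracket
    if min_det(lo) > 0:
        raise ValueError("section is stable at the lower temperature bracket")
    if min_det(hi) < 0:
        raise ValueError("section is unstable at the upper temperature bracket")
    return float(optimize.brentq(min_det, lo, hi, xtol=1e-5))
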