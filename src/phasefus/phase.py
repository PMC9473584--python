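"""Spinodals, critical points, binodals and phase-diagram scans.

Two-phase coexistence is located from the standard thermodynamic
criterion: equal protein exchange chemical potential mu = df/dphi and
equal osmotic pressure Pi = phi mu - f in the two phases.  Because
dPi/dmu = phi along each branch, the pressure mismatch is monotone in the
trial chemical potential, so the tie-line is found by a robust nested
bracketed search: for a trial mu, invert mu(phi) on the dilute branch
(below the spinodal) and on the dense branch (above it), then drive the
pressure difference to zero.  The common-tangent property of every
reported tie-line is verified in the test suite.

Concentration axes are converted with the hydration-sphere unit system;
ATP scans are semi-grand: the scan coordinate is the reservoir ATP
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .meanfield import InternalState, f_total, mu_protein, solve_internal
from .params import ModelParams
from .units import phi_to_molar

__all__ = [
    "PhasePoint",
    "CoexistenceResult",
    "mu_and_pressure",
    "spinodal_interval",
    "solve_coexistence",
    "critical_point",
    "scan_binding_energy",
    "scan_atp",
    "dissolution_concentration",
    "asymmetric_loop_metrics",
    "phi_to_molar",
]

#: default composition window scanned for instability
PHI_MIN, PHI_MAX = 1e-6, 0.90
#: floor for the dilute-branch search; mu(phi) diverges only as ln(phi)/N1,
#: so strong ATP crosslinking can push the dilute branch extremely low
PHI_FLOOR = 1e-250
#: ceiling for the dense-branch search
PHI_CEIL = 0.995


@dataclass(frozen=True)
class PhasePoint:
    """Free energy, chemical potential and osmotic pressure at one phi."""

    phi: float
    state: InternalState
    f: float
    mu: float
    Pi: float


@dataclass(frozen=True)
class CoexistenceResult:
    """A tie-line: dilute/dense compositions plus per-phase observables.

    ``rho_*`` are protein chain molarities; ``p_*`` the Tyr-Arg bond
    fractions, ``g_dense = L q`` the mean bound Arg per ATP in the dense
    phase.  ``converged`` is False when no two-phase region exists.
    """

    phi_dilute: float = math.nan
    phi_dense: float = math.nan
    rho_dilute: float = math.nan
    rho_dense: float = math.nan
    p_dilute: float = math.nan
    p_dense: float = math.nan
    g_dilute: float = math.nan
    g_dense: float = math.nan
    mu: float = math.nan
    converged: bool = False
    residual_mu: float = math.nan
    residual_pi: float = math.nan
    state_dilute: InternalState | None = field(default=None, repr=False)
    state_dense: InternalState | None = field(default=None, repr=False)


def phase_point(phi: float, params: ModelParams) -> PhasePoint:
    """Evaluate f, mu and Pi at one composition."""
    f, state = f_total(phi, params, return_state=True)
    mu = mu_protein(phi, params, state)
    return PhasePoint(phi=phi, state=state, f=f, mu=mu, Pi=phi * mu - f)


def mu_and_pressure(phi: float, params: ModelParams) -> tuple[float, float]:
    """Protein exchange chemical potential and osmotic pressure at phi."""
    pt = phase_point(phi, params)
    return pt.mu, pt.Pi


def _curvature(phi: float, params: ModelParams) -> float:
    """d^2 f / d phi^2 via central differences of the analytic mu."""
    h = 1e-5 * phi
    return (mu_protein(phi + h, params) - mu_protein(phi - h, params)) / (2 * h)


def _min_curvature(params: ModelParams, phi_min: float = PHI_MIN,
                   phi_max: float = PHI_MAX, n: int = 160) -> float:
    """Minimum of d^2f/dphi^2 over the composition window (refined).

    Negative iff the free energy has a concave (locally unstable) region,
    i.e. iff a two-phase region exists.
    """
    phis = np.geomspace(phi_min, phi_max, n)
    curv = np.array([_curvature(p, params) for p in phis])
    i = int(np.argmin(curv))
    if curv[i] < 0:
        return float(curv[i])
    lo = phis[max(i - 1, 0)]
    hi = phis[min(i + 1, n - 1)]
    res = minimize_scalar(lambda p: _curvature(p, params),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(min(res.fun, curv[i]))


def has_coexistence(params: ModelParams, **kw) -> bool:
    """Whether a two-phase region exists (free energy locally concave)."""
    return _min_curvature(params, **kw) < 0.0


def spinodal_interval(params: ModelParams, phi_min: float = PHI_MIN,
                      phi_max: float = PHI_MAX, n: int = 200) -> list[float]:
    """Zeros of d^2 f/d phi^2, bracketing the locally unstable region.

    Returns an empty list when the free energy is convex throughout.
    """
    phis = np.geomspace(phi_min, phi_max, n)
    curv = np.array([_curvature(p, params) for p in phis])
    roots: list[float] = []
    for i in range(n - 1):
        if curv[i] == 0.0:
            roots.append(float(phis[i]))
        elif curv[i] * curv[i + 1] < 0.0:
            roots.append(brentq(lambda p: _curvature(p, params),
                                phis[i], phis[i + 1], xtol=1e-14))
    return roots


def free_energy_curve(phis, params: ModelParams) -> pd.DataFrame:
    """Tabulate the free energy and internal state along a phi grid.

    Columns: phi, f_ref, f_bind, f_total, p, q, lam — ready for CSV
    export or plotting.
    """
    from .meanfield import f_binding_atp, f_reference_atp

    rows = []
    for phi in phis:
        f, state = f_total(float(phi), params, return_state=True)
        f_ref = f_reference_atp(float(phi), state.lam, params)
        rows.append({"phi": float(phi), "f_ref": f_ref,
                     "f_bind": f - f_ref, "f_total": f,
                     "p": state.p, "q": state.q, "lam": state.lam})
    return pd.DataFrame(rows)


def solve_coexistence(params: ModelParams) -> CoexistenceResult:
    """Tie-line from equal chemical potential and osmotic pressure.

    Returns a non-converged :class:`CoexistenceResult` when the free
    energy is convex (no phase separation).
    """
    sp = spinodal_interval(params)
    if len(sp) < 2:
        return CoexistenceResult(converged=False)
    s_lo, s_hi = sp[0], sp[-1]

    def mu_of(phi: float) -> float:
        return mu_protein(phi, params)

    def phi_dilute(mu: float) -> float:
        # solved in ln(phi) for conditioning: the branch spans many decades
        u = brentq(lambda u_: mu_of(math.exp(u_)) - mu,
                   math.log(PHI_FLOOR), math.log(s_lo),
                   xtol=1e-13, rtol=8.9e-16)
        return math.exp(u)

    def phi_dense(mu: float) -> float:
        return brentq(lambda p: mu_of(p) - mu, s_hi, PHI_CEIL,
                      xtol=1e-16, rtol=8.9e-16)

    def pressure(phi: float, mu: float) -> float:
        return phi * mu - f_total(phi, params)

    # attainable trial-mu window on both branches
    eps = 1e-12
    mu_lo = max(mu_of(s_hi), mu_of(PHI_FLOOR * 1.01)) + eps
    mu_hi = min(mu_of(s_lo), mu_of(PHI_CEIL)) - eps
    if not mu_lo < mu_hi:
        return CoexistenceResult(converged=False)

    def dpi(mu: float) -> float:
        return (pressure(phi_dense(mu), mu)
                - pressure(phi_dilute(mu), mu))

    d_lo, d_hi = dpi(mu_lo), dpi(mu_hi)
    if d_lo * d_hi > 0:
        return CoexistenceResult(converged=False)
    mu_star = brentq(dpi, mu_lo, mu_hi, xtol=1e-15, rtol=8.9e-16)
    p1, p2 = phi_dilute(mu_star), phi_dense(mu_star)
    st1 = solve_internal(p1, params)
    st2 = solve_internal(p2, params)
    n1 = params.protein.n1
    return CoexistenceResult(
        phi_dilute=p1, phi_dense=p2,
        rho_dilute=phi_to_molar(p1, n1, params.units),
        rho_dense=phi_to_molar(p2, n1, params.units),
        p_dilute=st1.p, p_dense=st2.p,
        g_dilute=st1.bound_arg_per_atp(params),
        g_dense=st2.bound_arg_per_atp(params),
        mu=mu_star, converged=True,
        residual_mu=abs(mu_protein(p1, params, st1)
                        - mu_protein(p2, params, st2)),
        residual_pi=abs(dpi(mu_star)),
        state_dilute=st1, state_dense=st2,
    )


def critical_point(params: ModelParams, scan_axis: str,
                   bracket: tuple[float, float],
                   rtol: float = 1e-4) -> tuple[float, float]:
    """Locate loop closure along a scan axis by bisection.

    ``scan_axis`` is ``"eps1"`` (Tyr-Arg bond energy, k_B T) or ``"atp"``
    (reservoir ATP concentration, mol/L).  The bracket must contain the
    onset: coexistence on one side, none on the other.  Returns the
    critical scan value and the critical composition phi_c (argmin of the
    curvature at closure).
    """

    def at(value: float) -> ModelParams:
        if scan_axis == "eps1":
            from dataclasses import replace
            return replace(params, beta_eps1=value)
        if scan_axis == "atp":
            return params.with_reservoir_molar(value)
        raise ValueError("scan_axis must be 'eps1' or 'atp'")

    lo, hi = bracket
    f_lo = has_coexistence(at(lo))
    f_hi = has_coexistence(at(hi))
    if f_lo == f_hi:
        raise ValueError(
            f"bracket {bracket} does not straddle the coexistence onset")
    log_space = scan_axis == "atp"
    while (abs(hi - lo) > rtol * max(abs(lo), abs(hi))):
        mid = math.sqrt(lo * hi) if log_space else 0.5 * (lo + hi)
        if has_coexistence(at(mid)) == f_lo:
            lo = mid
        else:
            hi = mid
    value = math.sqrt(lo * hi) if log_space else 0.5 * (lo + hi)
    # critical composition: where the curvature is flattest at closure
    side = at(lo) if f_lo else at(hi)
    phis = np.geomspace(PHI_MIN, PHI_MAX, 200)
    curv = [_curvature(p, side) for p in phis]
    return value, float(phis[int(np.argmin(curv))])


def _row(scan_name: str, scan_value: float,
         cx: CoexistenceResult) -> dict[str, float | bool]:
    return {
        scan_name: scan_value,
        "phi_dilute": cx.phi_dilute, "phi_dense": cx.phi_dense,
        "rho_dilute": cx.rho_dilute, "rho_dense": cx.rho_dense,
        "p_dilute": cx.p_dilute, "p_dense": cx.p_dense,
        "g_dense": cx.g_dense, "converged": cx.converged,
    }


def scan_binding_energy(eps1_values, params: ModelParams) -> pd.DataFrame:
    """Binodal branches versus the Tyr-Arg bond energy (no ATP needed).

    One row per eps1 value; rows without coexistence carry NaN branches.
    """
    from dataclasses import replace

    rows = []
    for e1 in eps1_values:
        cx = solve_coexistence(replace(params, beta_eps1=float(e1)))
        rows.append(_row("beta_eps1", float(e1), cx))
    return pd.DataFrame(rows)


def scan_atp(c_values, params: ModelParams) -> pd.DataFrame:
    """Binodal branches versus reservoir ATP concentration (mol/L).

    Captures the reentrant shape for L >= 2 (dilute branch first falls,
    then rises until the loop closes) and the monotone dissolution for
    L = 1.
    """
    rows = []
    for c in c_values:
        cx = solve_coexistence(params.with_reservoir_molar(float(c)))
        rows.append(_row("c_atp", float(c), cx))
    return pd.DataFrame(rows)


def dissolution_concentration(params: ModelParams, c_lo: float = 1e-9,
                              c_hi: float = 0.1,
                              rtol: float = 1e-3) -> float:
    """Smallest reservoir ATP concentration (mol/L) dissolving the condensate.

    Defined as closure of the binodal loop: no composition pair with equal
    chemical potential and pressure, equivalently a convex free energy.
    Located by log-space bisection between a coexisting and a
    non-coexisting reservoir level.
    """
    if not has_coexistence(params.with_reservoir_molar(c_lo)):
        raise ValueError(f"no coexistence at the lower bracket {c_lo} M")
    if has_coexistence(params.with_reservoir_molar(c_hi)):
        raise ValueError(f"coexistence persists at the upper bracket {c_hi} M")
    while c_hi / c_lo > 1.0 + rtol:
        mid = math.sqrt(c_lo * c_hi)
        if has_coexistence(params.with_reservoir_molar(mid)):
            c_lo = mid
        else:
            c_hi = mid
    return math.sqrt(c_lo * c_hi)


def loop_area(scan: pd.DataFrame, log_coords: bool = True) -> float:
    """Area enclosed by a closed-loop binodal in the (c, rho) plane.

    Integrates the branch separation over the scan coordinate by the
    trapezoidal rule; with ``log_coords`` both axes are log10 (the natural
    scale for concentration loops spanning decades).
    """
    ok = scan[scan["converged"]]
    if len(ok) < 2:
        return 0.0
    x = np.asarray(ok["c_atp"], dtype=float)
    lo = np.asarray(ok["rho_dilute"], dtype=float)
    hi = np.asarray(ok["rho_dense"], dtype=float)
    if log_coords:
        x, lo, hi = np.log10(x), np.log10(lo), np.log10(hi)
    return float(np.trapezoid(hi - lo, x))


def asymmetric_loop_metrics(params_a: ModelParams, params_b: ModelParams,
                            c_values) -> dict:
    """Closed-loop binodal summaries for two sticker-asymmetric proteins.

    Returns the two scans, their enclosed loop areas (log10 and linear
    coordinates) and the dense-phase bound-Arg-per-ATP curves, for
    comparing a Tyr-rich (m1 > m2) against an Arg-rich (m1 < m2) chain.
    """
    out = {}
    for tag, prm in (("a", params_a), ("b", params_b)):
        scan = scan_atp(c_values, prm)
        out[f"scan_{tag}"] = scan
        out[f"area_log_{tag}"] = loop_area(scan, log_coords=True)
        out[f"area_lin_{tag}"] = loop_area(scan, log_coords=False)
        out[f"n_coexisting_{tag}"] = int(scan["converged"].sum())
    return out
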