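"""Free-energy functionals and self-consistent bond fractions.

The solution is an incompressible lattice mixture of multivalent protein
chains (N1 sites, m1 Tyr + m2 Arg stickers), solvent chains (N2 sites) and,
optionally, single-site ATP molecules exchanged with a reservoir at fixed
chemical potential.  Stickers form reversible bonds: Tyr-Arg (one-to-one,
energy beta_eps1) and ATP-Arg (one ATP binds up to L Arg, energy beta_eps2
per bond).  All free energies are dimensionless densities: beta F v / V,
i.e. per lattice site, with beta = 1.

The association free energy follows from the exact bond-counting partition
function

    Z = sum_{k,b} C(n_p m1, k) C(n_atp L, b) C(n_p m2, k+b) (k+b)!
                  (v/V)^(k+b) exp(-k beta_eps1 - b beta_eps2)

via a saddle-point (Stirling) evaluation in the bond numbers k and b.  The
resulting attachment terms carry the factor ln[(m2 phi / N1) e^(-1 -
beta_eps)]; the extra e^(-1) relative to a naive mass-action reading is
required for consistency with the exact finite-size enumeration, which is
provided here as :func:`exact_association_oracle` and used by the test
suite as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .params import ModelParams

__all__ = [
    "InternalState",
    "SystemComposition",
    "f_reference",
    "f_binding_pure",
    "solve_p_pure",
    "mu_atp_reservoir",
    "f_reference_atp",
    "f_binding_atp",
    "solve_internal",
    "f_total",
    "mu_protein",
    "exact_association_oracle",
]

_TINY = 1e-300


def _xlogx(x: float) -> float:
    """x * ln(x) extended continuously to x = 0."""
    return x * math.log(x) if x > 0.0 else 0.0


def _check_phi(phi: float) -> None:
    if not 0.0 < phi < 1.0:
        raise ValueError(f"phi must lie strictly in (0, 1); got {phi}")


@dataclass(frozen=True)
class InternalState:
    """Order parameters minimising the free energy at fixed composition.

    ``p`` is the fraction of Tyr residues engaged in Tyr-Arg bonds, ``q``
    the fraction of ATP binding sites occupied by Arg, and ``lam`` the
    number of ATP molecules per protein residue (lambda = n_ATP /
    (n_p N1)).  ``sigma`` is the derived fraction of Arg residues that
    remain free; feasibility requires ``sigma >= 0``.
    """

    p: float
    q: float
    lam: float
    boundary: bool = False   # lambda optimum at the packing boundary

    def sigma(self, params: ModelParams) -> float:
        pr = params.protein
        s = 1.0 - self.p * pr.m1 / pr.m2 if pr.m2 else 1.0
        if pr.m2 and self.lam > 0:
            s -= self.q * params.valence * self.lam * pr.n1 / pr.m2
        return s

    def bound_arg_per_atp(self, params: ModelParams) -> float:
        """g = L q, the mean number of Arg residues bound to one ATP."""
        return params.valence * self.q


@dataclass(frozen=True)
class SystemComposition:
    """Finite molecule counts for the enumeration oracle.

    The total volume is ``V = (n_p N1 + n_s N2 + n_atp) v`` by
    incompressibility.
    """

    n_p: int
    n_s: int
    n_atp: int = 0

    def __post_init__(self) -> None:
        if min(self.n_p, self.n_s, self.n_atp) < 0:
            raise ValueError("molecule counts must be non-negative")

    def total_sites(self, params: ModelParams) -> int:
        return (self.n_p * params.protein.n1 + self.n_s * params.n2
                + self.n_atp)

    def phi(self, params: ModelParams) -> float:
        return self.n_p * params.protein.n1 / self.total_sites(params)

    def lam(self, params: ModelParams) -> float:
        return self.n_atp / (self.n_p * params.protein.n1)


# ---------------------------------------------------------------------------
# ATP-free model
# ---------------------------------------------------------------------------

def f_reference(phi: float, params: ModelParams) -> float:
    """Mixing free energy of the bond-free reference solution.

    (phi/N1) ln phi + ((1-phi)/N2) ln(1-phi); the limits phi -> 0 and
    phi -> 1 are taken continuously (both are 0).
    """
    if phi in (0.0, 1.0):
        return 0.0
    _check_phi(phi)
    return (_xlogx(phi) / params.protein.n1
            + _xlogx(1.0 - phi) / params.n2)


def _attach(phi: float, params: ModelParams) -> float:
    """ln[(m2 phi / N1) e^(-1)]: the phi-dependent part of attachment."""
    pr = params.protein
    return math.log(pr.m2 * phi / pr.n1) - 1.0


def f_binding_pure(phi: float, p: float, params: ModelParams) -> float:
    """Tyr-Arg association free energy density at bond fraction ``p``.

    Saddle-point (Stirling) form of the exact bond-counting partition
    function; see the module docstring for the attachment-term convention.
    """
    _check_phi(phi)
    pr = params.protein
    if pr.m1 == 0 or pr.m2 == 0 or p == 0.0:
        if p == 0.0:
            return 0.0
        raise ValueError("p must be 0 when a sticker type is absent")
    if p < 0.0 or p > 1.0:
        raise ValueError("p must lie in [0, 1]")
    s = 1.0 - p * pr.m1 / pr.m2
    if s <= 0.0:
        raise ValueError("Arg budget exceeded: 1 - p m1/m2 <= 0")
    c1 = pr.m1 * phi / pr.n1
    c2 = pr.m2 * phi / pr.n1
    return (c1 * (_xlogx(p) + _xlogx(1.0 - p))
            + c2 * _xlogx(s)
            - p * c1 * (_attach(phi, params) - params.beta_eps1))


def solve_p_pure(phi: float, params: ModelParams) -> float:
    """Equilibrium Tyr-Arg bond fraction of the ATP-free solution.

    Solves the stationarity (mass-action) condition

        p / [(1-p)(1 - p m1/m2)] = (m2 phi / N1) exp(-beta_eps1)

    in closed form via the stable quadratic root.
    """
    if phi == 0.0:
        return 0.0
    _check_phi(phi)
    pr = params.protein
    if pr.m1 == 0 or pr.m2 == 0:
        return 0.0
    a1 = (pr.m2 * phi / pr.n1) * math.exp(-params.beta_eps1)
    r = pr.m1 / pr.m2
    # a1*r*p^2 - (1 + a1*(1+r))*p + a1 = 0; physical root is the smaller one
    b = 1.0 + a1 * (1.0 + r)
    disc = b * b - 4.0 * a1 * a1 * r
    return 2.0 * a1 / (b + math.sqrt(disc))


# ---------------------------------------------------------------------------
# ATP model (semi-grand ensemble)
# ---------------------------------------------------------------------------

def mu_atp_reservoir(phi_bar: float, params: ModelParams) -> float:
    """Chemical potential of ATP in a reservoir at volume fraction phi_bar.

    The reservoir is a binary ATP/solvent mixture:
    ln phi_bar - ln(1-phi_bar)/N2 - 1/N2 + 1 + chi (1 - 2 phi_bar).
    """
    if not 0.0 < phi_bar < 1.0:
        raise ValueError(f"phi_bar must lie strictly in (0, 1); got {phi_bar}")
    n2, chi = params.n2, params.chi
    return (math.log(phi_bar) - math.log(1.0 - phi_bar) / n2 - 1.0 / n2
            + 1.0 + chi * (1.0 - 2.0 * phi_bar))


def f_reference_atp(phi: float, lam: float, params: ModelParams) -> float:
    """Reference free energy of the protein/solvent/ATP mixture.

    Protein and solvent mixing entropy, ATP translational entropy, the
    chi-interaction of ATP with solvent, and the reservoir-exchange term
    -lam phi mu_ATP.  ``lam = 0`` recovers :func:`f_reference` exactly.
    """
    _check_phi(phi)
    if lam < 0.0:
        raise ValueError("lam must be non-negative")
    psi = 1.0 - phi - lam * phi
    if psi <= 0.0 and lam > 0.0:
        raise ValueError("ATP + protein volume fractions exceed the box")
    f = _xlogx(phi) / params.protein.n1 + _xlogx(psi) / params.n2
    if lam > 0.0:
        mu = mu_atp_reservoir(params.atp_reservoir_phi, params)
        f += (_xlogx(lam * phi) + params.chi * lam * phi * psi
              - lam * phi * mu)
    return f


def f_binding_atp(phi: float, lam: float, p: float, q: float,
                  params: ModelParams) -> float:
    """Joint Tyr-Arg / ATP-Arg association free energy density.

    Reduces exactly to :func:`f_binding_pure` at lam = 0 (or q = 0 with no
    ATP).  Raises when the Arg budget 1 - p m1/m2 - q L lam N1/m2 is
    exhausted.
    """
    _check_phi(phi)
    pr = params.protein
    if lam == 0.0 or q == 0.0:
        # unoccupied ATP contributes no association term
        return f_binding_pure(phi, p, params)
    if pr.m2 == 0:
        raise ValueError("ATP-Arg binding requires m2 > 0")
    sigma = (1.0 - p * pr.m1 / pr.m2
             - q * params.valence * lam * pr.n1 / pr.m2)
    if sigma <= 0.0:
        raise ValueError("Arg budget exceeded (sigma <= 0)")
    c1 = pr.m1 * phi / pr.n1
    c2 = pr.m2 * phi / pr.n1
    cq = params.valence * lam * phi
    att = _attach(phi, params)
    f = c2 * _xlogx(sigma) + cq * (_xlogx(q) + _xlogx(1.0 - q))
    f -= q * cq * (att - params.eps2)
    if pr.m1 > 0 and p > 0:
        f += c1 * (_xlogx(p) + _xlogx(1.0 - p))
        f -= p * c1 * (att - params.beta_eps1)
    return f


def _solve_pq(phi: float, lam: float, params: ModelParams
              ) -> tuple[float, float, float]:
    """Mass-action (p, q, sigma) at fixed phi and ATP loading lam.

    Both bond types draw on the same pool of free Arg; with sigma the free
    fraction, p = A1 sigma / (1 + A1 sigma) and q = A2 sigma /
    (1 + A2 sigma), and sigma solves the scalar Arg balance (monotone in
    sigma, hence a unique root).
    """
    pr = params.protein
    if pr.m2 == 0:
        return 0.0, 0.0, 1.0
    base = pr.m2 * phi / pr.n1
    a1 = base * math.exp(-params.beta_eps1) if pr.m1 else 0.0
    a2 = base * math.exp(-params.eps2) if lam > 0 else 0.0
    r1 = pr.m1 / pr.m2
    r2 = params.valence * lam * pr.n1 / pr.m2 if lam > 0 else 0.0

    def arg_balance(sigma: float) -> float:
        p = a1 * sigma / (1.0 + a1 * sigma)
        q = a2 * sigma / (1.0 + a2 * sigma)
        return sigma - 1.0 + r1 * p + r2 * q

    if arg_balance(1.0) <= 0.0:
        sigma = 1.0
    else:
        sigma = brentq(arg_balance, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16)
    p = a1 * sigma / (1.0 + a1 * sigma)
    q = a2 * sigma / (1.0 + a2 * sigma)
    return p, q, sigma


def _lambda_balance(phi: float, lam: float, mu: float,
                    params: ModelParams) -> float:
    """Residual of d f_tot / d lambda = 0 at the inner (p, q) optimum.

    Equals the local ATP exchange chemical potential minus the reservoir
    value:  ln(lam phi) + 1 - (ln psi + 1)/N2 + chi (1 - phi - 2 lam phi)
    + L ln(1 - q) - mu_ATP.
    """
    q = _solve_pq(phi, lam, params)[1]
    psi = 1.0 - phi - lam * phi
    return (math.log(max(lam * phi, _TINY)) + 1.0
            - (math.log(max(psi, _TINY)) + 1.0) / params.n2
            + params.chi * (1.0 - phi - 2.0 * lam * phi)
            + params.valence * math.log(max(1.0 - q, _TINY)) - mu)


def solve_internal(phi: float, params: ModelParams,
                   check_minimum: bool = False) -> InternalState:
    """Self-consistent internal state (p, q, lambda) at fixed phi.

    The bond fractions follow from the shared-Arg mass-action balance; the
    ATP loading lambda equates the local and reservoir ATP chemical
    potentials.  When several stationary lambda exist the one with the
    lowest total free energy is returned; if the local potential stays
    below the reservoir value everywhere the optimum sits at the packing
    boundary (box filled with ATP).

    With ``check_minimum`` the Hessian of the free energy in the internal
    variables is verified positive definite by finite differences.
    """
    _check_phi(phi)
    if params.atp_reservoir_phi == 0.0:
        state = InternalState(p=solve_p_pure(phi, params), q=0.0, lam=0.0)
        if check_minimum:
            _verify_minimum(phi, state, params)
        return state
    mu = mu_atp_reservoir(params.atp_reservoir_phi, params)
    lam_max = (1.0 - phi) / phi * (1.0 - 1e-10)
    lam_lo = min(1e-12 / phi, lam_max * 1e-8)
    roots: list[tuple[float, bool]] = []
    if _lambda_balance(phi, lam_lo, mu, params) > 0.0:
        roots.append((lam_lo, True))
    else:
        grid = np.geomspace(lam_lo, lam_max, 48)
        vals = [_lambda_balance(phi, g, mu, params) for g in grid]
        for i in range(len(grid) - 1):
            if vals[i] < 0.0 <= vals[i + 1] or vals[i] >= 0.0 > vals[i + 1]:
                roots.append((
                    brentq(lambda l: _lambda_balance(phi, l, mu, params),
                           grid[i], grid[i + 1], xtol=1e-16, rtol=8.9e-16),
                    False))
        if not roots:
            roots.append((lam_max, True))  # boundary optimum
    best: tuple[float, InternalState] | None = None
    for lam, at_boundary in roots:
        p, q, _ = _solve_pq(phi, lam, params)
        st = InternalState(p=p, q=q, lam=lam, boundary=at_boundary)
        f = f_reference_atp(phi, lam, params) + f_binding_atp(phi, lam, p, q,
                                                              params)
        if best is None or f < best[0]:
            best = (f, st)
    assert best is not None
    if check_minimum:
        _verify_minimum(phi, best[1], params)
    return best[1]


def _f_at(phi: float, state: InternalState, params: ModelParams) -> float:
    return (f_reference_atp(phi, state.lam, params)
            + f_binding_atp(phi, state.lam, state.p, state.q, params))


def _verify_minimum(phi: float, state: InternalState,
                    params: ModelParams) -> None:
    """Finite-difference check that the stationary point is a minimum."""
    vars0 = [state.p, state.q, state.lam]
    active = [i for i, v in enumerate(vars0) if v > 1e-12]

    def f_of(vec: list[float]) -> float:
        return (f_reference_atp(phi, vec[2], params)
                + f_binding_atp(phi, vec[2], vec[0], vec[1], params))

    h = 1e-6
    hess = np.zeros((len(active), len(active)))
    for a, i in enumerate(active):
        for b_, j in enumerate(active):
            for si, sj, w in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                v = list(vars0)
                v[i] += si * h * max(vars0[i], 1e-3)
                v[j] += sj * h * max(vars0[j], 1e-3)
                hess[a, b_] += w * f_of(v)
            hess[a, b_] /= (2 * h * max(vars0[i], 1e-3)) * \
                           (2 * h * max(vars0[j], 1e-3))
    if active and np.linalg.eigvalsh(hess).min() <= 0:
        raise ArithmeticError(
            f"stationary point at phi={phi} is not a minimum")


def f_total(phi: float, params: ModelParams,
            return_state: bool = False):
    """Total free-energy density at the internal optimum.

    Returns ``f`` or ``(f, InternalState)``.  With an empty reservoir this
    equals f_reference + f_binding_pure at the mass-action p.
    """
    state = solve_internal(phi, params)
    f = _f_at(phi, state, params)
    if return_state:
        return f, state
    return f


def mu_protein(phi: float, params: ModelParams,
               state: InternalState | None = None) -> float:
    """Exchange chemical potential d f_total / d phi (per lattice site).

    By the envelope theorem the total derivative equals the partial
    derivative with respect to phi at the inner optimum.  The terms
    proportional to lambda are combined analytically with the stationarity
    condition d f/d lambda = 0 before evaluation: lambda diverges like
    1/phi in the dilute limit at fixed reservoir, and the naive term-by-
    term sum would cancel catastrophically there.  What survives is

        mu = mu_pure_like(phi, p) - chi lam phi + L (lam q) ln sigma,

    all of whose factors stay O(1).  When the lambda optimum sits on the
    packing boundary the stationarity residual is not zero and its
    contribution along the boundary is added explicitly.
    """
    _check_phi(phi)
    if state is None:
        state = solve_internal(phi, params)
    pr = params.protein
    p, q, lam = state.p, state.q, state.lam
    psi = 1.0 - phi - lam * phi
    sigma = state.sigma(params)
    d = ((math.log(phi) + 1.0) / pr.n1
         - (math.log(max(psi, _TINY)) + 1.0) / params.n2)
    if pr.m1 and pr.m2 and p > 0.0:
        att = _attach(phi, params)
        d += (pr.m1 / pr.n1) * (_xlogx(p) + _xlogx(1.0 - p))
        d -= p * (pr.m1 / pr.n1) * (att - params.beta_eps1 + 1.0)
    if pr.m2:
        d += (pr.m2 / pr.n1) * _xlogx(sigma)
    if lam > 0.0:
        d += (-params.chi * lam * phi
              + params.valence * (lam * q) * math.log(max(sigma, _TINY)))
        if state.boundary:
            mu_res = mu_atp_reservoir(params.atp_reservoir_phi, params)
            d -= _lambda_balance(phi, lam, mu_res, params) / phi
    return d


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

def exact_association_oracle(comp: SystemComposition, params: ModelParams,
                             max_terms: int = 2_000_000) -> float:
    """Association free-energy density by direct partition-function summation.

    Evaluates -(v/V) ln Z with Z summed exactly over all bond numbers
    (k, b); no Stirling approximation.  Used as the independent reference
    for :func:`f_binding_pure` / :func:`f_binding_atp`, whose saddle-point
    values it must approach as the composition is scaled up at fixed
    volume fractions.
    """
    pr = params.protein
    m1_tot = comp.n_p * pr.m1
    m2_tot = comp.n_p * pr.m2
    sites_tot = comp.n_atp * params.valence
    total = comp.total_sites(params)
    k_max = min(m1_tot, m2_tot)
    b_max = min(sites_tot, m2_tot)
    n_terms = (k_max + 1) * (b_max + 1)
    if n_terms > max_terms:
        raise ValueError(
            f"enumeration would need {n_terms} terms (> {max_terms})")
    k = np.arange(k_max + 1)[:, None]
    b = np.arange(b_max + 1)[None, :]
    kb = k + b
    log_v_over_V = -math.log(total)

    def log_binom(n: int, j: np.ndarray) -> np.ndarray:
        out = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        return np.where(j <= n, out, -np.inf)

    terms = (log_binom(m1_tot, k) + log_binom(sites_tot, b)
             + log_binom(m2_tot, kb) + gammaln(kb + 1)
             + kb * log_v_over_V
             - k * params.beta_eps1 - b * params.eps2)
    terms = np.where(kb <= m2_tot, terms, -np.inf)
    ln_z = logsumexp(terms)
    return -float(ln_z) / total
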