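"""Coarse-grained Langevin slab simulation of sticker-spacer chains + ATP.

Protein chains are bead-spring polymers (one bead per coarse residue,
harmonic bonds) carrying three bead types: Tyr stickers, Arg stickers and
non-interacting spacers; ATP is a single free bead.  Three potentials act:

* harmonic bonds           U_b(r) = k (r - r_b)^2,  k = 20 eps0 / r_b^2
* sticker attraction       U_a(r) = U0 (1 + cos(pi r / r0)),  r < r0
  with U0 = -20 eps0 for Tyr-Arg and U0 = -75 eps0 for ATP-Arg
* softened, truncated LJ   U_r(r) = 4 eps lam [((1-lam)^2 + (r/sigma)^6)^-2
                                    - ((1-lam)^2 + (r/sigma)^6)^-1],  r < r_c

The repulsive potential is shifted by -U_r(r_c) so the energy is
continuous at the cutoff (forces are unaffected).  Energies are in the
reduced unit eps0, lengths in nm.  The thermostat temperature is given in
eps0; the default mapping is k_B T = 10 eps0, which places the Tyr-Arg
well at 2 k_B T and the ATP-Arg well at 7.5 k_B T — the same per-contact
strengths the mean-field theory uses — so sticker bonds are reversible on
simulation timescales.

Coexistence is sampled with the slab geometry: chains start in a dense
slab spanning the short axes of an elongated periodic box, so the dense
phase, the dilute phase and their interface all appear along the long
axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CGForceField",
    "CGConfig",
    "CGSystem",
    "Trajectory",
    "pair_energy_force",
    "build_slab_system",
    "run_langevin",
    "density_profile",
    "exchange_statistics",
    "write_xyz",
]

NEUTRAL, TYR, ARG, ATP = 0, 1, 2, 3
_TYPE_LETTERS = {NEUTRAL: "N", TYR: "Y", ARG: "R", ATP: "A"}


@dataclass(frozen=True)
class CGForceField:
    """Potential parameters (energies in eps0, lengths in nm)."""

    r_b: float = 4.5          # mean bond length
    r0: float = 2.0           # sticker attraction range
    u0_tyr_arg: float = -20.0
    u0_atp_arg: float = -75.0
    lambda_lj: float = 0.68   # LJ softening
    sigma: float = 3.5
    r_c: float = 5.0          # repulsion cutoff
    eps_tyr: float = 0.621
    eps_arg: float = 0.15
    eps_neutral: float = 0.0   # spacers are non-interacting
    eps_atp: float = 0.15      # ATP repulsion scale (not printed; = Arg)

    @property
    def k_bond(self) -> float:
        return 20.0 / self.r_b**2

    def eps_of_type(self, t: int) -> float:
        return (self.eps_neutral, self.eps_tyr, self.eps_arg,
                self.eps_atp)[t]

    def pair_eps(self) -> np.ndarray:
        """Per-type-pair repulsion scale.

        The softened LJ acts between beads of the same type only (it is
        there to prevent same-type aggregation); sticker cross-pairs
        interact through the attraction alone and spacers are phantom.
        A repulsion between cross pairs at the combined scale would
        overwhelm the -40 eps0 contact attraction and suppress phase
        separation altogether.
        """
        e = np.array([self.eps_of_type(t) for t in range(4)])
        return np.diag(e)

    def pair_u0(self) -> np.ndarray:
        """Per-type-pair attraction depth (0 where no attraction acts)."""
        u0 = np.zeros((4, 4))
        u0[TYR, ARG] = u0[ARG, TYR] = self.u0_tyr_arg
        u0[ATP, ARG] = u0[ARG, ATP] = self.u0_atp_arg
        return u0

    def repulsion_shift(self, eps: float | np.ndarray):
        """-U_r(r_c): the constant added so the energy vanishes at r_c."""
        t = (1.0 - self.lambda_lj) ** 2 + (self.r_c / self.sigma) ** 6
        return -4.0 * eps * self.lambda_lj * (t**-2 - t**-1)


def pair_energy_force(kind: str, r, ff: CGForceField, *,
                      u0: float | None = None, eps: float | None = None):
    """Energy and radial force (positive = repulsive) of one interaction.

    ``kind`` is ``bond``, ``sticker_attraction`` (depth ``u0``, default
    Tyr-Arg) or ``soft_repulsion`` (scale ``eps``, default Tyr).  Accepts
    scalar or array ``r``; all forms are finite at r = 0.
    """
    r = np.asarray(r, dtype=float)
    if kind == "bond":
        e = ff.k_bond * (r - ff.r_b) ** 2
        f = -2.0 * ff.k_bond * (r - ff.r_b)
    elif kind == "sticker_attraction":
        u0 = ff.u0_tyr_arg if u0 is None else u0
        inside = r < ff.r0
        e = np.where(inside, u0 * (1.0 + np.cos(np.pi * r / ff.r0)), 0.0)
        f = np.where(inside,
                     u0 * (np.pi / ff.r0) * np.sin(np.pi * r / ff.r0), 0.0)
    elif kind == "soft_repulsion":
        eps = ff.eps_tyr if eps is None else eps
        lam = ff.lambda_lj
        t = (1.0 - lam) ** 2 + (r / ff.sigma) ** 6
        inside = r < ff.r_c
        e = np.where(inside,
                     4.0 * eps * lam * (t**-2 - t**-1)
                     + ff.repulsion_shift(eps), 0.0)
        dudr = 4.0 * eps * lam * (-2.0 * t**-3 + t**-2) \
            * 6.0 * r**5 / ff.sigma**6
        f = np.where(inside, -dudr, 0.0)
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")
    if e.ndim == 0:
        return float(e), float(f)
    return e, f


@dataclass(frozen=True)
class CGConfig:
    """Run configuration: system geometry and composition."""

    n_chains: int = 50
    chain_length: int = 50
    sticker_fraction: float = 0.06
    n_atp: int = 0
    box: tuple[float, float, float] = (50.0, 50.0, 250.0)
    slab_width: float = 50.0      # initial slab extent along the long axis
    sticker_placement: str = "random"   # or "even"
    forcefield: CGForceField = field(default_factory=CGForceField)


@dataclass
class CGSystem:
    """Bead coordinates, types, bonds and chain bookkeeping."""

    positions: np.ndarray         # (N, 3) nm
    types: np.ndarray             # (N,) int codes
    bonds: np.ndarray             # (Nb, 2) bead indices
    chain_id: np.ndarray          # (N,) chain index, -1 for ATP
    box: np.ndarray               # (3,)
    config: CGConfig

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return self.config.n_chains


@dataclass
class Trajectory:
    """Sampled frames of a Langevin run (times strictly increasing)."""

    times: np.ndarray             # (F,) in simulation time units
    positions: np.ndarray         # (F, N, 3)
    system: CGSystem


def _sticker_types(chain_length: int, fraction: float, placement: str,
                   rng: np.random.Generator) -> np.ndarray:
    n_per = round(fraction * chain_length)
    types = np.full(chain_length, NEUTRAL)
    if n_per == 0:
        return types
    if placement == "even":
        idx = np.linspace(0, chain_length - 1, 2 * n_per).round().astype(int)
    elif placement == "random":
        idx = rng.choice(chain_length, size=2 * n_per, replace=False)
    else:
        raise ValueError("sticker_placement must be 'random' or 'even'")
    types[idx[:n_per]] = TYR
    types[idx[n_per:]] = ARG
    return types


def build_slab_system(config: CGConfig, seed: int) -> CGSystem:
    """Initial configuration: chains in a central slab, ATP spread uniformly.

    Chains are grown as random walks of step r_b confined to the slab
    (periodic in the short axes); fully deterministic for a given seed.
    """
    ff = config.forcefield
    box = np.asarray(config.box, dtype=float)
    n_beads = config.n_chains * config.chain_length + config.n_atp
    # crude packing feasibility: beads at soft-core size must fit the slab
    slab_volume = box[0] * box[1] * min(config.slab_width, box[2])
    if config.n_chains * config.chain_length * 1.0 > slab_volume:
        raise ValueError("slab too small for the requested chains")
    rng = np.random.default_rng(seed)
    z_mid = box[2] / 2.0
    z_lo, z_hi = z_mid - config.slab_width / 2, z_mid + config.slab_width / 2
    positions = np.empty((n_beads, 3))
    types = np.empty(n_beads, dtype=int)
    chain_id = np.full(n_beads, -1, dtype=int)
    bonds = []
    i = 0
    for c in range(config.n_chains):
        types[i:i + config.chain_length] = _sticker_types(
            config.chain_length, config.sticker_fraction,
            config.sticker_placement, rng)
        pos = np.empty((config.chain_length, 3))
        pos[0] = [rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                  rng.uniform(z_lo, z_hi)]
        for b in range(1, config.chain_length):
            step = rng.normal(size=3)
            step *= ff.r_b / np.linalg.norm(step)
            nxt = pos[b - 1] + step
            nxt[2] = np.clip(nxt[2], z_lo, z_hi)   # keep the walk in the slab
            pos[b] = nxt
            bonds.append((i + b - 1, i + b))
        positions[i:i + config.chain_length] = pos
        chain_id[i:i + config.chain_length] = c
        i += config.chain_length
    if config.n_atp:
        positions[i:] = rng.uniform(0, 1, size=(config.n_atp, 3)) * box
        types[i:] = ATP
    positions %= box
    return CGSystem(positions=positions, types=types,
                    bonds=np.array(bonds, dtype=int).reshape(-1, 2),
                    chain_id=chain_id, box=box, config=config)


def _pair_tables(system: CGSystem):
    ff = system.config.forcefield
    iu, ju = np.triu_indices(system.n_beads, 1)
    t_i, t_j = system.types[iu], system.types[ju]
    eps_ij = ff.pair_eps()[t_i, t_j]
    u0_ij = ff.pair_u0()[t_i, t_j]
    bonded = np.zeros(len(iu), dtype=bool)
    if len(system.bonds):
        # direct neighbours interact through the bond term only
        n = system.n_beads
        keys = iu.astype(np.int64) * n + ju
        bond_keys = (np.minimum(system.bonds[:, 0], system.bonds[:, 1])
                     .astype(np.int64) * n
                     + np.maximum(system.bonds[:, 0], system.bonds[:, 1]))
        bonded = np.isin(keys, bond_keys)
    return iu, ju, eps_ij, u0_ij, bonded


def _forces_loop(positions, iu, ju, eps_ij, u0_ij, bonded, bonds, box,
                 lam, sigma, r_c, r0, k_bond, r_b, shift_unit):
    """Pair-loop force/energy kernel (numba-compiled when available)."""
    n = positions.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    sigma6 = sigma**6
    one_m_lam2 = (1.0 - lam) ** 2
    for m in range(len(iu)):
        if bonded[m]:
            continue
        i, j = iu[m], ju[m]
        dx = positions[i, 0] - positions[j, 0]
        dy = positions[i, 1] - positions[j, 1]
        dz = positions[i, 2] - positions[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r_c * r_c:
            continue
        r = math.sqrt(r2)
        fmag = 0.0
        t = one_m_lam2 + r2 * r2 * r2 / sigma6
        e = eps_ij[m]
        fmag -= 4.0 * e * lam * (-2.0 / t**3 + 1.0 / t**2) \
            * 6.0 * r2 * r2 * r / sigma6
        energy += 4.0 * e * lam * (1.0 / t**2 - 1.0 / t) + e * shift_unit
        if u0_ij[m] != 0.0 and r < r0:
            u0 = u0_ij[m]
            fmag += u0 * (math.pi / r0) * math.sin(math.pi * r / r0)
            energy += u0 * (1.0 + math.cos(math.pi * r / r0))
        if r > 1e-12:
            fx, fy, fz = fmag * dx / r, fmag * dy / r, fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    for m in range(len(bonds)):
        i, j = bonds[m, 0], bonds[m, 1]
        dx = positions[i, 0] - positions[j, 0]
        dy = positions[i, 1] - positions[j, 1]
        dz = positions[i, 2] - positions[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        fb = -2.0 * k_bond * (r - r_b)
        energy += k_bond * (r - r_b) ** 2
        if r > 1e-12:
            fx, fy, fz = fb * dx / r, fb * dy / r, fb * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return forces, energy


try:                                   # optional acceleration
    from numba import njit

    _forces_loop = njit(cache=False)(_forces_loop)
except ImportError:                    # pragma: no cover - numba installed
    pass


def compute_forces(positions: np.ndarray, system: CGSystem,
                   tables=None, return_energy: bool = False):
    """Total forces (and optionally energy) under minimum-image convention."""
    ff = system.config.forcefield
    if tables is None:
        tables = _pair_tables(system)
    iu, ju, eps_ij, u0_ij, bonded = tables
    # per-unit-eps energy shift so U_r is continuous at the cutoff
    shift_unit = float(ff.repulsion_shift(1.0))
    forces, energy = _forces_loop(
        positions, iu, ju, eps_ij, u0_ij, bonded,
        system.bonds.astype(np.int64), system.box.astype(float),
        ff.lambda_lj, ff.sigma, ff.r_c, ff.r0, ff.k_bond, ff.r_b,
        shift_unit)
    if return_energy:
        return forces, float(energy)
    return forces


def total_energy(positions: np.ndarray, system: CGSystem) -> float:
    return compute_forces(positions, system, return_energy=True)[1]


def run_langevin(system: CGSystem, dt: float, n_steps: int,
                 temperature: float = 10.0, friction: float = 1.0,
                 seed: int = 0, sample_every: int = 100) -> Trajectory:
    """BAOAB Langevin dynamics in the NVT ensemble.

    ``temperature`` is k_B T in eps0 (default 10, i.e. the Tyr-Arg well is
    2 k_B T); ``friction`` in inverse reduced time; bead mass is 1.
    Trajectories are bit-reproducible for a given seed.  Raises on
    non-finite coordinates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    pos = system.positions.copy()
    vel = np.zeros_like(pos)
    tables = _pair_tables(system)
    forces = compute_forces(pos, system, tables)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(temperature * (1.0 - c1 * c1))
    frames = [pos.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * forces
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.standard_normal(pos.shape)
        pos += 0.5 * dt * vel
        pos %= system.box
        forces = compute_forces(pos, system, tables)
        if not np.isfinite(forces).all() or not np.isfinite(pos).all():
            raise FloatingPointError(
                f"non-finite coordinates/forces at step {step}")
        vel += 0.5 * dt * forces
        if step % sample_every == 0:
            frames.append(pos.copy())
            times.append(step * dt)
    return Trajectory(times=np.array(times), positions=np.array(frames),
                      system=system)


def density_profile(traj: Trajectory, axis: int = 2, n_bins: int = 50,
                    skip_frames: int = 0, bead_mask: np.ndarray | None = None):
    """Time-averaged bead density along one axis, with condensate bounds.

    The condensate is the contiguous region (periodic-aware) around the
    density maximum where the density exceeds half the plateau (the
    maximum of the averaged profile).  ``bead_mask`` restricts the count
    (e.g. to protein beads only).  Returns ``(centers, profile, (lo, hi),
    rho_dense, rho_dilute)``; raises if no dense region stands out from
    the mean (uniform system).
    """
    box = traj.system.box
    length = box[axis]
    pos = traj.positions[skip_frames:]
    if len(pos) == 0:
        raise ValueError("no frames after skip")
    hist = np.zeros(n_bins)
    edges = np.linspace(0.0, length, n_bins + 1)
    for frame in pos:
        z = frame[:, axis] if bead_mask is None else frame[bead_mask, axis]
        hist += np.histogram(z % length, bins=edges)[0]
    volume_bin = np.prod(np.delete(box, axis)) * (length / n_bins)
    profile = hist / (len(pos) * volume_bin)
    centers = 0.5 * (edges[:-1] + edges[1:])
    plateau = profile.max()
    if plateau < 2.0 * profile.mean():
        raise ValueError("no condensate detected: profile nearly uniform")
    half = 0.5 * plateau
    peak = int(np.argmax(profile))
    lo_i = peak
    while profile[(lo_i - 1) % n_bins] >= half and lo_i > peak - n_bins:
        lo_i -= 1
    hi_i = peak
    while profile[(hi_i + 1) % n_bins] >= half and hi_i < peak + n_bins:
        hi_i += 1
    in_mask = np.zeros(n_bins, dtype=bool)
    for idx in range(lo_i, hi_i + 1):
        in_mask[idx % n_bins] = True
    rho_dense = profile[in_mask].mean()
    rho_dilute = profile[~in_mask].mean() if (~in_mask).any() else 0.0
    lo_z = centers[lo_i % n_bins] - 0.5 * length / n_bins
    hi_z = centers[hi_i % n_bins] + 0.5 * length / n_bins
    return centers, profile, (lo_z % length, hi_z % length), \
        rho_dense, rho_dilute


def _chain_inside(frame: np.ndarray, system: CGSystem, bounds,
                  axis: int = 2, pad: float = 0.0) -> np.ndarray:
    """Per-chain flag: at least half the beads within the (padded) bounds."""
    lo, hi = bounds
    length = system.box[axis]
    z = frame[:, axis] % length
    lo_p, hi_p = (lo - pad) % length, (hi + pad) % length
    if lo_p <= hi_p:
        inside_bead = (z >= lo_p) & (z <= hi_p)
    else:                                   # condensate wraps the boundary
        inside_bead = (z >= lo_p) | (z <= hi_p)
    n_chains = system.n_chains
    counts = np.bincount(system.chain_id[system.chain_id >= 0],
                         weights=inside_bead[system.chain_id >= 0],
                         minlength=n_chains)
    chain_lengths = np.bincount(system.chain_id[system.chain_id >= 0],
                                minlength=n_chains)
    return counts >= 0.5 * chain_lengths


@dataclass
class ExchangeStats:
    events_per_chain: np.ndarray
    total_events: int
    n_exchanging_chains: int
    inside_flags: np.ndarray       # (F, n_chains) debounced occupancy


def exchange_statistics(traj: Trajectory, bounds, axis: int = 2,
                        dwell: int = 5,
                        hysteresis: float = 1.0) -> ExchangeStats:
    """Count inside<->outside condensate transitions per chain.

    A chain is inside when at least half its beads lie within the bounds;
    a state flip must persist for ``dwell`` sampled frames to count as an
    exchange event, and the bounds are widened by ``hysteresis`` (nm) for
    chains currently inside, suppressing boundary flicker.
    """
    n_chains = traj.system.n_chains
    n_frames = len(traj.positions)
    raw_in = np.empty((n_frames, n_chains), dtype=bool)
    raw_in_pad = np.empty((n_frames, n_chains), dtype=bool)
    for f, frame in enumerate(traj.positions):
        raw_in[f] = _chain_inside(frame, traj.system, bounds, axis, 0.0)
        raw_in_pad[f] = _chain_inside(frame, traj.system, bounds, axis,
                                      hysteresis)
    state = raw_in[0].copy()
    flags = np.empty_like(raw_in)
    flags[0] = state
    events = np.zeros(n_chains, dtype=int)
    pending = np.zeros(n_chains, dtype=int)   # consecutive frames flipped
    for f in range(1, n_frames):
        observed = np.where(state, raw_in_pad[f], raw_in[f])
        flipped = observed != state
        pending = np.where(flipped, pending + 1, 0)
        commit = pending >= dwell
        events += commit
        state = np.where(commit, ~state, state)
        pending = np.where(commit, 0, pending)
        flags[f] = state
    return ExchangeStats(events_per_chain=events,
                         total_events=int(events.sum()),
                         n_exchanging_chains=int((events > 0).sum()),
                         inside_flags=flags)


def write_xyz(traj: Trajectory, path: str | Path,
              sidecar: bool = True) -> None:
    """Write the trajectory as typed XYZ plus a JSON metadata sidecar."""
    path = Path(path)
    letters = [_TYPE_LETTERS[t] for t in traj.system.types]
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.positions):
            fh.write(f"{len(frame)}\n")
            fh.write(f"time={t:.6g}\n")
            for letter, (x, y, z) in zip(letters, frame):
                fh.write(f"{letter} {x:.4f} {y:.4f} {z:.4f}\n")
    if sidecar:
        cfg = asdict(traj.system.config)
        meta = {"box": list(map(float, traj.system.box)),
                "n_frames": len(traj.times), "config": cfg}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
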