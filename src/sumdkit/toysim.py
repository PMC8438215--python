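"""Coarse-grained dynamics backend: bead receptor with a planted binding funnel.

The backend stands in for an external MD engine so the supervision algorithm
and the analysis chain can be exercised end to end on one CPU. It provides

* a bead-model receptor (fixed by default, optionally harmonically
  restrained) whose surface carries one deep "orthosteric" patch and any
  number of shallower decoy (metastable) patches;
* a small flexible bead ligand held together by harmonic bonds;
* a pairwise Lennard-Jones + Coulomb energy model with a
  distance-dependent dielectric and force-shifted truncation at the cutoff,
  so both energy and force are continuous (and zero) at the cutoff;
* BAOAB-discretized Langevin dynamics with counter-based seeding, giving
  bitwise-reproducible trajectories per (seed, chunk) stream.

Units: Å, ps, amu, kcal/mol, elementary charges, Kelvin. There is no
explicit solvent and no periodicity: solvent effects are folded into the
Langevin friction and the distance-dependent dielectric, and a flat-bottom
spherical wall plays the role of the simulation box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .core import AtomSelection, StructureModel, Trajectory

KB = 0.0019872041          # kcal/mol/K
F_CONV = 418.4             # kcal/mol -> amu Å²/ps²
COULOMB_K = 332.0636       # kcal Å / (mol e²), vacuum


class InvalidSpecError(ValueError):
    """Toy-system specification violates a build-time invariant."""


class PlacementError(RuntimeError):
    """No clash-free ligand placement found within the retry budget."""


class IntegrationError(RuntimeError):
    """Dynamics produced a non-finite force (typically overlapping beads)."""


class SingularEnergyError(ValueError):
    """Pair distance below 1e-6 Å; the point-charge/LJ energy is singular."""


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

@dataclass
class EnergyModel:
    """Pairwise LJ + Coulomb with distance-dependent dielectric.

    The dielectric is eps(r) = dielectric_slope * r, so the Coulomb term
    falls off as 1/r². Both terms are truncated at ``cutoff`` with a
    force-shift (V(r) - V(rc) - (r - rc) V'(rc)), which keeps energy *and*
    force continuous at the cutoff.
    """

    cutoff: float = 9.0             # Å; matches a common LJ cutoff choice
    dielectric_slope: float = 4.0   # eps(r) = slope * r


def _pair_param_block(
    sig_i, eps_i, q_i, sig_j, eps_j, q_j, model: EnergyModel
) -> np.ndarray:
    """Precompute per-pair (sigma, epsilon, coulomb_k, V(rc), V'(rc)).

    Lorentz-Berthelot mixing. Returned array has shape (n_i, n_j, 5).
    """
    sig = 0.5 * (np.add.outer(sig_i, sig_j))
    eps = np.sqrt(np.multiply.outer(eps_i, eps_j))
    cq = COULOMB_K * np.multiply.outer(q_i, q_j) / model.dielectric_slope
    rc = model.cutoff
    if np.isinf(rc):
        vc = np.zeros_like(sig)
        dvc = np.zeros_like(sig)
    else:
        sr6 = (sig / rc) ** 6
        vc = 4.0 * eps * (sr6 * sr6 - sr6) + cq / rc**2
        dvc = -24.0 * eps / rc * (2.0 * sr6 * sr6 - sr6) - 2.0 * cq / rc**3
    out = np.empty(sig.shape + (5,))
    out[..., 0] = sig
    out[..., 1] = eps
    out[..., 2] = cq
    out[..., 3] = vc
    out[..., 4] = dvc
    return out


def _np_pair_energy_forces(
    x_i: np.ndarray, x_j: np.ndarray, par: np.ndarray, rc: float,
    active: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Reference (numpy) pair energy and forces between two bead sets.

    Returns (energy, forces_on_i, forces_on_j). ``active`` masks pairs in.
    Raises :class:`SingularEnergyError` below 1e-6 Å separation.
    """
    disp = x_i[:, None, :] - x_j[None, :, :]
    r2 = (disp**2).sum(axis=2)
    if active is None:
        active = np.ones(r2.shape, dtype=bool)
    within = active & (r2 < rc * rc)
    if np.any(within & (r2 < 1e-12)):
        ii, jj = np.argwhere(within & (r2 < 1e-12))[0]
        raise SingularEnergyError(f"beads {ii} and {jj} closer than 1e-6 Å")
    r = np.sqrt(np.where(within, r2, 1.0))
    sig, eps, cq, vc, dvc = (par[..., k] for k in range(5))
    sr6 = (sig * sig / np.where(within, r2, 1.0)) ** 3
    v = 4.0 * eps * (sr6 * sr6 - sr6) + cq / r**2
    if not np.isinf(rc):
        v = v - vc - (r - rc) * dvc
    g = 24.0 * eps / r * (2.0 * sr6 * sr6 - sr6) + 2.0 * cq / r**3 + dvc
    v = np.where(within, v, 0.0)
    g = np.where(within, g, 0.0)
    fvec = (g / r)[..., None] * disp
    return float(v.sum()), fvec.sum(axis=1), -fvec.sum(axis=0)


# ---------------------------------------------------------------------------
# System specification
# ---------------------------------------------------------------------------

@dataclass
class ToySystemSpec:
    """A complete coarse-grained receptor–ligand system.

    Atom ordering everywhere is receptor beads first, then ligand beads.
    The receptor is fixed unless ``receptor_restraint_k`` is set, in which
    case its beads move under harmonic tethers to their build positions.
    """

    receptor_coords: np.ndarray
    receptor_sigma: np.ndarray
    receptor_epsilon: np.ndarray
    receptor_charge: np.ndarray
    ligand_sigma: np.ndarray
    ligand_epsilon: np.ndarray
    ligand_charge: np.ndarray
    ligand_mass: np.ndarray
    bonds: np.ndarray                 # (n_bonds, 2) ligand-bead indices
    bond_r0: np.ndarray
    bond_k: np.ndarray
    site_center: np.ndarray
    site_beads: np.ndarray            # receptor bead indices
    bound_pose: np.ndarray            # (n_ligand, 3) planted energy minimum
    decoy_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    decoy_beads: tuple = ()
    decoy_poses: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 3)))
    decoy_depths: tuple = ()
    temperature: float = 310.0        # K
    friction: float = 0.1             # ps^-1 (thermostat-style damping)
    timestep: float = 0.002           # ps
    receptor_restraint_k: float | None = None   # kcal/mol/Å², None = fixed
    receptor_mass: float = 50.0
    wall_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    wall_radius: float = 100.0        # Å flat-bottom sphere confining the ligand
    wall_k: float = 2.0               # kcal/mol/Å² beyond the wall
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("receptor_coords", "receptor_sigma", "receptor_epsilon",
                     "receptor_charge", "ligand_sigma", "ligand_epsilon",
                     "ligand_charge", "ligand_mass", "bond_r0", "bond_k",
                     "site_center", "site_beads", "bound_pose",
                     "decoy_centers", "wall_center"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.site_beads = np.asarray(self.site_beads, dtype=np.int64)
        self.decoy_beads = tuple(np.asarray(b, dtype=np.int64) for b in self.decoy_beads)
        self.decoy_poses = np.asarray(self.decoy_poses, dtype=float)
        if self.n_receptor < 1 or self.n_ligand < 1:
            raise InvalidSpecError("need at least one receptor and one ligand bead")
        if self.timestep <= 0:
            raise InvalidSpecError("timestep must be > 0")

    # -- sizes & ordering ---------------------------------------------------

    @property
    def n_receptor(self) -> int:
        return self.receptor_coords.shape[0]

    @property
    def n_ligand(self) -> int:
        return self.ligand_sigma.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.n_receptor + self.n_ligand

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.arange(self.n_receptor, self.n_atoms)

    @property
    def mobile_indices(self) -> np.ndarray:
        if self.receptor_restraint_k is None:
            return self.ligand_indices
        return np.arange(self.n_atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.concatenate([np.full(self.n_receptor, self.receptor_mass),
                               self.ligand_mass])

    # -- structure / selections --------------------------------------------

    def to_structure(self) -> StructureModel:
        nr, nl = self.n_receptor, self.n_ligand
        site = set(int(i) for i in self.site_beads)
        decoy = {int(i): k for k, beads in enumerate(self.decoy_beads) for i in beads}
        resnames = []
        for i in range(nr):
            if i in site:
                resnames.append("SIT")
            elif i in decoy:
                resnames.append(f"DC{decoy[i] + 1}")
            else:
                resnames.append("REC")
        resnames += ["LIG"] * nl
        coords = np.vstack([self.receptor_coords, self.bound_pose])
        return StructureModel(
            atom_name=["BB"] * nr + [f"B{i+1}" for i in range(nl)],
            element=["C"] * (nr + nl),
            residue_name=resnames,
            residue_number=np.concatenate([np.arange(1, nr + 1), np.full(nl, 1)]),
            insertion_code=[""] * (nr + nl),
            chain_id=["R"] * nr + ["L"] * nl,
            mass=self.masses,
            coords=coords,
            charge=np.concatenate([self.receptor_charge, self.ligand_charge]),
            lj_sigma=np.concatenate([self.receptor_sigma, self.ligand_sigma]),
            lj_epsilon=np.concatenate([self.receptor_epsilon, self.ligand_epsilon]),
        )

    def ligand_selection(self) -> AtomSelection:
        return AtomSelection.from_indices(self.ligand_indices, label="ligand")

    def site_selection(self) -> AtomSelection:
        return AtomSelection.from_indices(self.site_beads, label="binding site")

    def bound_pose_frame(self) -> np.ndarray:
        return np.vstack([self.receptor_coords, self.bound_pose])

    def initial_frame(self, ligand_coords: np.ndarray) -> np.ndarray:
        return np.vstack([self.receptor_coords, ligand_coords])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {}
        for name, val in self.__dict__.items():
            if name == "energy_model":
                d[name] = {"cutoff": val.cutoff, "dielectric_slope": val.dielectric_slope}
            elif isinstance(val, np.ndarray):
                d[name] = val.tolist()
            elif isinstance(val, tuple):
                d[name] = [v.tolist() if isinstance(v, np.ndarray) else v for v in val]
            else:
                d[name] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystemSpec":
        d = dict(d)
        d["energy_model"] = EnergyModel(**d["energy_model"])
        d["decoy_beads"] = tuple(np.asarray(b, dtype=np.int64) for b in d.get("decoy_beads", ()))
        d["decoy_depths"] = tuple(d.get("decoy_depths", ()))
        return cls(**d)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "ToySystemSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimState:
    """Checkpoint unit for the supervision loop: full-system snapshot."""

    coords: np.ndarray       # (n_atoms, 3) Å
    velocities: np.ndarray   # (n_atoms, 3) Å/ps; zero rows for fixed beads
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("velocity array shape must match coordinates")
        if not (np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("state must be finite")

    def copy(self) -> "SimState":
        return SimState(self.coords.copy(), self.velocities.copy(), self.time_ps)


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forces_nb(x, xs, ms_par, mm_par, mm_act, bonds, br0, bk,
               teth_k, teth_ref, wall_mask, wall_c, wall_r, wall_k, rc, f):
    n_m = x.shape[0]
    n_s = xs.shape[0]
    pe = 0.0
    for i in range(n_m):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rc2 = rc * rc
    # mobile vs static
    for i in range(n_m):
        for j in range(n_s):
            dx = x[i, 0] - xs[j, 0]
            dy = x[i, 1] - xs[j, 1]
            dz = x[i, 2] - xs[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                r = np.sqrt(r2)
                sig = ms_par[i, j, 0]
                eps = ms_par[i, j, 1]
                cq = ms_par[i, j, 2]
                vc = ms_par[i, j, 3]
                dvc = ms_par[i, j, 4]
                sr6 = (sig * sig / r2) ** 3
                pe += 4.0 * eps * (sr6 * sr6 - sr6) + cq / r2 - vc - (r - rc) * dvc
                g = 24.0 * eps / r * (2.0 * sr6 * sr6 - sr6) + 2.0 * cq / (r2 * r) + dvc
                gg = g / r
                f[i, 0] += gg * dx
                f[i, 1] += gg * dy
                f[i, 2] += gg * dz
    # mobile vs mobile
    for i in range(n_m):
        for j in range(i + 1, n_m):
            if not mm_act[i, j]:
                continue
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                r = np.sqrt(r2)
                sig = mm_par[i, j, 0]
                eps = mm_par[i, j, 1]
                cq = mm_par[i, j, 2]
                vc = mm_par[i, j, 3]
                dvc = mm_par[i, j, 4]
                sr6 = (sig * sig / r2) ** 3
                pe += 4.0 * eps * (sr6 * sr6 - sr6) + cq / r2 - vc - (r - rc) * dvc
                g = 24.0 * eps / r * (2.0 * sr6 * sr6 - sr6) + 2.0 * cq / (r2 * r) + dvc
                gg = g / r
                f[i, 0] += gg * dx
                f[i, 1] += gg * dy
                f[i, 2] += gg * dz
                f[j, 0] -= gg * dx
                f[j, 1] -= gg * dy
                f[j, 2] -= gg * dz
    # harmonic bonds (between mobile beads)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - br0[b]
        pe += 0.5 * bk[b] * dr * dr
        gg = -bk[b] * dr / r
        f[i, 0] += gg * dx
        f[i, 1] += gg * dy
        f[i, 2] += gg * dz
        f[j, 0] -= gg * dx
        f[j, 1] -= gg * dy
        f[j, 2] -= gg * dz
    # tethers and flat-bottom wall
    for i in range(n_m):
        if teth_k[i] > 0.0:
            dx = x[i, 0] - teth_ref[i, 0]
            dy = x[i, 1] - teth_ref[i, 1]
            dz = x[i, 2] - teth_ref[i, 2]
            pe += 0.5 * teth_k[i] * (dx * dx + dy * dy + dz * dz)
            f[i, 0] -= teth_k[i] * dx
            f[i, 1] -= teth_k[i] * dy
            f[i, 2] -= teth_k[i] * dz
        if wall_mask[i]:
            dx = x[i, 0] - wall_c[0]
            dy = x[i, 1] - wall_c[1]
            dz = x[i, 2] - wall_c[2]
            rr = np.sqrt(dx * dx + dy * dy + dz * dz)
            if rr > wall_r and rr > 1e-12:
                dr = rr - wall_r
                pe += 0.5 * wall_k * dr * dr
                gg = -wall_k * dr / rr
                f[i, 0] += gg * dx
                f[i, 1] += gg * dy
                f[i, 2] += gg * dz
    return pe


@njit(cache=True)
def _baoab_nb(x, v, xs, ms_par, mm_par, mm_act, bonds, br0, bk,
              teth_k, teth_ref, wall_mask, wall_c, wall_r, wall_k, rc,
              mass, dt, c1, c2, noise, record_every, rec_x, rec_v, rec_pe):
    n_m = x.shape[0]
    n_steps = noise.shape[0]
    f = np.zeros((n_m, 3))
    pe = _forces_nb(x, xs, ms_par, mm_par, mm_act, bonds, br0, bk,
                    teth_k, teth_ref, wall_mask, wall_c, wall_r, wall_k, rc, f)
    nrec = 0
    half = 0.5 * dt
    for s in range(n_steps):
        for i in range(n_m):
            sc = half * F_CONV / mass[i]
            for k in range(3):
                v[i, k] += sc * f[i, k]
                x[i, k] += half * v[i, k]
        for i in range(n_m):
            for k in range(3):
                v[i, k] = c1 * v[i, k] + c2[i] * noise[s, i, k]
                x[i, k] += half * v[i, k]
        pe = _forces_nb(x, xs, ms_par, mm_par, mm_act, bonds, br0, bk,
                        teth_k, teth_ref, wall_mask, wall_c, wall_r, wall_k, rc, f)
        for i in range(n_m):
            sc = half * F_CONV / mass[i]
            for k in range(3):
                v[i, k] += sc * f[i, k]
        if (s + 1) % record_every == 0:
            for i in range(n_m):
                for k in range(3):
                    rec_x[nrec, i, k] = x[i, k]
                    rec_v[nrec, i, k] = v[i, k]
            rec_pe[nrec] = pe
            nrec += 1
    return nrec


# ---------------------------------------------------------------------------
# Propagation API
# ---------------------------------------------------------------------------

def _mobile_param_pack(spec: ToySystemSpec):
    """Assemble kernel parameter arrays for the current mobile/static split."""
    st_sig = np.concatenate([spec.receptor_sigma, spec.ligand_sigma])
    st_eps = np.concatenate([spec.receptor_epsilon, spec.ligand_epsilon])
    st_q = np.concatenate([spec.receptor_charge, spec.ligand_charge])
    mob = spec.mobile_indices
    static = np.setdiff1d(np.arange(spec.n_atoms), mob)
    model = spec.energy_model
    ms_par = _pair_param_block(st_sig[mob], st_eps[mob], st_q[mob],
                               st_sig[static], st_eps[static], st_q[static], model)
    mm_par = _pair_param_block(st_sig[mob], st_eps[mob], st_q[mob],
                               st_sig[mob], st_eps[mob], st_q[mob], model)
    n_m = mob.size
    mm_act = np.ones((n_m, n_m), dtype=np.bool_)
    np.fill_diagonal(mm_act, False)
    # exclusions: bonded ligand pairs; receptor-receptor pairs are kept only
    # when the receptor is mobile (restrained), where they provide sterics.
    mob_pos = {int(a): k for k, a in enumerate(mob)}
    lig_off = spec.n_receptor
    for b in range(spec.bonds.shape[0]):
        i = mob_pos[int(spec.bonds[b, 0]) + lig_off]
        j = mob_pos[int(spec.bonds[b, 1]) + lig_off]
        mm_act[i, j] = mm_act[j, i] = False
    bonds_m = np.array(
        [[mob_pos[int(i) + lig_off], mob_pos[int(j) + lig_off]] for i, j in spec.bonds],
        dtype=np.int64,
    ).reshape(-1, 2)
    teth_k = np.zeros(n_m)
    teth_ref = np.zeros((n_m, 3))
    if spec.receptor_restraint_k is not None:
        for k, a in enumerate(mob):
            if a < spec.n_receptor:
                teth_k[k] = spec.receptor_restraint_k
                teth_ref[k] = spec.receptor_coords[a]
    wall_mask = np.array([a >= spec.n_receptor for a in mob], dtype=np.bool_)
    return {
        "mob": mob, "static": static, "ms_par": ms_par, "mm_par": mm_par,
        "mm_act": mm_act, "bonds": bonds_m, "teth_k": teth_k,
        "teth_ref": teth_ref, "wall_mask": wall_mask,
        "mass": spec.masses[mob],
    }


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw velocities (Å/ps) from the Maxwell–Boltzmann distribution."""
    kt = KB * max(temperature, 0.0) * F_CONV
    s = np.sqrt(kt / np.asarray(masses, dtype=float))
    return s[:, None] * rng.standard_normal((len(masses), 3))


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K) of the given beads."""
    ke = 0.5 * (np.asarray(masses)[:, None] * np.asarray(velocities) ** 2).sum() / F_CONV
    ndof = 3 * len(masses)
    return float(2.0 * ke / (ndof * KB))


def _rng_from_seed(seed) -> np.random.Generator:
    """Counter-based (Philox) generator; ``seed`` may be an int or sequence."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return np.random.Generator(np.random.Philox(ss))


def propagate_langevin(
    state: SimState,
    spec: ToySystemSpec,
    n_steps: int,
    record_every: int = 1,
    seed=0,
    with_velocities: bool = False,
    _pack: dict | None = None,
) -> tuple[SimState, Trajectory]:
    """BAOAB Langevin propagation under the toy energy model.

    Returns the advanced state and a trajectory of ``n_steps //
    record_every`` full-system frames. The same ``seed`` reproduces the
    output bitwise. Noise is generated in chunks from one Philox stream, so
    memory stays bounded for long runs. With ``with_velocities`` the
    returned trajectory additionally carries per-frame mobile-bead
    velocities (``mobile_velocities``) and potential energies
    (``potential_energies``) for kinetic/thermodynamic checks.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    pack = _pack if _pack is not None else _mobile_param_pack(spec)
    mob, static = pack["mob"], pack["static"]
    x = state.coords[mob].copy()
    v = state.velocities[mob].copy()
    xs = state.coords[static].copy()
    dt = spec.timestep
    gamma = spec.friction
    c1 = float(np.exp(-gamma * dt))
    kt = KB * spec.temperature * F_CONV
    c2 = np.sqrt(kt * max(0.0, 1.0 - c1 * c1) / pack["mass"])
    n_rec = n_steps // record_every
    rec_x = np.empty((n_rec, mob.size, 3))
    rec_v = np.empty((n_rec, mob.size, 3))
    rec_pe = np.empty(n_rec)
    rng = _rng_from_seed(seed)
    model = spec.energy_model
    done = 0
    rec_done = 0
    chunk = record_every * max(1, 200_000 // record_every)
    while done < n_steps:
        this = min(chunk, n_steps - done)
        noise = rng.standard_normal((this, mob.size, 3))
        nr = (done + this) // record_every - rec_done
        sl = slice(rec_done, rec_done + nr)
        # steps not aligned to record_every at the tail record nothing extra
        got = _baoab_nb(
            x, v, xs, pack["ms_par"], pack["mm_par"], pack["mm_act"],
            pack["bonds"], spec.bond_r0, spec.bond_k,
            pack["teth_k"], pack["teth_ref"], pack["wall_mask"],
            spec.wall_center, spec.wall_radius, spec.wall_k, model.cutoff,
            pack["mass"], dt, c1, c2, noise, record_every,
            rec_x[sl], rec_v[sl], rec_pe[sl],
        )
        rec_done += got
        done += this
        if not np.all(np.isfinite(x)):
            bad = np.flatnonzero(~np.isfinite(x).all(axis=1))
            raise IntegrationError(
                f"non-finite coordinates for mobile beads {bad.tolist()} "
                f"after {done} steps (overlapping beads?)"
            )
    # assemble full-system frames
    template = state.coords.copy()
    frames = np.repeat(template[None, :, :], n_rec, axis=0)
    frames[:, mob, :] = rec_x
    times = state.time_ps + (np.arange(1, n_rec + 1)) * record_every * dt
    traj = Trajectory(coords=frames, times_ps=times, tag="toysim")
    if with_velocities:
        traj.mobile_velocities = rec_v
        traj.potential_energies = rec_pe
    new_coords = template
    new_coords[mob] = x
    new_vel = state.velocities.copy()
    new_vel[mob] = v
    new_state = SimState(new_coords, new_vel, state.time_ps + n_steps * dt)
    return new_state, traj


def potential_energy(frame: np.ndarray, spec: ToySystemSpec) -> float:
    """Total potential energy (kcal/mol) of the mobile subsystem in a frame."""
    pack = _mobile_param_pack(spec)
    mob, static = pack["mob"], pack["static"]
    f = np.zeros((mob.size, 3))
    return float(_forces_nb(
        np.ascontiguousarray(frame[mob]), np.ascontiguousarray(frame[static]),
        pack["ms_par"], pack["mm_par"], pack["mm_act"],
        pack["bonds"], spec.bond_r0, spec.bond_k,
        pack["teth_k"], pack["teth_ref"], pack["wall_mask"],
        spec.wall_center, spec.wall_radius, spec.wall_k,
        spec.energy_model.cutoff, f,
    ))


def interaction_energy(
    frame: np.ndarray,
    spec: ToySystemSpec,
    ligand_selection: AtomSelection | None = None,
    receptor_selection: AtomSelection | None = None,
) -> float:
    """Ligand–receptor nonbonded interaction energy (kcal/mol) of one frame.

    Sum of force-shifted LJ + Coulomb over all selected cross pairs within
    the cutoff; exactly 0 when every pair is beyond the cutoff.
    """
    structure = spec.to_structure()
    lig = (ligand_selection or spec.ligand_selection()).resolve(structure)
    rec = (receptor_selection or AtomSelection.from_indices(
        np.arange(spec.n_receptor), label="receptor")).resolve(structure)
    if np.intersect1d(lig, rec).size:
        raise ValueError("ligand and receptor selections must be disjoint")
    frame = np.asarray(frame, dtype=float)
    sig = structure.lj_sigma
    eps = structure.lj_epsilon
    q = structure.charge
    par = _pair_param_block(sig[lig], eps[lig], q[lig], sig[rec], eps[rec], q[rec],
                            spec.energy_model)
    e, _, _ = _np_pair_energy_forces(frame[lig], frame[rec], par,
                                     spec.energy_model.cutoff)
    return e


# ---------------------------------------------------------------------------
# Funnel-system builder
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    rxy = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([rxy * np.cos(theta), rxy * np.sin(theta), z], axis=1)
    return radius * pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _ligand_template() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                                np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Four-bead macrocycle-like ring: square with stiff edge + diagonal bonds.

    The beads are chemically distinct (like the residues of a macrocyclic
    peptide): a charged "guanidinium-like" anchor bead plus three beads with
    different LJ parameters, so no ring flip or rotation is energy-degenerate
    and the bound orientation is identifiable.
    """
    s = 2.4
    # bead 1 is lifted out of the ring plane (a substituent-like bump): the
    # ligand is chiral-ish, so a mirrored pose must push the bump into the
    # receptor and is sterically penalized, not energy-degenerate
    coords = np.array([
        [s / 2, s / 2, 0.0], [-s / 2, s / 2, 0.9],
        [-s / 2, -s / 2, 0.0], [s / 2, -s / 2, 0.0],
    ])
    bonds = np.array([[0, 1], [1, 2], [2, 3], [3, 0], [0, 2], [1, 3]])
    r0 = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)
    k = np.array([50.0, 50.0, 50.0, 50.0, 25.0, 25.0])
    mass = np.array([30.0, 25.0, 20.0, 25.0])
    sigma = np.array([3.0, 3.2, 3.0, 2.8])
    eps = np.array([0.05, 3.0, 0.2, 0.03])    # bead 1: bulky hydrophobic
    # bead 0: guanidinium-like cation; bead 2: carbonyl-like partial anion.
    # Two charged contacts across the ring make the bound orientation unique.
    charge = np.array([1.0, 0.0, -0.5, 0.0])
    return coords, bonds, r0, k, mass, sigma, eps, charge


def _minimize_pose(
    guess: np.ndarray,
    rec_coords: np.ndarray,
    rec_sig: np.ndarray, rec_eps: np.ndarray, rec_q: np.ndarray,
    lig_sig: np.ndarray, lig_eps: np.ndarray, lig_q: np.ndarray,
    bonds: np.ndarray, bond_r0: np.ndarray, bond_k: np.ndarray,
    model: EnergyModel,
) -> tuple[np.ndarray, float]:
    """Locally minimize interaction + bond energy over ligand coordinates."""
    par = _pair_param_block(lig_sig, lig_eps, lig_q, rec_sig, rec_eps, rec_q, model)
    nl = guess.shape[0]

    def objective(flat):
        x = flat.reshape(nl, 3)
        e, fl, _ = _np_pair_energy_forces(x, rec_coords, par, model.cutoff)
        grad = -fl
        d = x[bonds[:, 0]] - x[bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - bond_r0
        e += float(0.5 * (bond_k * dr**2).sum())
        gb = (bond_k * dr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(grad, bonds[:, 0], gb)
        np.add.at(grad, bonds[:, 1], -gb)
        return e, grad.ravel()

    res = minimize(objective, guess.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    x = res.x.reshape(nl, 3)
    e_int, _, _ = _np_pair_energy_forces(x, rec_coords, par, model.cutoff)
    return x, float(e_int)


def _lj_energy_vs_subset(x_lig, rec_coords, subset, rec_sig, rec_eps,
                         lig_sig, lig_eps, model) -> float:
    """LJ-only interaction of the ligand with a receptor-bead subset."""
    par = _pair_param_block(lig_sig, lig_eps, np.zeros_like(lig_sig),
                            rec_sig[subset], rec_eps[subset],
                            np.zeros(len(subset)), model)
    e, _, _ = _np_pair_energy_forces(x_lig, rec_coords[subset], par, model.cutoff)
    return e


def build_funnel_system(
    site_depth: float = -10.0,
    n_decoys: int = 1,
    decoy_depths: Sequence[float] = (-5.0,),
    seed: int = 0,
    receptor_radius: float = 10.0,
    bead_spacing: float = 3.6,
    patch_radius: float = 3.8,
    decoy_patch_radius: float = 6.0,
    temperature: float = 310.0,
    friction: float = 5.0,
    timestep: float = 0.004,
    wall_radius: float = 100.0,
    wall_k: float = 2.0,
    cutoff: float = 9.0,
) -> ToySystemSpec:
    """Build a spherical bead receptor with a planted binding funnel.

    ``site_depth`` (kcal/mol, < 0) sets the target interaction energy of the
    planted bound pose; decoy patches must all be shallower than the main
    site. The sticky-patch epsilons are calibrated so the locally minimized
    pose energies approximate the requested depths; the planted bound pose
    is the local energy minimum found by that minimization. Deterministic
    for a given ``seed``.

    Note: friction defaults to 5 ps⁻¹ here (solvent drag folded into the
    Langevin friction), intentionally larger than the bare thermostat-style
    damping that :class:`ToySystemSpec` defaults to.
    """
    decoy_depths = tuple(float(d) for d in decoy_depths)
    if len(decoy_depths) != n_decoys:
        raise InvalidSpecError("decoy_depths must have n_decoys entries")
    if site_depth >= 0:
        raise InvalidSpecError("site_depth must be < 0")
    for d in decoy_depths:
        if d >= 0:
            raise InvalidSpecError("decoy depths must be < 0")
        if d <= site_depth:
            raise InvalidSpecError(
                f"decoy depth {d} kcal/mol is at least as deep as the main site "
                f"({site_depth}); decoys must be shallower"
            )
    rng = _rng_from_seed(seed)
    model = EnergyModel(cutoff=cutoff)
    n_beads = max(16, int(round(4 * np.pi * receptor_radius**2 / bead_spacing**2)))
    rec = _fibonacci_sphere(n_beads, receptor_radius)
    jitter = rng.normal(0.0, 0.12, size=rec.shape)
    rec = rec + jitter
    rec *= (receptor_radius / np.linalg.norm(rec, axis=1))[:, None]
    rec_sig = np.full(n_beads, 3.2)
    rec_eps = np.full(n_beads, 0.05)
    rec_q = np.zeros(n_beads)

    apex = np.array([0.0, 0.0, receptor_radius])
    site_beads = np.flatnonzero(np.linalg.norm(rec - apex, axis=1) <= patch_radius)
    anchor_bead = site_beads[np.argmin(np.linalg.norm(rec[site_beads] - apex, axis=1))]
    # sculpt a concave pocket: recess the anchor, raise the surrounding rim.
    # Lateral sliding out of the seat then costs steric energy, so the bound
    # pose is a well-separated minimum rather than one of many lattice seats.
    rim = np.flatnonzero(
        (np.linalg.norm(rec - apex, axis=1) > patch_radius)
        & (np.linalg.norm(rec - apex, axis=1) <= patch_radius + 3.2))
    rec[rim] *= ((np.linalg.norm(rec[rim], axis=1) + 1.8)
                 / np.linalg.norm(rec[rim], axis=1))[:, None]
    rec[anchor_bead] *= (np.linalg.norm(rec[anchor_bead]) - 1.0) / np.linalg.norm(rec[anchor_bead])
    # two charged beads in the patch (a "deep acidic" anchor plus a basic
    # neighbour): paired with the ligand's +1/−0.5 beads they pin both the
    # position and the in-plane orientation of the bound ring, while the
    # calibrated patch LJ supplies the remaining depth
    rec_q[anchor_bead] = -min(0.5, abs(site_depth) / 20.0)
    site_weights = np.ones(site_beads.size)
    others = site_beads[site_beads != anchor_bead]
    partner = None
    if others.size:
        partner = others[np.argmin(np.linalg.norm(rec[others] - rec[anchor_bead],
                                                  axis=1))]
        rec_q[partner] = min(0.8, abs(site_depth) / 12.5)
    # a hydrophobic subpocket off the charged axis (think aryl-binding
    # pocket): one site bead several-fold stickier, pairing with the bulky
    # ligand bead and pinning the soft pivot about the charged diagonal
    sub_cands = [b for b in site_beads if b != anchor_bead and b != partner]
    if sub_cands:
        subpocket = max(sub_cands,
                        key=lambda b: np.linalg.norm(rec[b] - rec[anchor_bead]))
        site_weights[np.searchsorted(site_beads, subpocket)] = 6.0

    lig_coords, bonds, bond_r0, bond_k, lig_mass, lig_sig, lig_eps, lig_q = _ligand_template()

    def tangent_guesses(direction: np.ndarray) -> list[np.ndarray]:
        """Ring placed tangent to the surface in several distinct orientations
        (in-plane rotations and the flipped ring), so the planted pose is the
        deepest of the competing arrangements, not just a local one."""
        direction = direction / np.linalg.norm(direction)
        z = np.array([0.0, 0.0, 1.0])
        vcross = np.cross(z, direction)
        c = float(np.dot(z, direction))
        if np.linalg.norm(vcross) < 1e-9:
            rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -vcross[2], vcross[1]],
                           [vcross[2], 0, -vcross[0]],
                           [-vcross[1], vcross[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
        center = direction * (receptor_radius + 2.8)
        guesses = []
        for flip in (1.0, -1.0):
            for ang in np.arange(0.0, 2 * np.pi, np.pi / 4):
                ca, sa = np.cos(ang), np.sin(ang)
                rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
                ring = lig_coords @ np.diag([1.0, flip, flip]).T @ rz.T
                guesses.append(ring @ rot.T + center)
        return guesses

    def calibrate_patch(beads: np.ndarray, depth: float, direction: np.ndarray,
                        eps0: float = 1.0, weights: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, float]:
        """Scale patch epsilon so the deepest minimized pose reaches depth."""
        eps_val = eps0
        w_patch = np.ones(beads.size) if weights is None else weights
        pose = None
        e_tot = 0.0
        eps_arr = rec_eps.copy()
        for _ in range(10):
            eps_arr = rec_eps.copy()
            eps_arr[beads] = eps_val * w_patch
            starts = [pose] if pose is not None else []
            starts += tangent_guesses(direction)
            cands = [
                _minimize_pose(g, rec, rec_sig, eps_arr, rec_q, lig_sig,
                               lig_eps, lig_q, bonds, bond_r0, bond_k, model)
                for g in starts
            ]
            pose, e_tot = min(cands, key=lambda c: c[1])
            e_patch = _lj_energy_vs_subset(pose, rec, beads, rec_sig, eps_arr,
                                           lig_sig, lig_eps, model)
            e_rest = e_tot - e_patch
            target = min(depth - e_rest, -0.05)
            if abs(e_tot - depth) < 0.15 or e_patch >= -1e-9:
                break
            # patch LJ scales as sqrt(eps) through Lorentz-Berthelot mixing
            eps_val = float(np.clip(eps_val * (target / e_patch) ** 2, 1e-3, 200.0))
        return eps_arr[beads], pose, e_tot

    eps_site, bound_pose, e_bound = calibrate_patch(site_beads, site_depth, apex,
                                                    weights=site_weights)
    rec_eps[site_beads] = eps_site

    decoy_beads = []
    decoy_poses = []
    decoy_centers = []
    phi0 = rng.uniform(0.0, 2 * np.pi)
    polar = np.deg2rad(70.0)
    for k in range(n_decoys):
        phi = phi0 + 2 * np.pi * k / max(n_decoys, 1)
        direction = np.array([np.sin(polar) * np.cos(phi),
                              np.sin(polar) * np.sin(phi), np.cos(polar)])
        dists = np.linalg.norm(rec - receptor_radius * direction, axis=1)
        beads = np.flatnonzero(dists <= decoy_patch_radius)
        beads = np.setdiff1d(beads, site_beads)
        if beads.size == 0:
            beads = np.array([int(np.argmin(dists))])
        eps_d, pose_d, e_d = calibrate_patch(beads, decoy_depths[k], direction)
        rec_eps[beads] = eps_d
        decoy_beads.append(beads)
        decoy_poses.append(pose_d)
        decoy_centers.append(rec[beads].mean(axis=0))

    site_center = rec[site_beads].mean(axis=0)
    spec = ToySystemSpec(
        receptor_coords=rec, receptor_sigma=rec_sig, receptor_epsilon=rec_eps,
        receptor_charge=rec_q, ligand_sigma=lig_sig, ligand_epsilon=lig_eps,
        ligand_charge=lig_q, ligand_mass=lig_mass, bonds=bonds,
        bond_r0=bond_r0, bond_k=bond_k, site_center=site_center,
        site_beads=site_beads, bound_pose=bound_pose,
        decoy_centers=np.array(decoy_centers).reshape(-1, 3),
        decoy_beads=tuple(decoy_beads),
        decoy_poses=(np.array(decoy_poses).reshape(len(decoy_poses), -1, 3)
                     if decoy_poses else np.zeros((0, 4, 3))),
        decoy_depths=decoy_depths,
        temperature=temperature, friction=friction, timestep=timestep,
        wall_radius=wall_radius, wall_k=wall_k, energy_model=model, seed=seed,
    )
    # build-time invariant: the planted pose is deeper than every decoy pose
    e_bound = interaction_energy(spec.bound_pose_frame(), spec)
    for k in range(n_decoys):
        e_dec = interaction_energy(spec.initial_frame(spec.decoy_poses[k]), spec)
        if e_bound >= e_dec:
            raise InvalidSpecError(
                f"planted bound pose ({e_bound:.2f} kcal/mol) is not deeper than "
                f"decoy {k} ({e_dec:.2f} kcal/mol)"
            )
    return spec


def place_ligand_at_distance(
    spec: ToySystemSpec, distance: float, seed=0, max_retries: int = 200
) -> SimState:
    """Place the ligand with its COM at ``distance`` Å from the site center.

    The direction and orientation are randomized by ``seed``; placements
    clashing with the receptor (any pair < 2 Å) or outside the wall are
    retried. Velocities are drawn from Maxwell–Boltzmann at the spec
    temperature. By construction |ligand COM − site center| is exact to
    floating point, well within the ±0.1 Å contract.
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    rng = _rng_from_seed(seed)
    com = (spec.ligand_mass[:, None] * spec.bound_pose).sum(axis=0) / spec.ligand_mass.sum()
    template = spec.bound_pose - com
    for _ in range(max_retries):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        rot = _random_rotation(rng)
        pos = spec.site_center + distance * u
        lig = template @ rot.T + pos
        dmin = np.min(np.linalg.norm(
            lig[:, None, :] - spec.receptor_coords[None, :, :], axis=2))
        inside = np.all(np.linalg.norm(lig - spec.wall_center, axis=1)
                        < spec.wall_radius)
        if dmin >= 2.0 and inside:
            coords = spec.initial_frame(lig)
            vel = np.zeros_like(coords)
            mob = spec.mobile_indices
            vel[mob] = maxwell_boltzmann_velocities(
                spec.masses[mob], spec.temperature, rng)
            return SimState(coords, vel, 0.0)
    raise PlacementError(
        f"no clash-free placement at {distance} Å after {max_retries} tries")
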