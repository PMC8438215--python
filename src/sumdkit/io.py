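"""Standard-format I/O, configuration files and run manifests.

PDB structures are read and written through gemmi (fixed-width records,
altloc and insertion-code aware). Trajectories are exchanged as DCD or XTC
via MDAnalysis, or as a plain-text XYZ dialect whose comment line carries
the frame time — the lossless, diffable default for fixtures. Configs are
YAML/JSON with strict unknown-key rejection, and every pipeline command can
be stamped with a :class:`RunManifest` sufficient to re-run it bitwise.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import AtomSelection, SelectionError, StructureModel, Trajectory
from .supervisor import SupervisionConfig
from .toysim import ToySystemSpec, build_funnel_system


class PDBFormatError(ValueError):
    """A PDB record could not be parsed."""


class ConfigError(ValueError):
    """A configuration file violates the schema."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path) -> StructureModel:
    """Read ATOM/HETATM records into a :class:`StructureModel`.

    Insertion codes are preserved as part of residue identity. When
    alternate locations are present, the highest-occupancy altloc of each
    atom is kept (ties: the one listed first). Masses come from the element
    lookup; an unknown element is an error.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models found")
    model = st[0]
    names, elements, resnames, resnums, icodes, chains = [], [], [], [], [], []
    masses, coords = [], []
    for chain in model:
        for residue in chain:
            # altloc rule: keep highest occupancy, tie -> first listed
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            for atom in residue:
                if by_name.get(atom.name) is not atom:
                    continue
                el = atom.element
                if el.name in ("X", "") or el.weight <= 0:
                    raise PDBFormatError(
                        f"{path}: unknown element for atom {atom.name!r} in "
                        f"{chain.name}/{residue.seqid.num}{residue.seqid.icode.strip()}")
                names.append(atom.name)
                elements.append(el.name)
                resnames.append(residue.name)
                resnums.append(residue.seqid.num)
                icodes.append(residue.seqid.icode.strip())
                chains.append(chain.name)
                masses.append(el.weight)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not names:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    return StructureModel(
        atom_name=names, element=elements, residue_name=resnames,
        residue_number=np.array(resnums), insertion_code=icodes,
        chain_id=chains, mass=np.array(masses), coords=np.array(coords))


def write_pdb(structure: StructureModel, path) -> None:
    """Write a structure as fixed-width PDB (coordinates to 3 decimals)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "sumdkit"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(structure.n_atoms):
        cid = structure.chain_id[i]
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        chain = chain_map[cid]
        num = int(structure.residue_number[i])
        icode = structure.insertion_code[i] or " "
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if (last.seqid.num == num and last.seqid.icode.strip() ==
                    icode.strip() and last.name == structure.residue_name[i]):
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = structure.residue_name[i]
            res.seqid = gemmi.SeqId(num, icode)
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = structure.atom_name[i]
        atom.element = gemmi.Element(structure.element[i])
        atom.pos = gemmi.Position(*structure.coords[i])
        atom.occ = 1.0
        res.add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """Plain-text XYZ dialect: the comment line carries ``t= <ps>``."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times_ps[f]:.6f} ps tag= {traj.tag}\n")
            for x, y, z in traj.coords[f]:
                fh.write(f"X {x:.8f} {y:.8f} {z:.8f}\n")


def read_trajectory_xyz(path) -> Trajectory:
    frames, times = [], []
    tag = ""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1].split()
        t = float(comment[1]) if len(comment) >= 2 and comment[0] == "t=" else len(times) * 1.0
        if "tag=" in comment:
            k = comment.index("tag=")
            tag = " ".join(comment[k + 1:])
        block = lines[i + 2:i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        times.append(t)
        i += 2 + n
    return Trajectory(coords=np.array(frames), times_ps=np.array(times), tag=tag)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write DCD/XTC (via MDAnalysis) or the plain-text XYZ dialect.

    Format is chosen by extension. XTC is lossy at its 0.001 nm
    quantization (≈0.01 Å); DCD and XYZ round-trip to float precision.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        write_trajectory_xyz(traj, path)
        return
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f].astype(np.float32)
            u.trajectory.ts.time = traj.times_ps[f]
            u.trajectory.ts.frame = f
            w.write(u.atoms)


def read_trajectory(path, n_atoms: int | None = None, tag: str = "") -> Trajectory:
    """Read DCD/XTC (via MDAnalysis) or the plain-text XYZ dialect.

    ``n_atoms`` (the topology's atom count) is required for binary formats
    and validated against the file; frame times default to the stored times
    where the format provides them.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        traj = read_trajectory_xyz(path)
        if n_atoms is not None and traj.n_atoms != n_atoms:
            raise ValueError(f"{path}: {traj.n_atoms} atoms, expected {n_atoms}")
        return traj
    import MDAnalysis as mda

    if n_atoms is None:
        raise ValueError("n_atoms is required for binary trajectory formats")
    u = mda.Universe.empty(n_atoms, trajectory=True)
    try:
        u.load_new(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"{path}: cannot read trajectory ({exc})") from exc
    if u.trajectory.n_atoms != n_atoms:
        raise ValueError(f"{path}: {u.trajectory.n_atoms} atoms, expected {n_atoms}")
    frames, times = [], []
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float).copy())
        times.append(float(ts.time))
    times = np.asarray(times)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(1.0, times.size + 1)     # formats without real times
    return Trajectory(coords=np.array(frames), times_ps=times, tag=tag or path.stem)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_SYSTEM_KEYS = {
    "kind", "site_depth", "n_decoys", "decoy_depths", "seed", "receptor_radius",
    "bead_spacing", "patch_radius", "temperature", "friction", "timestep",
    "wall_radius", "wall_k", "cutoff", "path",
}
_SUPERVISION_KEYS = {
    "site_residues", "ligand_chain", "window_length_ps", "dcm_samples_per_window",
    "slope_threshold", "max_consecutive_rejections", "success_distance",
    "supervision_off_distance", "max_total_windows", "base_seed",
}
_ANALYSIS_KEYS = {
    "stride", "noise_threshold", "neighbor_count", "min_samples", "xi", "max_eps",
    "min_residence_ps", "dcm_band", "exclude_below", "dcm_bins", "energy_bins",
}
_ANALYSIS_DEFAULTS = {
    "stride": 10, "noise_threshold": 0.01, "neighbor_count": 5,
    "min_samples": 10, "xi": 0.05, "max_eps": float("inf"),
    "min_residence_ps": 50.0, "dcm_band": 2.0, "exclude_below": 5.0,
    "dcm_bins": 40, "energy_bins": 40,
}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}")


def load_config(path) -> tuple[ToySystemSpec, SupervisionConfig, dict]:
    """Load a YAML/JSON pipeline config.

    Sections: ``system`` (funnel parameters or a path to a saved spec),
    ``supervision`` (site residues as chain/resnum/icode triples, window
    length, thresholds, seeds) and ``analysis``. Unknown keys are rejected
    so typos fail loudly; omitted keys take the documented defaults (e.g.
    the window length defaults to 600 ps).
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("<top>", raw, {"system", "supervision", "analysis"})

    sys_cfg = dict(raw.get("system") or {})
    _check_keys("system", sys_cfg, _SYSTEM_KEYS)
    if "path" in sys_cfg:
        spec = ToySystemSpec.load_json(sys_cfg["path"])
    else:
        kind = sys_cfg.pop("kind", "funnel")
        if kind != "funnel":
            raise ConfigError(f"unknown system kind {kind!r}")
        if "decoy_depths" in sys_cfg and "n_decoys" not in sys_cfg:
            sys_cfg["n_decoys"] = len(sys_cfg["decoy_depths"])
        spec = build_funnel_system(**sys_cfg)

    sup_cfg = dict(raw.get("supervision") or {})
    _check_keys("supervision", sup_cfg, _SUPERVISION_KEYS)
    site_residues = sup_cfg.pop("site_residues", None)
    ligand_chain = sup_cfg.pop("ligand_chain", None)
    kwargs = dict(sup_cfg)
    if site_residues is not None:
        kwargs["site_selection"] = AtomSelection.from_residues(
            site_residues, label="site residues")
    if ligand_chain is not None:
        kwargs["ligand_selection"] = AtomSelection.from_chain(
            ligand_chain, label="ligand")
    try:
        sup = SupervisionConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc

    ana = dict(_ANALYSIS_DEFAULTS)
    given = dict(raw.get("analysis") or {})
    _check_keys("analysis", given, _ANALYSIS_KEYS)
    ana.update(given)
    return spec, sup, ana


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility envelope of one pipeline command.

    Records the resolved configuration, every seed, the tool version, input
    file hashes, per-stage timestamps and the hashes of all declared
    outputs — enough to re-run the command bitwise and verify its products.
    """

    command: str
    config: dict
    seeds: dict
    version: str = ""
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stages: list = field(default_factory=list)    # (stage, unix time)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path) -> None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"declared output {p} does not exist")
        self.outputs[str(p)] = _sha256(p)

    def stamp(self, stage: str) -> None:
        self.stages.append([stage, _time.time()])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def verify_outputs(self) -> bool:
        """True iff every declared output is present with a matching hash."""
        for p, h in self.outputs.items():
            if not Path(p).exists() or _sha256(Path(p)) != h:
                return False
        return True
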