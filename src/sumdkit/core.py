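"""Domain types and geometric primitives for receptor–ligand trajectories.

Conventions used throughout the package:

* coordinates in Å, times in ps internally (ns in user-facing reports),
  energies in kcal/mol, masses in amu;
* frame indexing is 0-based; report-generating code additionally prints
  1-based frame numbers;
* superposition is mass-weighted by default and never returns a reflection
  (molecular chirality must be preserved);
* residue identity is the triple (chain, residue number, insertion code),
  so ``97`` and ``97A`` are distinct residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


class SelectionError(ValueError):
    """An atom selection failed to resolve to a non-empty index list."""


class DegenerateGeometryError(ValueError):
    """Superposition input is degenerate (too few or collinear points)."""


# ---------------------------------------------------------------------------
# Structures and selections
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Static topology: per-atom identity, mass, charge, LJ parameters, coords.

    Arrays are columnar over atoms; ``coords`` is (n_atoms, 3) in Å.
    ``(chain_id, residue_number, insertion_code, atom_name)`` must be unique.
    """

    atom_name: list[str]
    element: list[str]
    residue_name: list[str]
    residue_number: np.ndarray
    insertion_code: list[str]
    chain_id: list[str]
    mass: np.ndarray
    coords: np.ndarray
    charge: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.mass = np.asarray(self.mass, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if self.charge is None:
            self.charge = np.zeros(n)
        self.charge = np.asarray(self.charge, dtype=float)
        for name, arr in [("element", self.element), ("residue_name", self.residue_name),
                          ("insertion_code", self.insertion_code), ("chain_id", self.chain_id)]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if not np.all(self.mass > 0):
            raise ValueError("all atom masses must be > 0")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = set(self.atom_keys())
        if len(keys) != n:
            raise ValueError("(chain, residue number, insertion code, atom name) must be unique per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def atom_keys(self) -> list[tuple[str, int, str, str]]:
        return [
            (self.chain_id[i], int(self.residue_number[i]), self.insertion_code[i], self.atom_name[i])
            for i in range(self.n_atoms)
        ]

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=np.asarray(coords, dtype=float))


def parse_residue_spec(spec: str) -> tuple[str, int, str]:
    """Parse a ``chain/resnum/icode`` residue address, e.g. ``A/97/A``.

    The insertion-code slot may be empty (``A/219/``) or omitted (``A/219``).
    """
    parts = spec.split("/")
    if len(parts) == 2:
        parts.append("")
    if len(parts) != 3 or not parts[0]:
        raise SelectionError(f"bad residue spec {spec!r}; expected chain/resnum/icode")
    try:
        num = int(parts[1])
    except ValueError as exc:
        raise SelectionError(f"bad residue number in spec {spec!r}") from exc
    return parts[0], num, parts[2]


@dataclass(frozen=True)
class AtomSelection:
    """Selects atoms either by explicit indices or by a predicate.

    The predicate is the intersection of any of: chains, residues
    (``chain/resnum/icode`` triples), and atom names. Resolution against a
    structure always yields a strictly increasing, duplicate-free, non-empty
    index list; anything else raises :class:`SelectionError`.
    """

    indices: tuple[int, ...] | None = None
    chains: tuple[str, ...] | None = None
    residues: tuple[tuple[str, int, str], ...] | None = None
    atom_names: tuple[str, ...] | None = None
    label: str = ""

    @classmethod
    def from_indices(cls, indices: Iterable[int], label: str = "") -> "AtomSelection":
        return cls(indices=tuple(int(i) for i in indices), label=label)

    @classmethod
    def from_residues(cls, specs: Iterable[str], label: str = "") -> "AtomSelection":
        return cls(residues=tuple(parse_residue_spec(s) for s in specs), label=label)

    @classmethod
    def from_chain(cls, chain: str, label: str = "") -> "AtomSelection":
        return cls(chains=(chain,), label=label)

    def resolve(self, structure: StructureModel) -> np.ndarray:
        name = self.label or "selection"
        if self.indices is not None:
            idx = np.asarray(self.indices, dtype=int)
            if idx.size == 0:
                raise SelectionError(f"{name}: empty explicit index list")
            if np.any(idx < 0) or np.any(idx >= structure.n_atoms):
                raise SelectionError(f"{name}: index out of range for {structure.n_atoms} atoms")
            if np.any(np.diff(idx) <= 0):
                idx = np.unique(idx)
            return idx
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(np.asarray(structure.chain_id), list(self.chains))
        if self.residues is not None:
            want = set(self.residues)
            res_keys = [
                (structure.chain_id[i], int(structure.residue_number[i]), structure.insertion_code[i])
                for i in range(structure.n_atoms)
            ]
            mask &= np.array([k in want for k in res_keys])
        if self.atom_names is not None:
            mask &= np.isin(np.asarray(structure.atom_name), list(self.atom_names))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"{name}: resolved to no atoms")
        return idx


@dataclass
class Trajectory:
    """Time-ordered coordinate frames (ps) over a fixed atom set (Å)."""

    coords: np.ndarray            # (n_frames, n_atoms, 3)
    times_ps: np.ndarray          # strictly increasing
    box: np.ndarray | None = None  # optional per-frame orthorhombic lengths
    tag: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.times_ps.shape != (self.coords.shape[0],):
            raise ValueError("times must match frame count")
        if self.coords.shape[0] > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return self.times_ps / 1000.0

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    @classmethod
    def concatenate(cls, parts: Sequence["Trajectory"], tag: str = "") -> "Trajectory":
        if not parts:
            raise ValueError("nothing to concatenate")
        coords = np.concatenate([p.coords for p in parts], axis=0)
        times = np.concatenate([p.times_ps for p in parts])
        return cls(coords=coords, times_ps=times, tag=tag or parts[0].tag)


@dataclass
class RMSDMatrix:
    """Frame-against-frame RMSD grid (Å) between two trajectories."""

    values: np.ndarray            # (n_A, n_B), Å, >= 0
    times_a_ps: np.ndarray
    times_b_ps: np.ndarray
    tag_a: str = ""
    tag_b: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < -1e-12):
            raise ValueError("RMSD matrix entries must be finite and non-negative")

    def argmin(self) -> tuple[int, int, float]:
        """Return (row, col, value) of the global minimum."""
        i, j = np.unravel_index(np.argmin(self.values), self.values.shape)
        return int(i), int(j), float(self.values[i, j])

    def to_csv(self, path) -> None:
        """Write the grid with row/col headers equal to frame times in ns."""
        import pandas as pd

        df = pd.DataFrame(
            self.values,
            index=np.round(self.times_a_ps / 1000.0, 6),
            columns=np.round(self.times_b_ps / 1000.0, 6),
        )
        df.index.name = f"{self.tag_a or 'A'}_time_ns"
        df.to_csv(path)

    def to_heatmap_png(self, path, title: str | None = None) -> None:
        from matplotlib.backends.backend_agg import FigureCanvasAgg
        from matplotlib.figure import Figure

        fig = Figure(figsize=(6, 5))
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)
        im = ax.imshow(self.values, aspect="auto", origin="lower", cmap="viridis",
                       extent=(self.times_b_ps[0] / 1e3, self.times_b_ps[-1] / 1e3,
                               self.times_a_ps[0] / 1e3, self.times_a_ps[-1] / 1e3))
        ax.set_xlabel(f"{self.tag_b or 'B'} time (ns)")
        ax.set_ylabel(f"{self.tag_a or 'A'} time (ns)")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax, label="ligand RMSD (Å)")
        fig.savefig(path, dpi=120)


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

def center_of_mass(
    structure: StructureModel,
    selection: AtomSelection,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted centroid Σ mᵢxᵢ / Σ mᵢ over the selected atoms.

    ``coords`` overrides the structure's own coordinates (e.g. a trajectory
    frame over the same atom set).
    """
    idx = selection.resolve(structure)
    x = (structure.coords if coords is None else np.asarray(coords, dtype=float))[idx]
    m = structure.mass[idx]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def superpose_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    weighted least-squares sense. The rotation is always proper
    (det = +1); reflections are disallowed.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or a
    collinear point set, where the rotation is not uniquely determined.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mob).sum(axis=0) / wsum
    cr = (w[:, None] * ref).sum(axis=0) / wsum
    a = mob - cm
    b = ref - cr
    # collinearity check on both point sets
    for pts in (a, b):
        s = np.linalg.svd(pts * np.sqrt(w)[:, None], compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            raise DegenerateGeometryError("points are collinear; rotation underdetermined")
    h = (w[:, None] * a).T @ b           # 3x3 covariance, mobile -> reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = a @ rot.T + cr
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum() / wsum))
    return rot, trans, rmsd


def _rmsd(x: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    d2 = ((x - y) ** 2).sum(axis=1)
    if w is None:
        return float(np.sqrt(d2.mean()))
    return float(np.sqrt((w * d2).sum() / w.sum()))


def ligand_rmsd(
    frame: np.ndarray,
    reference_frame: np.ndarray,
    structure: StructureModel,
    fit_selection: AtomSelection,
    measure_selection: AtomSelection,
    mass_weighted: bool = True,
) -> float:
    """Binding-mode RMSD: fit on one selection, measure on another.

    The frame is superposed onto the reference over ``fit_selection``
    (typically the receptor) and the RMSD is then evaluated over
    ``measure_selection`` (typically the ligand) without refitting, so the
    value reflects pose similarity rather than global displacement.
    """
    frame = np.asarray(frame, dtype=float)
    reference_frame = np.asarray(reference_frame, dtype=float)
    if frame.shape != reference_frame.shape:
        raise ValueError("frame and reference must share the atom set")
    fit_idx = fit_selection.resolve(structure)
    meas_idx = measure_selection.resolve(structure)
    w_fit = structure.mass[fit_idx] if mass_weighted else None
    rot, trans, _ = superpose_kabsch(frame[fit_idx], reference_frame[fit_idx], w_fit)
    moved = frame[meas_idx] @ rot.T + trans
    w_meas = structure.mass[meas_idx] if mass_weighted else None
    return _rmsd(moved, reference_frame[meas_idx], w_meas)


def rmsd_matrix(
    traj_a: Trajectory,
    traj_b: Trajectory,
    structure: StructureModel,
    fit_selection: AtomSelection,
    measure_selection: AtomSelection,
    mass_weighted: bool = True,
) -> RMSDMatrix:
    """All-against-all binding-mode RMSD between two trajectories.

    Entry (i, j) is :func:`ligand_rmsd` between frame i of ``traj_a`` and
    frame j of ``traj_b``. Used to compare a supervised replica against a
    reference unsupervised trajectory frame by frame.
    """
    if traj_a.n_atoms != traj_b.n_atoms or traj_a.n_atoms != structure.n_atoms:
        raise ValueError("trajectories and structure must share the atom count")
    vals = np.empty((traj_a.n_frames, traj_b.n_frames))
    for i in range(traj_a.n_frames):
        for j in range(traj_b.n_frames):
            vals[i, j] = ligand_rmsd(
                traj_a.coords[i], traj_b.coords[j], structure,
                fit_selection, measure_selection, mass_weighted,
            )
    return RMSDMatrix(values=vals, times_a_ps=traj_a.times_ps, times_b_ps=traj_b.times_ps,
                      tag_a=traj_a.tag, tag_b=traj_b.tag)


def substructure_flexibility_rmsd(
    traj: Trajectory,
    structure: StructureModel,
    anchor_selection: AtomSelection,
    measure_selection: AtomSelection,
    mass_weighted: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Internal-flexibility RMSD series against the first frame.

    Every frame is aligned on ``anchor_selection`` of frame 0 (e.g. the
    atoms of a shared macrocycle ring) and the RMSD is measured over
    ``measure_selection``. Rigid-body motion is removed by the alignment, so
    the series quantifies internal distortion only; frame 0 is exactly 0.

    Returns ``(per_frame_series, mean, sd)``.
    """
    if traj.n_frames < 2:
        raise ValueError("flexibility analysis needs at least 2 frames")
    anchor_idx = anchor_selection.resolve(structure)
    meas_idx = measure_selection.resolve(structure)
    ref = traj.coords[0]
    w_fit = structure.mass[anchor_idx] if mass_weighted else None
    w_meas = structure.mass[meas_idx] if mass_weighted else None
    out = np.empty(traj.n_frames)
    out[0] = 0.0
    for i in range(1, traj.n_frames):
        rot, trans, _ = superpose_kabsch(traj.coords[i][anchor_idx], ref[anchor_idx], w_fit)
        moved = traj.coords[i][meas_idx] @ rot.T + trans
        out[i] = _rmsd(moved, ref[meas_idx], w_meas)
    return out, float(out.mean()), float(out.std(ddof=1))
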