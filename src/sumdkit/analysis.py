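"""Post-processing of recognition trajectories.

The chain mirrors how recognition campaigns are analysed in practice:
replica trajectories are aligned on a common receptor reference, merged and
strided into a pose matrix; sparse outlier poses are discarded by a cosine
similarity pre-filter; the remaining poses are clustered with the
density-based OPTICS algorithm; each cluster is summarised by its size, its
mean per-frame binding energy and a representative pose (the member with
the most favourable energy). Separate tools detect metastable stopover
events on the dcm(t) profile, bin frames into an energy-vs-distance
landscape, aggregate binding-energy summaries over time windows and extract
hydrogen-bond distance series.

Energies come from a pluggable per-frame scorer: the built-in nonbonded
interaction energy for toy systems, or an imported per-frame table (CSV)
for energies computed outside the package, e.g. end-point MM-GBSA values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import OPTICS
from sklearn.metrics.pairwise import cosine_similarity

from .core import AtomSelection, StructureModel, Trajectory, superpose_kabsch
from .toysim import ToySystemSpec, interaction_energy


# ---------------------------------------------------------------------------
# Energy scorers (built-in nonbonded | imported table)
# ---------------------------------------------------------------------------

class NonbondedScorer:
    """Scores a frame by the toy model's ligand–receptor interaction energy."""

    name = "builtin-nonbonded"

    def __init__(self, spec: ToySystemSpec):
        self.spec = spec

    def __call__(self, frame: np.ndarray) -> float:
        return interaction_energy(frame, self.spec)

    def score_trajectory(self, traj: Trajectory) -> np.ndarray:
        return np.array([self(traj.coords[i]) for i in range(traj.n_frames)])


class TableScorer:
    """Per-frame energies imported from a table (frame_index, time_ns, dG_kcal_mol)."""

    name = "imported-table"

    def __init__(self, energies: np.ndarray):
        self.energies = np.asarray(energies, dtype=float)

    @classmethod
    def from_csv(cls, path) -> "TableScorer":
        df = pd.read_csv(path)
        required = {"frame_index", "dG_kcal_mol"}
        if not required.issubset(df.columns):
            raise ValueError(f"energy CSV needs columns {sorted(required)}; "
                             f"got {list(df.columns)}")
        df = df.sort_values("frame_index")
        idx = df["frame_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError("frame_index must be the contiguous range 0..n-1")
        return cls(df["dG_kcal_mol"].to_numpy())

    def score_trajectory(self, traj: Trajectory) -> np.ndarray:
        if len(self.energies) != traj.n_frames:
            raise ValueError(
                f"energy table has {len(self.energies)} rows but the trajectory "
                f"has {traj.n_frames} frames")
        return self.energies.copy()


def _frame_energies(traj: Trajectory, scorer) -> np.ndarray:
    if hasattr(scorer, "score_trajectory"):
        return np.asarray(scorer.score_trajectory(traj), dtype=float)
    if callable(scorer):
        return np.array([scorer(traj.coords[i]) for i in range(traj.n_frames)])
    arr = np.asarray(scorer, dtype=float)
    if arr.shape != (traj.n_frames,):
        raise ValueError("scorer array must have one energy per frame")
    return arr


# ---------------------------------------------------------------------------
# Pose matrix
# ---------------------------------------------------------------------------

@dataclass
class PoseMatrix:
    """Per-frame flattened ligand coordinates after receptor alignment.

    Each row is one ligand pose (3 × n_ligand_atoms values) with
    (replica/tag, frame, time) provenance; rows come from every stride-th
    frame of the merged input trajectories.
    """

    rows: np.ndarray                      # (n_rows, 3 * n_ligand_atoms)
    provenance: pd.DataFrame              # columns: tag, frame_index, time_ps
    stride: int
    n_ligand_atoms: int

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[1] != 3 * self.n_ligand_atoms:
            raise ValueError("row length must be 3 × n_ligand_atoms")
        if len(self.provenance) != self.rows.shape[0]:
            raise ValueError("provenance must have one entry per row")
        dup = self.provenance.duplicated(["tag", "frame_index"]).any()
        if dup:
            raise ValueError("provenance must be unique per row")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def subset(self, keep: np.ndarray) -> "PoseMatrix":
        return PoseMatrix(self.rows[keep],
                          self.provenance.iloc[keep].reset_index(drop=True),
                          self.stride, self.n_ligand_atoms)


def build_pose_matrix(
    trajectories: Sequence[Trajectory],
    structure: StructureModel,
    reference_frame: np.ndarray,
    ligand_selection: AtomSelection,
    fit_selection: AtomSelection,
    stride: int = 10,
    mass_weighted: bool = True,
) -> PoseMatrix:
    """Merge, align and stride trajectories into a pose matrix.

    Every stride-th frame of every trajectory is superposed on the
    reference receptor (``fit_selection``) and the ligand coordinates are
    flattened into one row. A stride of 10 keeps every tenth frame.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    lig_idx = ligand_selection.resolve(structure)
    fit_idx = fit_selection.resolve(structure)
    w = structure.mass[fit_idx] if mass_weighted else None
    ref = np.asarray(reference_frame, dtype=float)
    rows = []
    prov = []
    for t_i, traj in enumerate(trajectories):
        if traj.n_atoms != structure.n_atoms:
            raise ValueError(f"trajectory {t_i} does not match the topology "
                             f"({traj.n_atoms} atoms vs {structure.n_atoms})")
        tag = traj.tag or f"traj-{t_i}"
        for f in range(0, traj.n_frames, stride):
            frame = traj.coords[f]
            rot, trans, _ = superpose_kabsch(frame[fit_idx], ref[fit_idx], w)
            rows.append((frame[lig_idx] @ rot.T + trans).ravel())
            prov.append((tag, f, traj.times_ps[f]))
    return PoseMatrix(
        rows=np.asarray(rows),
        provenance=pd.DataFrame(prov, columns=["tag", "frame_index", "time_ps"]),
        stride=stride, n_ligand_atoms=lig_idx.size)


# ---------------------------------------------------------------------------
# Noise pre-filter and clustering
# ---------------------------------------------------------------------------

def filter_noise_cosine(
    matrix: PoseMatrix,
    similarity_threshold: float = 0.01,
    neighbor_count: int = 5,
) -> tuple[PoseMatrix, np.ndarray]:
    """Discard isolated pose rows by a k-NN maximum cosine-similarity rule.

    Rows are centred (their scalar mean subtracted) and a row is flagged as
    noise iff the maximum cosine similarity to its ``neighbor_count``
    nearest neighbours falls below the threshold. Duplicated rows are
    always mutually similar (similarity 1) and never flagged. Returns the
    kept matrix and the indices of the discarded rows.
    """
    n = matrix.n_rows
    if n < 2:
        raise ValueError("need at least 2 rows")
    if neighbor_count >= n:
        raise ValueError(f"neighbor_count {neighbor_count} must be < n rows {n}")
    x = matrix.rows - matrix.rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    sim = np.zeros((n, n))
    ok = norms > 1e-12
    if ok.any():
        sim[np.ix_(ok, ok)] = cosine_similarity(x[ok])
    if (~ok).any():
        # degenerate (all-equal-coordinate) rows: similar only to exact twins
        bad = np.flatnonzero(~ok)
        for i in bad:
            same = np.all(matrix.rows == matrix.rows[i], axis=1)
            sim[i, same] = 1.0
            sim[same, i] = 1.0
    np.fill_diagonal(sim, -np.inf)
    # max over the k nearest (by cosine) equals the max over the top-k values
    kmax = np.sort(sim, axis=1)[:, -neighbor_count:].max(axis=1)
    noise = np.flatnonzero(kmax < similarity_threshold - 1e-9)
    keep = np.setdiff1d(np.arange(n), noise)
    if keep.size == 0:
        raise ValueError("noise filter discarded every row; threshold too strict")
    return matrix.subset(keep), noise


@dataclass
class ClusterResult:
    """Noise-filtered pose clusters with energetics and representatives."""

    labels: np.ndarray                    # -1 = noise
    provenance: pd.DataFrame
    params: dict
    table: pd.DataFrame | None = None     # filled by rank_cluster_representatives

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels >= 0])

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def table_report(self) -> pd.DataFrame:
        """Cluster summary with integer-rounded mean energies.

        Columns: cluster (1-based), n_frames, mean_dG_kcal_mol_rounded.
        """
        if self.table is None:
            raise ValueError("energetics not computed yet; call "
                             "rank_cluster_representatives first")
        out = self.table.copy()
        out["cluster"] = out["cluster_id"] + 1
        out["mean_dG_kcal_mol_rounded"] = out["mean_energy"].round().astype(int)
        return out[["cluster", "n_frames", "mean_dG_kcal_mol_rounded"]]


def cluster_poses(
    matrix: PoseMatrix,
    min_samples: int = 10,
    max_eps: float = np.inf,
    xi: float = 0.05,
) -> ClusterResult:
    """Density-based pose clustering via OPTICS reachability ordering.

    Uses xi-extraction on the reachability plot; sparse rows get label −1.
    A degenerate all-identical input collapses to a single cluster.
    Deterministic given inputs and parameters.
    """
    if matrix.n_rows < min_samples:
        raise ValueError(f"need at least min_samples={min_samples} rows")
    x = matrix.rows
    if np.allclose(x, x[0], atol=1e-12):
        labels = np.zeros(matrix.n_rows, dtype=int)
    else:
        opt = OPTICS(min_samples=min_samples, max_eps=max_eps, xi=xi)
        labels = opt.fit_predict(x)
    return ClusterResult(
        labels=labels, provenance=matrix.provenance.copy(),
        params={"min_samples": min_samples, "max_eps": max_eps, "xi": xi,
                "algorithm": "OPTICS/xi"})


def rank_cluster_representatives(
    clusters: ClusterResult,
    energies: np.ndarray,
) -> ClusterResult:
    """Attach energetics: per-cluster size, mean and min energy, representative.

    The representative of each cluster is its member with the most
    favourable (minimum) energy. ``energies`` is aligned with the cluster
    rows; missing (NaN) energies on clustered rows are an error.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.shape != clusters.labels.shape:
        raise ValueError("energies must align with cluster rows")
    missing = np.flatnonzero(np.isnan(energies) & (clusters.labels >= 0))
    if missing.size:
        raise ValueError(f"missing energies for clustered rows {missing.tolist()}")
    rows = []
    for cid in clusters.cluster_ids:
        mem = clusters.members(cid)
        e = energies[mem]
        rep = int(mem[np.argmin(e)])
        rows.append({"cluster_id": int(cid), "n_frames": int(mem.size),
                     "mean_energy": float(e.mean()), "min_energy": float(e.min()),
                     "representative_row": rep})
    table = pd.DataFrame(rows)
    return ClusterResult(labels=clusters.labels, provenance=clusters.provenance,
                         params=dict(clusters.params), table=table)


# ---------------------------------------------------------------------------
# Metastable events
# ---------------------------------------------------------------------------

@dataclass
class MetastableEvent:
    """A stopover with measurable residence time en route to the site."""

    start_ps: float
    end_ps: float
    mean_dcm: float
    median_dcm: float
    mean_energy: float

    @property
    def residence_ps(self) -> float:
        return self.end_ps - self.start_ps

    @property
    def residence_ns(self) -> float:
        return self.residence_ps / 1000.0


def detect_metastable_events(
    times_ps: np.ndarray,
    dcm: np.ndarray,
    energies: np.ndarray | None = None,
    min_residence_ps: float = 50.0,
    dcm_band: float = 2.0,
    exclude_below: float = 5.0,
) -> list[MetastableEvent]:
    """Find dcm plateaus with enough residence time to count as metastable.

    An event is a maximal contiguous interval whose dcm samples all stay
    within ±``dcm_band`` of the interval median, lasting at least
    ``min_residence_ps``, with median dcm above ``exclude_below`` (so the
    final bound state is not reported as a stopover). Events are
    non-overlapping and time-ordered.
    """
    t = np.asarray(times_ps, dtype=float)
    d = np.asarray(dcm, dtype=float)
    if t.shape != d.shape:
        raise ValueError("times and dcm series must align")
    e = None if energies is None else np.asarray(energies, dtype=float)
    if e is not None and e.shape != d.shape:
        raise ValueError("energy series must align with dcm series")
    n = t.size
    events: list[MetastableEvent] = []
    i = 0
    while i < n - 1:
        j = i + 1
        while j < n:
            med = np.median(d[i:j + 1])
            if np.all(np.abs(d[i:j + 1] - med) <= dcm_band):
                j += 1
            else:
                break
        j -= 1  # last index still satisfying the band
        med = np.median(d[i:j + 1])
        if (t[j] - t[i] >= min_residence_ps) and (med > exclude_below):
            events.append(MetastableEvent(
                start_ps=float(t[i]), end_ps=float(t[j]),
                mean_dcm=float(d[i:j + 1].mean()), median_dcm=float(med),
                mean_energy=float(e[i:j + 1].mean()) if e is not None else float("nan")))
            i = j + 1
        else:
            i += 1
    return events


def events_to_frame(events: Sequence[MetastableEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start_ns": ev.start_ps / 1e3, "end_ns": ev.end_ps / 1e3,
        "residence_ns": ev.residence_ns, "mean_dcm_A": ev.mean_dcm,
        "median_dcm_A": ev.median_dcm, "mean_energy_kcal_mol": ev.mean_energy,
    } for ev in events])


# ---------------------------------------------------------------------------
# Energy landscape and summaries
# ---------------------------------------------------------------------------

@dataclass
class LandscapeGrid:
    """2-D histogram of frames over (dcm, interaction energy)."""

    counts: np.ndarray           # (n_dcm_bins, n_energy_bins)
    dcm_edges: np.ndarray
    energy_edges: np.ndarray
    min_energy_profile: np.ndarray   # per-dcm-bin minimum energy (NaN if empty)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dcm_edges) <= 0) or np.any(np.diff(self.energy_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        centers_d = 0.5 * (self.dcm_edges[:-1] + self.dcm_edges[1:])
        centers_e = 0.5 * (self.energy_edges[:-1] + self.energy_edges[1:])
        df = pd.DataFrame(self.counts, index=np.round(centers_d, 4),
                          columns=np.round(centers_e, 4))
        df.index.name = "dcm_A"
        df.to_csv(path)

    def to_png(self, path, title: str | None = None) -> None:
        from matplotlib.backends.backend_agg import FigureCanvasAgg
        from matplotlib.figure import Figure

        fig = Figure(figsize=(6, 5))
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)
        im = ax.pcolormesh(self.dcm_edges, self.energy_edges, self.counts.T,
                           cmap="inferno")
        centers = 0.5 * (self.dcm_edges[:-1] + self.dcm_edges[1:])
        ax.plot(centers, self.min_energy_profile, "c.-", lw=1,
                label="per-bin minimum")
        ax.set_xlabel("dcm ligand–site (Å)")
        ax.set_ylabel("interaction energy (kcal/mol)")
        ax.legend(loc="upper right", fontsize=8)
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax, label="frames")
        fig.savefig(path, dpi=120)


def energy_landscape(
    trajectory: Trajectory,
    structure: StructureModel,
    ligand_selection: AtomSelection,
    site_selection: AtomSelection,
    scorer,
    dcm_bins: np.ndarray | int = 40,
    energy_bins: np.ndarray | int = 40,
) -> LandscapeGrid:
    """Bin trajectory frames into an energy-vs-distance landscape.

    Local minima of the per-dcm-bin minimum-energy profile at distances
    above the bound state reveal metastable patches. Counts always sum to
    the number of frames analysed.
    """
    from .supervisor import dcm_series

    _, d = dcm_series(trajectory, structure, ligand_selection, site_selection)
    e = _frame_energies(trajectory, scorer)
    counts, d_edges, e_edges = np.histogram2d(d, e, bins=(dcm_bins, energy_bins))
    prof = np.full(len(d_edges) - 1, np.nan)
    which = np.clip(np.digitize(d, d_edges) - 1, 0, len(d_edges) - 2)
    for b in range(len(d_edges) - 1):
        sel = which == b
        if sel.any():
            prof[b] = e[sel].min()
    return LandscapeGrid(counts=counts, dcm_edges=d_edges, energy_edges=e_edges,
                         min_energy_profile=prof)


@dataclass
class EnergySummary:
    """Mean binding energy over a time window, with provenance of the scorer."""

    t0_ns: float
    t1_ns: float
    mean_kcal_mol: float
    sd_kcal_mol: float
    n_frames: int
    scorer: str

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("summary needs at least one frame")


#: two binding-energy estimates closer than this are not meaningfully different
DDG_MEANINGFUL_KCAL = 5.0


def binding_energy_summary(
    trajectory: Trajectory,
    window_ns: tuple[float, float],
    scorer,
) -> EnergySummary:
    """Mean ± sd of the per-frame binding energy over a time window (ns)."""
    t0, t1 = window_ns
    times = trajectory.times_ns
    sel = (times >= t0) & (times <= t1)
    if not sel.any():
        raise ValueError(f"no frames in window [{t0}, {t1}] ns")
    e = _frame_energies(trajectory, scorer)[sel]
    name = getattr(scorer, "name", "array")
    return EnergySummary(t0_ns=float(t0), t1_ns=float(t1),
                         mean_kcal_mol=float(e.mean()),
                         sd_kcal_mol=float(e.std(ddof=1)) if e.size > 1 else 0.0,
                         n_frames=int(e.size), scorer=name)


def ddg_comparison(a: EnergySummary | float, b: EnergySummary | float,
                   threshold: float = DDG_MEANINGFUL_KCAL) -> tuple[float, bool]:
    """ΔΔG between two binding-energy estimates and whether it is meaningful.

    Returns ``(ddg, meaningful)`` with ``meaningful`` true iff
    ``|ΔΔG| >= threshold`` (default 5 kcal/mol).
    """
    ea = a.mean_kcal_mol if isinstance(a, EnergySummary) else float(a)
    eb = b.mean_kcal_mol if isinstance(b, EnergySummary) else float(b)
    ddg = ea - eb
    return float(ddg), bool(abs(ddg) >= threshold)


# ---------------------------------------------------------------------------
# Hydrogen-bond distance series
# ---------------------------------------------------------------------------

def hbond_distance_series(
    trajectory: Trajectory,
    structure: StructureModel,
    donor_hydrogen: AtomSelection | int,
    acceptor: AtomSelection | int,
) -> tuple[np.ndarray, float, float]:
    """Per-frame H···acceptor distance (Å) with mean ± sd.

    Tracks a single hydrogen-bond geometry over time, e.g. an internal
    H-bond that rigidifies a macrocycle.
    """
    def one_atom(sel, what) -> int:
        if isinstance(sel, (int, np.integer)):
            if not 0 <= sel < structure.n_atoms:
                raise ValueError(f"{what} atom index {sel} out of range")
            return int(sel)
        idx = sel.resolve(structure)
        if idx.size != 1:
            raise ValueError(f"{what} selection must resolve to exactly one atom")
        return int(idx[0])

    h = one_atom(donor_hydrogen, "donor hydrogen")
    a = one_atom(acceptor, "acceptor")
    d = np.linalg.norm(trajectory.coords[:, h] - trajectory.coords[:, a], axis=1)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return d, float(d.mean()), sd
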