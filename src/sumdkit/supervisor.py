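"""The SuMD supervision loop: tabu-like window acceptance on the COM distance.

A supervised run alternates short unbiased MD windows with an acceptance
test on dcm, the distance between the ligand center of mass and the
binding-site center of mass. A window is kept only when the least-squares
slope of its dcm samples is below a threshold (default 0: the ligand must,
on balance, approach the site); otherwise the window is discarded, the
system is restored to the last accepted checkpoint and velocities are
redrawn from Maxwell–Boltzmann with a fresh deterministic seed. Below a
disengagement distance the supervision is switched off and every window is
accepted, letting the ligand settle and rearrange inside the site.

The loop talks to the propagation backend through a narrow contract
(state in → frames out), so an external engine adapter can replace the
built-in coarse-grained backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtomSelection, StructureModel, Trajectory, center_of_mass, ligand_rmsd
from .toysim import (
    SimState,
    ToySystemSpec,
    _mobile_param_pack,
    _rng_from_seed,
    maxwell_boltzmann_velocities,
    propagate_langevin,
)


class IntegrityError(RuntimeError):
    """A stored supervision log is internally inconsistent."""


@dataclass
class SupervisionConfig:
    """The supervision rulebook.

    ``window_length_ps`` defaults to 600 ps with 1000 ps as the common
    alternative — appropriate for all-atom systems; the coarse-grained
    funnel uses much shorter windows (see :func:`funnel_supervision_config`)
    because its diffusive time scales are ~100× shorter.
    """

    ligand_selection: AtomSelection | None = None   # None: system's ligand beads
    site_selection: AtomSelection | None = None     # None: system's planted site
    window_length_ps: float = 600.0
    dcm_samples_per_window: int = 10
    slope_threshold: float = 0.0          # Å/ps; accept iff slope < threshold
    max_consecutive_rejections: int = 30
    success_distance: float = 5.0         # Å, COM–COM arrival threshold
    supervision_off_distance: float | None = None   # default = success_distance
    max_total_windows: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length_ps <= 0:
            raise ValueError("window_length_ps must be > 0")
        if self.dcm_samples_per_window < 2:
            raise ValueError("dcm_samples_per_window must be >= 2")
        if self.success_distance <= 0:
            raise ValueError("success_distance must be > 0")
        if not np.isfinite(self.slope_threshold):
            raise ValueError("slope_threshold must be finite")

    @property
    def off_distance(self) -> float:
        return (self.success_distance if self.supervision_off_distance is None
                else self.supervision_off_distance)


def funnel_supervision_config(
    window_length_ps: float = 20.0,
    max_total_windows: int = 100,
    base_seed: int = 0,
    **overrides,
) -> SupervisionConfig:
    """Supervision defaults scaled to the coarse-grained funnel system."""
    return SupervisionConfig(window_length_ps=window_length_ps,
                             max_total_windows=max_total_windows,
                             base_seed=base_seed, **overrides)


@dataclass
class WindowRecord:
    """Audit record of one attempted window."""

    index: int
    start_time_ps: float            # productive time at window start
    sample_times_ps: np.ndarray     # offsets within the window
    dcm_samples: np.ndarray         # Å
    slope: float                    # Å/ps
    accepted: bool
    rejections_so_far: int          # consecutive rejections before this window
    seed: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sample_times_ps"] = self.sample_times_ps.tolist()
        d["dcm_samples"] = self.dcm_samples.tolist()
        d["seed"] = list(self.seed)
        return d


@dataclass
class SuMDResult:
    """Full audit log of one supervised run."""

    trajectory: Trajectory | None     # productive frames (accepted windows only)
    windows: list[WindowRecord]
    outcome: str                      # bound | failed | exhausted
    productive_time_ps: float
    windows_attempted: int
    windows_accepted: int
    time_to_binding_ps: float | None
    final_dcm: float
    config: SupervisionConfig
    replica: int = 0
    final_state: SimState | None = None   # last accepted checkpoint

    @property
    def productive_time_ns(self) -> float:
        return self.productive_time_ps / 1000.0

    @property
    def time_to_binding_ns(self) -> float | None:
        return None if self.time_to_binding_ps is None else self.time_to_binding_ps / 1000.0

    def window_log_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for w in self.windows:
                fh.write(json.dumps(w.to_dict()) + "\n")


# ---------------------------------------------------------------------------
# Supervision primitives
# ---------------------------------------------------------------------------

def dcm_series(
    trajectory: Trajectory,
    structure: StructureModel,
    ligand_selection: AtomSelection,
    site_selection: AtomSelection,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame distance between ligand COM and site COM.

    Returns ``(times_ps, distances_Å)``.
    """
    lig = ligand_selection.resolve(structure)
    site = site_selection.resolve(structure)
    ml = structure.mass[lig]
    ms = structure.mass[site]
    com_l = (ml[None, :, None] * trajectory.coords[:, lig]).sum(axis=1) / ml.sum()
    com_s = (ms[None, :, None] * trajectory.coords[:, site]).sum(axis=1) / ms.sum()
    return trajectory.times_ps.copy(), np.linalg.norm(com_l - com_s, axis=1)


def fit_dcm_slope(times: np.ndarray, distances: np.ndarray) -> float:
    """Ordinary least-squares slope (Å/ps) of distance versus time."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if t.size < 2 or d.size != t.size:
        raise ValueError("need >= 2 paired samples")
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom <= 0:
        raise ValueError("all sample times equal; slope undefined")
    return float((tc * (d - d.mean())).sum() / denom)


def window_accepted(record: WindowRecord, config: SupervisionConfig) -> bool:
    """Tabu-like acceptance: productive slope, or supervision disengaged.

    True iff the dcm slope is below the threshold, or every sample already
    lies below the disengagement distance (the ligand is settling in the
    site). A slope exactly at the threshold rejects.
    """
    if bool(np.all(record.dcm_samples < config.off_distance)):
        return True
    return record.slope < config.slope_threshold


# ---------------------------------------------------------------------------
# The supervised run
# ---------------------------------------------------------------------------

def supervised_run(
    spec: ToySystemSpec,
    state0: SimState,
    config: SupervisionConfig,
    replica: int = 0,
    keep_trajectory: bool = True,
) -> SuMDResult:
    """Run one supervised recognition simulation on the toy backend.

    Terminates ``bound`` when every dcm sample of a committed window is
    below the success distance (arrival sustained for one full window),
    ``failed`` after ``max_consecutive_rejections`` consecutive rejected
    windows, or ``exhausted`` when the window budget runs out. The same
    (spec, config, base seed, replica) reproduces the result bitwise.
    """
    structure = spec.to_structure()
    lig_sel = config.ligand_selection or spec.ligand_selection()
    site_sel = config.site_selection or spec.site_selection()
    lig_idx = lig_sel.resolve(structure)
    site_idx = site_sel.resolve(structure)
    ml = structure.mass[lig_idx]
    ms = structure.mass[site_idx]

    def dcm_of(frame: np.ndarray) -> float:
        cl = (ml[:, None] * frame[lig_idx]).sum(axis=0) / ml.sum()
        cs = (ms[:, None] * frame[site_idx]).sum(axis=0) / ms.sum()
        return float(np.linalg.norm(cl - cs))

    if dcm_of(state0.coords) <= config.success_distance:
        raise ValueError(
            f"initial dcm {dcm_of(state0.coords):.2f} Å is already below the "
            f"success distance {config.success_distance} Å")

    dt = spec.timestep
    samples = config.dcm_samples_per_window
    steps_per_window = max(samples, int(round(config.window_length_ps / dt)))
    record_every = max(1, steps_per_window // samples)
    steps_per_window = record_every * samples
    window_ps = steps_per_window * dt

    pack = _mobile_param_pack(spec)
    mob = pack["mob"]

    checkpoint = state0.copy()
    windows: list[WindowRecord] = []
    kept_frames: list[np.ndarray] = []
    kept_times: list[np.ndarray] = []
    productive_ps = 0.0
    accepted_n = 0
    consec_rej = 0
    outcome = "exhausted"
    ttb: float | None = None
    w = 0
    while w < config.max_total_windows:
        seed_key = (int(config.base_seed), int(replica), int(w))
        state_in = checkpoint.copy()
        if consec_rej > 0:
            vel_rng = _rng_from_seed(np.random.SeedSequence(list(seed_key) + [1]))
            state_in.velocities[mob] = maxwell_boltzmann_velocities(
                pack["mass"], spec.temperature, vel_rng)
        state_out, traj = propagate_langevin(
            state_in, spec, steps_per_window, record_every,
            seed=np.random.SeedSequence(list(seed_key)), _pack=pack)
        dcm = np.array([dcm_of(traj.coords[i]) for i in range(traj.n_frames)])
        t_off = (np.arange(1, samples + 1)) * record_every * dt
        slope = fit_dcm_slope(t_off, dcm)
        rec = WindowRecord(
            index=w, start_time_ps=productive_ps, sample_times_ps=t_off,
            dcm_samples=dcm, slope=slope, accepted=False,
            rejections_so_far=consec_rej, seed=seed_key)
        rec.accepted = window_accepted(rec, config)
        windows.append(rec)
        w += 1
        if rec.accepted:
            if keep_trajectory:
                kept_frames.append(traj.coords)
                kept_times.append(productive_ps + t_off)
            productive_ps += window_ps
            accepted_n += 1
            consec_rej = 0
            checkpoint = SimState(state_out.coords.copy(),
                                  state_out.velocities.copy(), productive_ps)
            if bool(np.all(dcm < config.success_distance)):
                outcome = "bound"
                ttb = productive_ps
                break
        else:
            consec_rej += 1
            if consec_rej >= config.max_consecutive_rejections:
                outcome = "failed"
                break

    traj_out = None
    if keep_trajectory and kept_frames:
        traj_out = Trajectory(
            coords=np.concatenate(kept_frames, axis=0),
            times_ps=np.concatenate(kept_times),
            tag=f"sumd-replica-{replica}")
    return SuMDResult(
        trajectory=traj_out, windows=windows, outcome=outcome,
        productive_time_ps=productive_ps, windows_attempted=len(windows),
        windows_accepted=accepted_n, time_to_binding_ps=ttb,
        final_dcm=dcm_of(checkpoint.coords), config=config, replica=replica,
        final_state=checkpoint)


def classify_outcome(result: SuMDResult, config: SupervisionConfig) -> str:
    """Re-derive the outcome label from the window log (audit of stored runs).

    Raises :class:`IntegrityError` when the stored acceptance flags, counts
    or outcome disagree with what the log implies.
    """
    consec = 0
    accepted_n = 0
    outcome = "exhausted"
    for rec in result.windows:
        slope = fit_dcm_slope(rec.sample_times_ps, rec.dcm_samples)
        if not np.isclose(slope, rec.slope, atol=1e-9):
            raise IntegrityError(f"window {rec.index}: stored slope {rec.slope} "
                                 f"!= recomputed {slope}")
        should_accept = window_accepted(rec, config)
        if should_accept != rec.accepted:
            raise IntegrityError(f"window {rec.index}: acceptance flag inconsistent "
                                 "with the acceptance rule")
        if rec.rejections_so_far != consec:
            raise IntegrityError(f"window {rec.index}: rejection counter mismatch")
        if rec.accepted:
            consec = 0
            accepted_n += 1
            if bool(np.all(rec.dcm_samples < config.success_distance)):
                outcome = "bound"
                break
        else:
            consec += 1
            if consec >= config.max_consecutive_rejections:
                outcome = "failed"
                break
    expected_prod = accepted_n * result.windows[0].sample_times_ps[-1] if result.windows else 0.0
    if accepted_n != result.windows_accepted or not np.isclose(
            expected_prod, result.productive_time_ps, atol=1e-6):
        raise IntegrityError("productive-time bookkeeping inconsistent")
    if outcome != result.outcome:
        raise IntegrityError(f"stored outcome {result.outcome!r} != derived {outcome!r}")
    return outcome


# ---------------------------------------------------------------------------
# Campaigns
# ---------------------------------------------------------------------------

def run_campaign(
    spec: ToySystemSpec,
    config: SupervisionConfig,
    n_replicas: int,
    base_seed: int | None = None,
    start_distance: float = 40.0,
    out_dir: str | Path | None = None,
    keep_trajectories: bool = False,
    settle_ps: float = 200.0,
) -> tuple[pd.DataFrame, list[SuMDResult]]:
    """Run ``n_replicas`` independent supervised replicas.

    Each replica gets its own placement and window seeds derived from the
    base seed. Returns a per-replica table (outcome, time to binding,
    minimum ligand RMSD against the planted bound pose) plus the result
    objects. With ``out_dir`` set, completed replicas are skipped on rerun
    (resumable campaigns); per-replica errors are recorded in the table
    rather than aborting the campaign.

    Replicas that reach the site get an extra ``settle_ps`` of plain
    (unsupervised) dynamics appended to their trajectory — supervision is
    already disengaged at that distance, and the settling phase lets the
    pose relax and fluctuate in the site the way recognition runs are
    continued with classical MD before pose analysis. Set 0 to disable.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    base = config.base_seed if base_seed is None else base_seed
    structure = spec.to_structure()
    ref_frame = spec.bound_pose_frame()
    fit_sel = AtomSelection.from_indices(np.arange(spec.n_receptor), label="receptor")
    lig_sel = spec.ligand_selection()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    results: list[SuMDResult] = []
    for r in range(n_replicas):
        if out_path is not None:
            cache = out_path / f"replica_{r:03d}.json"
            if cache.exists():
                rows.append(json.loads(cache.read_text()))
                results.append(None)
                continue
        try:
            place_seed = np.random.SeedSequence([int(base), r, 7])
            state0 = _place(spec, start_distance, place_seed)
            cfg = SupervisionConfig(**{**config.__dict__, "base_seed": int(base)})
            res = supervised_run(spec, state0, cfg, replica=r)
            if (res.outcome == "bound" and settle_ps > 0
                    and res.final_state is not None
                    and res.trajectory is not None):
                dt = spec.timestep
                rec = max(1, int(round(cfg.window_length_ps / dt))
                          // cfg.dcm_samples_per_window)
                n_steps = int(round(settle_ps / dt)) // rec * rec
                if n_steps >= rec:
                    _, settle = propagate_langevin(
                        res.final_state, spec, n_steps, rec,
                        seed=np.random.SeedSequence([int(base), r, 9]))
                    res.trajectory = Trajectory.concatenate(
                        [res.trajectory, settle], tag=res.trajectory.tag)
            min_rmsd = np.nan
            if res.trajectory is not None:
                vals = [
                    ligand_rmsd(res.trajectory.coords[i], ref_frame, structure,
                                fit_sel, lig_sel)
                    for i in range(res.trajectory.n_frames)
                ]
                min_rmsd = float(np.min(vals))
            row = {
                "replica": r, "outcome": res.outcome,
                "windows_attempted": res.windows_attempted,
                "windows_accepted": res.windows_accepted,
                "productive_time_ns": res.productive_time_ns,
                "time_to_binding_ns": res.time_to_binding_ns,
                "min_pose_rmsd_A": min_rmsd,
                "final_dcm_A": res.final_dcm,
                "error": "",
            }
            if not keep_trajectories:
                res.trajectory = None
            results.append(res)
        except Exception as exc:  # per-replica failure is recorded, not fatal
            row = {"replica": r, "outcome": "error", "windows_attempted": 0,
                   "windows_accepted": 0, "productive_time_ns": np.nan,
                   "time_to_binding_ns": np.nan, "min_pose_rmsd_A": np.nan,
                   "final_dcm_A": np.nan, "error": str(exc)}
            results.append(None)
        rows.append(row)
        if out_path is not None:
            (out_path / f"replica_{r:03d}.json").write_text(json.dumps(row))
    table = pd.DataFrame(rows)
    return table, results


def _place(spec: ToySystemSpec, distance: float, seed) -> SimState:
    from .toysim import place_ligand_at_distance

    return place_ligand_at_distance(spec, distance, seed=seed)


def unsupervised_first_passage(
    spec: ToySystemSpec,
    state0: SimState,
    success_distance: float = 5.0,
    max_time_ps: float = 30_000.0,
    seed=0,
    sample_every_ps: float = 1.0,
    chunk_ps: float = 500.0,
) -> tuple[bool, float]:
    """First-passage time of plain (unsupervised) dynamics to the site.

    Propagates without any acceptance rule until dcm first drops below
    ``success_distance`` or the time cap is reached. Returns
    ``(bound, first_passage_ps)``; a censored run reports the cap. Used as
    the classical-MD control against which the supervised speed-up is
    measured.
    """
    structure = spec.to_structure()
    lig_idx = spec.ligand_selection().resolve(structure)
    site_idx = spec.site_selection().resolve(structure)
    ml = structure.mass[lig_idx]
    ms = structure.mass[site_idx]
    pack = _mobile_param_pack(spec)
    dt = spec.timestep
    record_every = max(1, int(round(sample_every_ps / dt)))
    chunk_steps = max(record_every, int(round(chunk_ps / dt)) // record_every * record_every)
    state = state0.copy()
    elapsed = 0.0
    chunk_i = 0
    while elapsed < max_time_ps:
        steps = min(chunk_steps, int(round((max_time_ps - elapsed) / dt)))
        if steps < 1:
            break
        state, traj = propagate_langevin(
            state, spec, steps, record_every,
            seed=np.random.SeedSequence([0x5EED, int(seed), chunk_i]),
            _pack=pack)
        cl = (ml[None, :, None] * traj.coords[:, lig_idx]).sum(axis=1) / ml.sum()
        cs = (ms[None, :, None] * traj.coords[:, site_idx]).sum(axis=1) / ms.sum()
        dcm = np.linalg.norm(cl - cs, axis=1)
        hit = np.flatnonzero(dcm < success_distance)
        if hit.size:
            return True, float(traj.times_ps[hit[0]])
        elapsed = state.time_ps
        chunk_i += 1
    return False, float(max_time_ps)
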