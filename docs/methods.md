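# Methods

## The supervision algorithm

A supervised run alternates unbiased Langevin-dynamics windows with an
acceptance test on dcm, the distance between the mass-weighted ligand
center of mass and the binding-site center of mass. Within each window dcm
is sampled at `dcm_samples_per_window` (default 10) equally spaced frames
and an ordinary least-squares slope is fitted. Acceptance is tabu-like:

* accept iff slope < `slope_threshold` (default 0 Å/ps); a slope exactly
  at the threshold rejects;
* below `supervision_off_distance` (default = `success_distance`, 5 Å) the
  test is bypassed and every window is accepted, so the ligand can settle
  and rearrange inside the site;
* on rejection the coordinates are restored bitwise from the last accepted
  checkpoint and velocities are redrawn from the Maxwell–Boltzmann
  distribution with a fresh, deterministic seed.

Termination: *bound* once every dcm sample of a committed window is below
`success_distance` (arrival sustained for a full window); *failed* after
`max_consecutive_rejections` (default 30) rejected windows in a row;
*exhausted* at `max_total_windows`. The OLS slope was chosen as the
acceptance statistic because it is robust to single-frame noise; the
threshold, window length, sample count and both distances are
configuration, and every report prints the thresholds used.

The loop talks to the propagation backend through a narrow contract
(state in → frames out), so an external engine adapter can be substituted
for the built-in coarse-grained backend; only the built-in backend is
implemented and tested here.

Seeding is counter-based throughout: window noise comes from a Philox
stream keyed by (base seed, replica, window index), velocity redraws from
a sub-key of the same triple, so a rejected window's retry sees fresh
noise while the whole run — and any campaign built from such runs — is
bitwise reproducible from (system, config, base seed).

## The coarse-grained backend

The backend stands in for an all-atom engine so the method is testable at
desk scale. It is intentionally minimal:

* **Energy model.** Pairwise Lennard-Jones (Lorentz–Berthelot mixing) plus
  Coulomb with a distance-dependent dielectric ε(r) = 4r, truncated at a
  9 Å cutoff with a force shift, V(r) − V(rc) − (r − rc)V′(rc). The force
  shift (rather than a bare energy shift) keeps both energy and force
  continuous — and zero — at the cutoff, which the NVE drift check
  requires. Ligand topology adds harmonic bonds; there is no explicit
  solvent and no periodicity. A flat-bottom spherical wall (radius 100 Å,
  2 kcal mol⁻¹ Å⁻² beyond it) plays the role of the simulation box, and
  solvent friction is folded into the Langevin friction coefficient.
* **Integrator.** BAOAB-split Langevin dynamics (good configurational
  sampling at moderate time steps). With friction and temperature both
  zero it reduces exactly to velocity Verlet, which is how the energy-
  conservation check is run. The inner loop is JIT-compiled with numba;
  reference numpy implementations of the energy and forces are kept and
  the kernel forces are tested against central differences of the numpy
  potential.
* **Receptor.** Bead shell (Fibonacci lattice, radius 10 Å, spacing
  3.6 Å, ≈97 beads), fixed by default; optional harmonic restraints
  (5 kcal mol⁻¹ Å⁻²) make it mobile.
* **Units.** Å, ps, amu, kcal/mol, elementary charges, Kelvin;
  k_B = 0.0019872041 kcal/mol/K; 1 kcal/mol = 418.4 amu Å² ps⁻².

### The planted funnel

`build_funnel_system` sculpts one deep "orthosteric" patch at the +z apex
and any number of shallower decoy patches:

* the apex bead is recessed 1 Å and the surrounding ring of beads is
  raised 1.8 Å, making a concave seat rather than a convex bump;
* two charged site beads (−0.5 e anchor, +0.8 e neighbour) pair with the
  ligand's +1 e and −0.5 e beads, pinning position and in-plane
  orientation (two salt bridges, like a guanidinium in a deep acidic
  pocket plus a backbone contact);
* one site bead is several-fold stickier (a hydrophobic subpocket) and
  pairs with the ligand's bulky apolar bead, removing the soft pivot
  about the charged diagonal;
* patch epsilons are calibrated by fixed-point iteration so the locally
  minimized pose energy matches the requested depth (default −10 kcal/mol
  for the site, −5 for the decoy); the minimization is multi-start (eight
  in-plane orientations × both ring faces) so the planted pose is the
  deepest of the competing arrangements, and the build fails loudly if a
  decoy ends up at least as deep as the site.

The ligand is a four-bead macrocycle-like ring (side 2.4 Å, stiff edge
and diagonal bonds) whose beads are chemically distinct — charges
(+1, 0, −0.5, 0), contrasting LJ parameters, and one bead lifted 0.9 Å out
of the ring plane. The asymmetry is deliberate: a macrocyclic peptide's
residues are distinguishable, and without it ring flips and rotations are
energy-degenerate and no binding *mode* is identifiable at all.

Decoy patches use a wider footprint (6 Å vs 3.8 Å) so a metastable
surface patch has a realistic capture cross-section, and sit at polar
angle 70° from the site, which puts the decoy 10.7 Å (COM–COM) from it —
far enough (> 10 Å) to count as a remote stopover, close enough that
approach paths actually cross it.

### Time scales of the toy study

The coarse-grained system diffuses ~100× faster than a solvated all-atom
complex, so the supervision windows scale down accordingly:
`funnel_supervision_config` uses 20 ps windows and a 100-window budget
(2 ns), while the generic `SupervisionConfig` default stays at the
all-atom-appropriate 600 ps (1 ns preset available). The default campaign
starts the ligand 40 Å from the site — beyond the 9 Å cutoff, so the
initial state carries no premature interaction — and runs 20 replicas.
The unsupervised control runs the same starting states without any
acceptance rule, capped at 10× the supervised budget (20 ns), censored
values counted at the cap.

Replicas that reach the site get 200 ps of plain dynamics appended
("settling"): supervision is already disengaged below the arrival
threshold, and recognition studies routinely continue arrived replicas
with classical MD so the pose can relax before analysis. Settling frames
are part of the analysed trajectory but not of the productive time.

## Analysis chain

* **Pose matrix**: every stride-th frame (default 10) of every replica is
  superposed on a common reference receptor (mass-weighted Kabsch,
  reflections forbidden) and the ligand coordinates are flattened; rows
  carry (replica, frame, time) provenance.
* **Noise pre-filter**: a row is discarded iff the maximum cosine
  similarity to its k (default 5) nearest neighbours — computed on
  row-centred vectors — falls below 0.01. The filter runs as a separate
  stage before clustering; its parameters are reported in the output.
* **Clustering**: OPTICS (scikit-learn) with xi-extraction, defaults
  min_samples = 10, xi = 0.05; label −1 is noise. Each cluster is
  summarised by size, mean energy and its representative — the member
  with the most favourable energy; the tabular report rounds mean
  energies to integer kcal/mol.
* **Energies** come from a pluggable per-frame scorer: the built-in
  nonbonded ligand–receptor interaction energy for toy systems, or an
  imported CSV (frame_index, time_ns, dG_kcal_mol) for energies computed
  elsewhere (e.g. end-point MM-GBSA pipelines, whose solvation math is
  out of scope here). The two streams are never mixed and the scorer
  identity is recorded in every summary. Two mean binding energies are
  flagged "meaningfully different" only when |ΔΔG| ≥ 5 kcal/mol.
* **Metastable events**: maximal contiguous intervals of a dcm series
  whose samples stay within ±2 Å of the interval median, last at least
  50 ps, and whose median lies above the 5 Å arrival threshold (so the
  bound state is not reported as a stopover). The detector takes whatever
  series it is given; campaign-level analysis feeds it window-end samples
  (one per committed window), which is the time resolution at which the
  supervision itself operates — per-frame series carry intra-window
  fluctuations larger than the band.
* **Landscape**: 2-D histogram of frames over (dcm, interaction energy)
  plus a per-dcm-bin minimum-energy profile; counts always sum to the
  frames analysed.

## What the toy study shows — and what it does not

Passing tests show that the supervision logic extracts a binding pathway
from diffusive dynamics orders of magnitude faster than free dynamics,
that the analysis chain recovers a planted binding mode and a planted
stopover from the sampled trajectories alone, and that every component is
deterministic and self-consistent. They do not show anything about force-
field accuracy, solvation, conformational gating, or the kinetics of real
protein–ligand systems: the toy receptor is rigid, the ligand has four
beads, and the solvent is a friction coefficient. Numbers measured on
this system (bound fractions, times to binding, cluster energies)
characterise the method at toy scale, not any real complex.

## Numerical choices and degenerate inputs

* Time step 0.004 ps for the funnel (stiffest bond period ≈ 0.15 ps);
  0.002 ps default elsewhere and for NVE checks.
* Friction 5 ps⁻¹ in funnel systems (solvent drag folded in);
  the bare `ToySystemSpec` default is 0.1 ps⁻¹, a thermostat-style
  damping appropriate when friction is not standing in for solvent.
* Kabsch superposition needs ≥3 non-collinear points; collinear or
  too-small inputs raise a degenerate-geometry error rather than
  returning an arbitrary rotation. Reflections are never returned.
* Slope ties (exactly at the threshold) reject; all-identical cluster
  input collapses to one cluster without error; an empty atom selection
  is always an error, never a silent empty result.
* Pair distances below 1e-6 Å raise a singular-energy error; non-finite
  forces abort propagation naming the offending beads.
* Frame indexing is 0-based internally; reports additionally print
  1-based frame numbers.

## Known limitations

* The acceptance statistic is a plain OLS slope; no adaptive window
  lengths, no multi-ligand supervision, no binding-site search (the site
  is user-specified).
* OPTICS parameters are data-scale sensitive; the defaults suit pose
  matrices in Å with sub-Å cluster spreads.
* XTC round-trips quantize coordinates at ~0.01 Å (format precision);
  the XYZ dialect and DCD are effectively lossless.
* The toy model's NVT ensemble has no pressure; barostats are out of
  scope.
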