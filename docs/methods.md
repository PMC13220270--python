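# Methods

This note documents the models, numerical choices and known limitations
behind each stage of the pipeline, and what the synthetic-data
generators do and do not emulate.

## Channel detection

**Model.** The protein is a set of hard spheres (heavy atoms at their
van der Waals radii; hydrogens and solvent are never obstacles). Free
space is discretised on a regular grid; each voxel stores its
*clearance*, the distance from the voxel centre to the nearest obstacle
vdW surface, i.e. the radius of the largest spherical probe centred
there. Clearance is capped at 10 Å: caps only affect regions far from
any atom, which can never be the bottleneck of a membrane-spanning
channel, and the cap bounds the per-atom update volume so grid
construction stays linear in atom count.

**Search objective.** A channel from the seed residue to bulk solvent
on each membrane side is the widest path on the 26-connected voxel
graph (Euclidean edge lengths): maximise the minimum clearance along
the path, tie-broken by shorter arc length. This is implemented as a
lexicographic Dijkstra — labels ordered by (bottleneck descending,
length ascending) — which settles each voxel with its optimal label;
the first settled voxel inside a bulk region is that region's optimum.
A full cost-function formulation with a tunable exponent (as in
general-purpose tunnel software) was deliberately not adopted: the
bottleneck radius is the physically interpretable quantity here (a
probe passes or it does not) and the maximin objective makes the result
independent of any cost-weight choice. The two legs (seed → N-side
bulk, seed → P-side bulk) are concatenated into one N→P path; the
channel coordinate R is cumulative arc length with R = 0 at the N-side
terminus, so profiles read from the proton-uptake side to the release
side.

**Parameters.**

| parameter | default | unit | rationale |
|---|---|---|---|
| probe radius | 0.9 | Å | smallest probe that still means "a water wire could thread here with side-chain relaxation" |
| grid spacing | 0.8 | Å | must resolve the 0.9 Å probe; halving it changes bottlenecks by less than the coarse spacing (tested) |
| smoothing window | 3 | points | removes voxel jaggedness without corner-cutting |
| clearance cap | 10 | Å | see above |
| contact cutoff (lining) | 4.0 | Å | heavy-atom distance to centerline defining a lining residue |

**Bulk definition.** Bulk solvent defaults to the two slabs beyond the
obstacle extent along z (the membrane normal); the axis and plane
offsets are configurable. For a structure that does not include
membrane atoms, an unconstrained grid would let the search walk around
the protein laterally; the grid margin therefore accepts per-axis
values, and a *negative* lateral margin trims the grid inside the
obstacle footprint, which is how the tests confine the search to the
slab fixtures. Real systems with a modelled membrane do not need this.

**Smoothing and radii.** The voxel centerline is smoothed by a centred
moving average (endpoints fixed); local radii are then re-evaluated
*exactly* against the obstacle spheres (not interpolated from the
grid). Any smoothed point whose exact clearance would drop below the
probe radius reverts to its raw voxel position, so the reported
bottleneck never violates the probe constraint.

**Radius provenance.** When no per-atom radius/charge table is given,
radii fall back to the bundled Bondi element set. Different published
vdW sets shift clearances by roughly 0.1–0.2 Å; for analyses where that
matters, supply the force-field radii through the side table.

**Lining and the gate-free radius.** Residues within the contact cutoff
of a centerline point are classified nonpolar / polar / titratable from
a bundled table (titratable takes precedence: Asp, Glu, Lys, Arg, His,
Cys, Tyr). The radius profile is evaluated with titratable residues
removed from the obstacle set, because protonatable side chains that
line the conduction pathway would otherwise mask the geometric lumen
they serve.

**Manual-curation replacement.** Published tunnel searches are often
finished by hand-extending termini to bulk. `extend_to_bulk` automates
this: a shortest passable extension (breadth-first, capped at 10 Å by
default) is appended from each terminus that has not reached its bulk
slab, and extension points are labelled in the path's segment
provenance. A sealed terminus yields a warning and a `reached_bulk =
False` flag rather than an error.

## Hydration and electric-field profiles

Profiles are evaluated at points every `step` (default 1 Å) of arc
length along one fixed path, computed once in a reference structure.
This matches the way occupancy and field are normally plotted against a
single channel coordinate; it assumes frames are superposed onto that
reference (`superpose` provides the Kabsch fit and per-frame RMSD), and
it deliberately does not recompute time-resolved tunnels per frame.

Occupancy at R is the fraction of frames with ≥ 1 water *oxygen* within
the capture radius (2 Å default) — presence is keyed on the oxygen
only, the standard convention. Replica aggregation reports the mean and
the population SD (ddof = 0) across replicas; with `normalize=True` the
mean is rescaled by its own maximum (per-profile-max mode — the
alternative, normalising to a bulk-water expectation, needs a bulk
reference volume the profile itself does not define, so it is not the
default).

The field at R is the direct vacuum Coulomb sum over non-solvent
partial charges at distances greater than the exclusion radius (2 Å
default). Two interpretation choices are explicit:

* the 2 Å cutoff *excludes near* sources (avoiding near-singular 1/r²
  terms from atoms essentially at the measurement point); the opposite
  reading — keep only sources within 2 Å — is available as
  `include_within_instead` but is physically implausible for a field
  profile and is not the default;
* the reported magnitude is |⟨E⟩| — the magnitude of the frame-averaged
  vector; per-frame-magnitude averaging ⟨|E|⟩ is available as an option
  (the two differ when the direction fluctuates).

No dielectric screening is applied (vacuum permittivity); values are in
V/Å, and 1 V/Å = 100 MV/cm. Minimum-image distances are used whenever
the structure carries an orthorhombic box, consistent with trajectories
produced under periodic boundary conditions.

## Liposome kinetics

**Pyranine.** pH = a·log₁₀(R) + b with R = I460/I405. The calibration
fit is ordinary least squares of pH on log₁₀(R). ΔpH = initial − final,
where the initial pH averages the baseline (first 60 s, before ATP) and
the final pH is the plateau pH∞ of a three-parameter exponential
pH(t) = pH∞ + (pH₀ − pH∞)·e^(−k(t−t₀)) fitted to the post-addition
segment. Initialisation (plateau from the last decile, amplitude from
the first post-event point, k from the log-linearised early decay)
makes the fit converge reliably across the 0.008–0.09 ΔpH range; the
fit is unconstrained — no parameter is pinned — and a fitted k ≤ 0 or a
flat trace is returned flagged rather than raised, because a
non-transporting construct is a valid measurement. The event time is
taken from trace metadata, not auto-detected.

**Oxonol VI / Nernst.** Δψ is assumed linear in ΔA₅₈₈₋₆₂₅ over the
calibrated range (the functional form of dye response is not modelled);
calibration potentials are valinomycin-mediated K⁺ diffusion potentials
Δψ = (RT/F)·ln([K⁺]out/[K⁺]in). Initial rates are least-squares slopes
over the first second (≈500 points at 2 ms sampling).

**Capacitance flux.** A liposome of diameter d is a spherical capacitor
of area πd² and specific capacitance C_m, so dΨ/dt implies a charging
current C_m·πd²·dΨ/dt and a proton flux of that divided by the
elementary charge. Defaults d = 100 nm (the extrusion pore size) and
C_m = 0.9 μF cm⁻² (a standard lipid-bilayer value) give 211.8 H⁺ s⁻¹
at 120 mV s⁻¹. Fluxes are reported uncorrected for transporter
orientation; an optional correction dividing by the fraction of
transporters with the uptake side facing the lumen (default 0.75) is
provided but off by default, matching how raw rates are usually quoted.

## Respiration assays

O₂ and FeCN rates are least-squares slopes. The automatic linear-range
selector computes a running local slope over 10-point windows and fits
the longest contiguous run whose local slope stays within 10% of the
median local slope — "linear range" has no standard definition, so the
tolerance and window are exposed as parameters. O₂ consumption is
reported positive. Normalisation is
100·(rate/protein/FeCN)/(same for the reference construct); the SD adds
relative variances to first order, which agrees with Monte-Carlo SDs
within 10% up to ~15% CV (tested). Reported ± values are treated as SDs
across replicates. sfGFP levels use the 510 nm emission sample
(nearest) or a three-point quadratic refinement of the local peak.

## Synthetic data: what it does and does not emulate

The generators define the conditions under which the pipeline is
validated:

* **Channel fixtures** — a cubic lattice (2 Å spacing) of 1.7 Å
  pseudo-atoms fills a membrane-spanning slab; atoms intruding into the
  lumen are removed, so the analytic centerline and radius (including
  ring-shaped blockers that constrict the lumen to an exact radius) are
  known ground truth. Straight, bent and S-shaped geometries cover the
  path-following logic. The 2 Å lattice leaves sub-probe surface
  roughness only (largest inter-atom void ≈ 0.03 Å), so no false
  passages exist.
* **Water trajectories** — per frame and channel point, a water oxygen
  is present independently with the target probability, jittered within
  0.3 Å; sample points are spaced 2·capture + 0.5 Å so capture spheres
  are disjoint and realised occupancies are exact Bernoulli counts.
  Placement is i.i.d. across frames: temporal autocorrelation does not
  change the expectation of a per-frame ratio, but real water wires are
  correlated, so convergence in real data is slower than the binomial
  rate the tests verify.
* **Charge systems** — point charges with a closed-form Coulomb oracle
  implemented through an independent code path (scipy physical
  constants, plain loop) for cross-checking the field engine.
* **Assay traces** — exponential (pyranine, 600 ms sampling, noise in
  pH units) and linear-then-plateau (oxonol at 2 ms, oxygraph at 1 s)
  shapes with Gaussian noise, inverted through the same calibrations
  the analysis uses; generating parameters travel in trace metadata.

All generators are deterministic given their seed. Passing recovery
tests on these fixtures demonstrates the estimators are unbiased and
correctly scaled under their stated noise models; it does not
demonstrate robustness to baseline drift, photobleaching, dye leakage
or correlated noise, none of which are modelled.

## Validation problem sizes

The bundled checks run at desk scale, chosen so the full suite
completes in well under a minute of compute per stage: 25 random
cavities (up to 20³ voxels) for exact agreement between the Dijkstra
bottleneck and a brute-force threshold-connectivity oracle; 2000-frame
trajectories for occupancy recovery within 3 binomial SE per point; 100
random charge systems for field agreement to 1e-10 relative; 100
replicate traces each for ΔpH (0.008–0.090 range) and initial-rate
(10–55 mV s⁻¹) recovery within 3× the fit SE.

## Known limitations

* Single reference channel: no per-frame tunnel recomputation or
  multi-tunnel ranking/clustering.
* Orthorhombic periodic boxes only; triclinic cells are rejected.
* Vacuum electrostatics: no reaction field, PME or dielectric model —
  profiles are comparative, not absolute free-energy quantities.
* Exit choice in proteins with several plausible mouths is governed by
  the bulk definition (axis/offsets), not by automated curation of
  side routes.
* The exponential ΔpH fit assumes a single kinetic phase; biphasic
  traces will fold both phases into one rate constant.
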