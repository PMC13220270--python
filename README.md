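# protonpath

Analysis toolkit for proton-channel gating in membrane transporters —
in particular the antiporter-like subunits of respiratory Complex I —
combining structure-based channel detection with quantitative analysis
of proteoliposome proton-transport spectroscopy.

## Who this is for

Groups that (a) run molecular-dynamics simulations of membrane proteins
and want reproducible water-occupancy and electric-field profiles along
a putative proton pathway, and/or (b) measure proton transport in
reconstituted proteoliposomes with optical probes (pyranine/HPTS,
oxonol VI) and respiration in isolated membranes (Clark electrode,
FeCN assay) and want the trace → number reduction under version control
instead of in a spreadsheet.

## What it computes

**Channel detection.** Heavy atoms are hard spheres of their van der
Waals radii; free space is discretised on a grid storing clearance (the
largest probe radius that fits at each voxel). From a seed residue
(e.g. the central lysine of an antiporter module) the channel to bulk
solvent on both membrane sides is the *widest path* on the 26-connected
voxel graph: maximise the bottleneck clearance, break ties by arc
length. A voxel is passable if its clearance ≥ the probe radius
(default 0.9 Å). The result is an arc-length-parameterised centerline —
the channel coordinate R, N-side = 0 — with local radii, plus residue
lining (polar / nonpolar / titratable) and a gate-free radius profile
with titratable side chains removed from the obstacle set.

**Hydration and field profiles.** Along the fixed channel coordinate,
water occupancy at R is the fraction of trajectory frames with a water
oxygen within the 2 Å capture radius; profiles from replica simulations
are aggregated as mean ± SD and optionally peak-normalised. The electric
field at R is the vacuum Coulomb sum E = Σ k·qᵢ·r̂ᵢ/rᵢ² over non-solvent
partial charges beyond a 2 Å exclusion radius, averaged over frames
(V/Å; ×100 for MV/cm).

**Liposome kinetics.** Pyranine is ratiometric: pH = a·log₁₀(I460/I405) + b
with (a, b) fitted from calibration points (the bundled worked examples
use a = 1.931, b = 7.926). ΔpH of an ATP-driven pumping assay is the
baseline pH (first minute) minus the plateau of a single-exponential
fit after ATP addition. Oxonol VI reports Δψ linearly in A588 − A625,
calibrated against valinomycin/K⁺ Nernst potentials
Δψ = (RT/F)·ln([K⁺]out/[K⁺]in); initial rates are linear fits over the
first second. A Δψ rate converts to a per-liposome proton flux through
the membrane capacitance: flux = C_m·πd²·(dΨ/dt)/e.

**Respiration.** O₂-consumption slopes (automatic linear-range
selection) normalised by total protein and FeCN-measured dehydrogenase
activity, reported as percent of a reference construct with first-order
error propagation; sfGFP expression from the 510 nm emission peak.

A synthetic-data module generates every fixture with known ground truth
(channel geometries, Bernoulli water trajectories, point-charge systems
with a closed-form field oracle, assay traces at instrument-native
sampling), so the full pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
from protonpath import (LiposomeSpec, PyranineCalibration, SearchSpec,
                        aggregate_replicas, build_grid, extract_delta_ph,
                        find_channel, ph_trace, proton_flux, water_occupancy)
from protonpath.synthetic import (ChannelFixtureSpec, TraceFixtureSpec,
                                  make_channel_structure, make_pyranine_trace,
                                  make_water_trajectory)

# a 40 Å membrane slab with a 3 Å channel bored through it
spec = ChannelFixtureSpec(length=40.0, lumen_radius=3.0,
                          lining=["titratable", "nonpolar", "polar"])
structure, truth = make_channel_structure(spec)
search = SearchSpec(start=truth.point_at(20.0), probe_radius=0.9)
grid = build_grid(structure, search, spacing=0.8, margin=[-2, -2, 4])
path = find_channel(grid, search)
print(f"bottleneck: {path.bottleneck_radius:.2f} A, arc length: {path.length:.1f} A")

# triplicate water trajectories with a known occupancy profile
profiles = []
for rep in range(3):
    combined, traj = make_water_trajectory(
        structure, truth, lambda r: 0.2 + 0.6 * np.exp(-((r - 20) / 8) ** 2),
        n_frames=500, seed=rep)
    profiles.append(water_occupancy(traj, combined, truth, step=4.5))
agg = aggregate_replicas(profiles, normalize=True)

# a pyranine assay trace and the capacitance flux conversion
calib = PyranineCalibration(a=1.931, b=7.926)
trace = make_pyranine_trace(TraceFixtureSpec(
    true_delta_ph=0.081, kinetic_constant=0.01, noise_sd=0.002, seed=1), calib)
res = extract_delta_ph(ph_trace(trace, calib), event_time=60.0)
print(f"delta_pH = {res.delta_pH:.3f}")
print(f"flux at 120 mV/s: {proton_flux(120.0, LiposomeSpec()):.1f} H+/s")
```

prints

```
bottleneck: 3.05 A, arc length: 44.0 A
delta_pH = 0.081
flux at 120 mV/s: 211.8 H+/s
```

The detected bottleneck (3.05 Å) matches the fixture's analytic lumen
radius within the grid spacing; the ΔpH estimate recovers the
generating 0.081 from a noisy trace; and a 120 mV s⁻¹ potential
build-up across a 100 nm liposome at 0.9 μF cm⁻² corresponds to
≈212 protons per second. The aggregated occupancy profile in `agg`
peaks at 1.0 (normalised) at mid-channel with replica SDs of ~0.01.

A `protonpath` console script exposes the same operations
(`channel`, `calibrate-ph`, `calibrate-psi`, `delta-ph`, `rate`,
`flux`, `respiration`, `simulate`, `run`); `protonpath --help` lists
them, and `run` drives whole configured workflows from one JSON file.

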