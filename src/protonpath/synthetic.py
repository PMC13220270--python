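"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the study conditions each analysis stage expects:

* a membrane-mimicking slab of pseudo-atoms with a channel of known
  geometry bored through it, lined by polar/nonpolar/titratable
  pseudo-residues (channel detection and lining analysis);
* trajectories whose water oxygens visit channel coordinates with known
  Bernoulli occupancies (hydration profiling);
* point-charge systems with a closed-form Coulomb field oracle
  (field profiling);
* pyranine, oxonol VI, oxygraph and emission-spectrum traces generated
  from known ΔpH, rates and noise at the instruments' native sampling
  (600 ms pyranine, 2 ms stopped-flow).

Every generator is deterministic given its seed, and every fixture
carries its generating parameters in metadata.  Water placement is
i.i.d. across frames (no autocorrelation); wall pseudo-atoms are
uncharged so hydration and field tests stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.constants

from .channel import TunnelPath
from .core import AssayTrace, AtomRecord, StructureModel, Trajectory
from .kinetics import PsiCalibration, PyranineCalibration

__all__ = [
    "ChannelFixtureSpec",
    "TraceFixtureSpec",
    "make_channel_structure",
    "make_water_trajectory",
    "make_charge_system",
    "coulomb_field_oracle",
    "make_pyranine_trace",
    "make_oxonol_trace",
    "make_o2_trace",
    "make_emission_spectrum",
]

_CLASS_RESNAMES = {"nonpolar": "LEU", "polar": "SER", "titratable": "LYS"}


@dataclass
class ChannelFixtureSpec:
    """A membrane slab with a channel of known centerline and radius.

    ``lining`` assigns polarity classes to equal slices of the channel
    length; ``blockers`` are (R, radius) narrowings realised as rings of
    wall atoms constricting the lumen to exactly ``radius`` at channel
    coordinate ``R``.
    """

    length: float = 40.0  # Å
    lumen_radius: float = 3.0  # Å
    geometry: str = "straight"  # straight | l_bend | s_curve
    lining: list = field(default_factory=lambda: ["nonpolar"])
    blockers: list = field(default_factory=list)  # [(R, radius), ...]
    seed: int = 0
    wall_atom_radius: float = 1.7  # Å
    lattice_spacing: float = 2.0  # Å
    wall_thickness: float = 6.0  # Å

    def __post_init__(self):
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if self.lumen_radius < self.lattice_spacing / 2:
            raise ValueError(
                "lumen narrower than the wall lattice can resolve without "
                "artifacts"
            )
        if any(r < 0 for _, r in self.blockers):
            raise ValueError("blocker radius must be non-negative")
        if self.geometry not in ("straight", "l_bend", "s_curve"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _centerline(spec: ChannelFixtureSpec, ds: float = 0.25) -> np.ndarray:
    """Densely sampled centerline points for the requested geometry."""
    L = spec.length
    if spec.geometry == "straight":
        n = int(np.ceil(L / ds)) + 1
        z = np.linspace(0, L, n)
        return np.column_stack([np.zeros(n), np.zeros(n), z])
    if spec.geometry == "l_bend":
        w = 0.25 * L
        knots = np.array(
            [[0, 0, 0], [0, 0, 0.4 * L], [w, 0, 0.4 * L], [w, 0, L]]
        )
        pieces = []
        for a, b in zip(knots[:-1], knots[1:]):
            seg_len = np.linalg.norm(b - a)
            n = max(int(np.ceil(seg_len / ds)), 1)
            t = np.linspace(0, 1, n, endpoint=False)[:, None]
            pieces.append(a + t * (b - a))
        pieces.append(knots[-1:])
        return np.vstack(pieces)
    # s_curve: sinusoidal lateral sweep
    n = int(np.ceil(L / (ds / 2))) + 1
    z = np.linspace(0, L, n)
    x = 0.15 * L * np.sin(2 * np.pi * z / L)
    return np.column_stack([x, np.zeros(n), z])


def _arc_length(points: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def make_channel_structure(
    spec: ChannelFixtureSpec,
) -> tuple[StructureModel, TunnelPath]:
    """Build the slab structure and the analytic ground-truth path.

    Wall pseudo-atoms (radius ``wall_atom_radius``) sit on a cubic
    lattice filling a slab that spans the channel's z-extent; atoms whose
    sphere would intrude into the lumen are removed, so the free radius
    around the centerline is exactly ``lumen_radius`` (up to lattice
    granularity, which only adds clearance).  The returned TunnelPath is
    the analytic centerline with the analytic clearance, including
    blocker constrictions.
    """
    dense = _centerline(spec, ds=0.25)
    arc = _arc_length(dense)
    lateral = np.abs(dense[:, :2]).max() if len(dense) else 0.0
    half_width = (
        lateral + spec.lumen_radius + spec.wall_atom_radius + spec.wall_thickness
    )
    s = spec.lattice_spacing
    xs = np.arange(-half_width, half_width + s / 2, s)
    zs = np.arange(0.0, spec.length + s / 2, s)
    gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # bore the channel: drop lattice atoms intruding into the lumen
    bore_radius = spec.lumen_radius + spec.wall_atom_radius
    d2 = np.full(len(lattice), np.inf)
    for p in dense:
        d2 = np.minimum(d2, ((lattice - p) ** 2).sum(axis=1))
    dist = np.sqrt(d2)
    keep = dist >= bore_radius
    lattice = lattice[keep]
    dist = dist[keep]

    lining_shell = dist <= bore_radius + s
    n_cls = max(len(spec.lining), 1)
    atoms: list[AtomRecord] = []
    serial = 1
    per_res_count: dict[tuple[str, int], int] = {}
    for pos, is_lining in zip(lattice, lining_shell):
        slab = int(np.clip(pos[2] // s, 0, 10_000))
        if is_lining:
            cls_idx = int(
                np.clip(pos[2] / spec.length * n_cls, 0, n_cls - 1)
            )
            cls = spec.lining[cls_idx] if spec.lining else "nonpolar"
            resname = _CLASS_RESNAMES[cls]
            chain = "A"
        else:
            resname, chain = "GLY", "B"
        key = (chain, slab)
        per_res_count[key] = per_res_count.get(key, 0) + 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=f"C{per_res_count[key]}",
                residue_name=resname,
                residue_id=slab + 1,
                chain=chain,
                position=pos,
                vdw_radius=spec.wall_atom_radius,
                partial_charge=0.0,
            )
        )
        serial += 1

    # blockers: rings of wall atoms constricting the lumen to the target
    # radius at the requested channel coordinate
    tangents = np.gradient(dense, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    blocker_rings = []
    for r_coord, rho in spec.blockers:
        i = int(np.argmin(np.abs(arc - r_coord)))
        center, tan = dense[i], tangents[i]
        u = np.cross(tan, [0.0, 1.0, 0.0])
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(tan, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(tan, u)
        ring_r = rho + spec.wall_atom_radius
        n_ring = max(int(np.ceil(2 * np.pi * ring_r / 1.2)), 6)
        blocker_rings.append((center, tan, ring_r))
        resid = 9000 + len(blocker_rings)
        for j in range(n_ring):
            ang = 2 * np.pi * j / n_ring
            pos = center + ring_r * (np.cos(ang) * u + np.sin(ang) * v)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{j + 1}",
                    residue_name="GLY",
                    residue_id=resid,
                    chain="B",
                    position=pos,
                    vdw_radius=spec.wall_atom_radius,
                    partial_charge=0.0,
                )
            )
            serial += 1

    structure = StructureModel(atoms)

    # ground-truth path: centerline every 0.5 Å with analytic clearance
    stride = 2  # dense sampling is 0.25 Å
    pts = dense[::stride]
    truth_r = np.full(len(pts), float(spec.lumen_radius))
    for center, tan, ring_r in blocker_rings:
        t_axial = (pts - center) @ tan
        # clearance of a centerline point to a coaxial ring of radius
        # ring_r: sqrt(t² + ring_r²) − wall_atom_radius
        ring_clear = np.sqrt(t_axial**2 + ring_r**2) - spec.wall_atom_radius
        truth_r = np.minimum(truth_r, ring_clear)
    truth = TunnelPath(
        points=pts, local_radius=truth_r, segments=["truth"] * len(pts)
    )
    return structure, truth


def make_water_trajectory(
    structure: StructureModel,
    path: TunnelPath,
    occupancy_profile,
    n_frames: int,
    seed: int = 0,
    capture_radius: float = 2.0,
    frame_interval: float = 1.0,
    replica_id: int = 0,
    jitter: float = 0.3,
) -> tuple[StructureModel, Trajectory]:
    """Trajectory whose water occupancy at sample coordinates is known.

    Sample coordinates are spaced ``2·capture_radius + 0.5`` Å apart so
    capture spheres are disjoint: the realised occupancy at each sample
    point is then an independent Bernoulli(n_frames, target) count.  Per
    frame and point, a water oxygen is present with its target
    probability (placed within ``jitter`` Å of the point) and parked far
    outside the structure otherwise.  Targets are either an array over
    the sample grid or a callable of R; the grid and targets are recorded
    in the trajectory metadata.
    """
    spacing = 2 * capture_radius + 0.5
    rgrid = np.arange(0.0, path.length + 1e-9, spacing)
    points = np.array([path.point_at(r) for r in rgrid])
    if callable(occupancy_profile):
        targets = np.array([occupancy_profile(r) for r in rgrid], float)
    else:
        targets = np.asarray(occupancy_profile, float)
        if len(targets) != len(rgrid):
            raise ValueError(
                f"occupancy_profile must have {len(rgrid)} entries for this "
                f"path (grid spacing {spacing} Å)"
            )
    if np.any((targets < 0) | (targets > 1)):
        raise ValueError("occupancy targets must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_waters = len(rgrid)
    waters = [
        AtomRecord(
            serial=len(structure) + j + 1,
            name="O",
            residue_name="HOH",
            residue_id=5000 + j,
            chain="W",
            position=np.zeros(3),
            vdw_radius=1.52,
            partial_charge=0.0,
            is_solvent=True,
        )
        for j in range(n_waters)
    ]
    combined = StructureModel(structure.atoms + waters, box=structure.box)

    park = points.min(axis=0) - np.array([0.0, 0.0, 500.0])
    base = np.array([a.position for a in combined.atoms])
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    w0 = len(structure)
    present = rng.random((n_frames, n_waters)) < targets[None, :]
    offsets = rng.normal(size=(n_frames, n_waters, 3))
    offsets *= (
        jitter
        * rng.random((n_frames, n_waters, 1)) ** (1 / 3)
        / np.linalg.norm(offsets, axis=2, keepdims=True)
    )
    for j in range(n_waters):
        pos = np.where(
            present[:, j, None],
            points[j] + offsets[:, j, :],
            park + np.array([3.0 * j, 0.0, 0.0]),
        )
        frames[:, w0 + j, :] = pos
    traj = Trajectory(frames, frame_interval=frame_interval,
                      replica_id=replica_id)
    traj.metadata = {
        "rgrid": rgrid,
        "targets": targets,
        "capture_radius": capture_radius,
        "seed": seed,
    }
    return combined, traj


def make_charge_system(placements) -> StructureModel:
    """Point charges as massless pseudo-atoms (field sources only).

    ``placements`` is an iterable of (position, charge_e).  The atoms are
    flagged non-heavy with zero radius so they never enter tunnel
    geometry; :func:`coulomb_field_oracle` provides the closed-form field
    through an independent code path.
    """
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="Q",
            residue_name="CHG",
            residue_id=i + 1,
            chain="Q",
            position=np.asarray(pos, float),
            vdw_radius=0.0,
            partial_charge=float(q),
            is_heavy=False,
        )
        for i, (pos, q) in enumerate(placements)
    ]
    return StructureModel(atoms)


def coulomb_field_oracle(placements, point, exclusion_radius: float = 0.0):
    """Direct Coulomb sum at ``point`` (V/Å), independent implementation.

    Uses physical constants from scipy.constants rather than the
    pipeline's precomputed conversion factor.
    """
    e = scipy.constants.elementary_charge
    eps0 = scipy.constants.epsilon_0
    k_v_ang = e / (4 * np.pi * eps0 * 1e-10)  # V at 1 Å from 1 e
    point = np.asarray(point, float)
    total = np.zeros(3)
    for pos, q in placements:
        d = point - np.asarray(pos, float)
        r = float(np.sqrt((d * d).sum()))
        if r <= exclusion_radius or r == 0.0:
            continue
        total = total + k_v_ang * q * d / r**3
    return total


@dataclass
class TraceFixtureSpec:
    """Generating parameters of a synthetic assay trace."""

    true_delta_ph: float = 0.08
    true_rate: float = 50.0  # mV s⁻¹
    kinetic_constant: float = 0.01  # s⁻¹
    noise_sd: float = 0.0  # pH units (pyranine) or mV (oxonol)
    sample_interval: float = 0.6  # s; 0.6 pyranine, 0.002 stopped-flow
    event_time: float = 60.0  # s
    duration: float = 480.0  # s
    initial_ph: float = 7.4
    seed: int = 0


def make_pyranine_trace(
    spec: TraceFixtureSpec, calib: PyranineCalibration
) -> AssayTrace:
    """ATP-driven acidification trace in (I405, I460) intensity space.

    pH holds at ``initial_ph`` before the event, then relaxes
    exponentially to ``initial_ph − true_delta_ph`` with rate
    ``kinetic_constant``.  Gaussian noise (``noise_sd``, pH units) is
    added before inverting through the calibration with I405 held
    constant.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, spec.sample_interval)
    ph = np.full_like(t, spec.initial_ph)
    after = t >= spec.event_time
    ph[after] = spec.initial_ph - spec.true_delta_ph * (
        1 - np.exp(-spec.kinetic_constant * (t[after] - spec.event_time))
    )
    if spec.noise_sd > 0:
        ph = ph + rng.normal(0.0, spec.noise_sd, size=len(t))
    i405 = np.full_like(t, 100.0)
    i460 = calib.ratio(ph) * i405
    return AssayTrace(
        t,
        {"I405": i405, "I460": i460},
        spec.sample_interval,
        metadata={
            "true_delta_ph": spec.true_delta_ph,
            "kinetic_constant": spec.kinetic_constant,
            "initial_ph": spec.initial_ph,
            "event_time": spec.event_time,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


def make_oxonol_trace(
    spec: TraceFixtureSpec,
    calib: PsiCalibration,
    saturation_time: float = 5.0,
    duration: float = 20.0,
) -> AssayTrace:
    """Δψ buildup trace in (A588, A625) absorbance space.

    Δψ rises linearly at ``true_rate`` until ``saturation_time`` and then
    plateaus; Gaussian noise (``noise_sd``, mV) is added before mapping
    back through the calibration, split symmetrically across the two
    absorbance channels around a 0.5 AU baseline.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.sample_interval if spec.sample_interval else 0.002
    t = np.arange(0.0, duration, dt)
    psi = spec.true_rate * np.minimum(t, saturation_time)
    if spec.noise_sd > 0:
        psi = psi + rng.normal(0.0, spec.noise_sd, size=len(t))
    da = calib.delta_a(psi)
    a588 = 0.5 + da / 2
    a625 = 0.5 - da / 2
    return AssayTrace(
        t,
        {"A588": a588, "A625": a625},
        dt,
        metadata={
            "true_rate": spec.true_rate,
            "saturation_time": saturation_time,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


def make_o2_trace(
    rate: float,
    break_time: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    o2_start: float = 250.0,
    duration: float = 200.0,
    sample_interval: float = 1.0,
) -> AssayTrace:
    """Oxygraph trace: linear O₂ decline at ``rate`` then a plateau.

    ``rate`` is signed (negative for consumption); the plateau models O₂
    exhaustion or reaction stop at ``break_time``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, sample_interval)
    o2 = o2_start + rate * np.minimum(t, break_time)
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=len(t))
    return AssayTrace(
        t,
        {"O2": o2},
        sample_interval,
        metadata={"true_rate": rate, "break_time": break_time, "seed": seed},
    )


def make_emission_spectrum(
    peak_height: float,
    peak_nm: float = 510.0,
    sigma_nm: float = 15.0,
    wl_start: float = 500.0,
    wl_end: float = 600.0,
    step_nm: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayTrace:
    """Gaussian emission spectrum (wavelength carried on the time axis)."""
    rng = np.random.default_rng(seed)
    wl = np.arange(wl_start, wl_end + step_nm / 2, step_nm)
    em = baseline + peak_height * np.exp(-((wl - peak_nm) ** 2) / (2 * sigma_nm**2))
    if noise_sd > 0:
        em = em + rng.normal(0.0, noise_sd, size=len(wl))
    return AssayTrace(
        wl,
        {"emission": em},
        step_nm,
        metadata={"peak_height": peak_height, "peak_nm": peak_nm,
                  "sigma_nm": sigma_nm, "seed": seed},
    )
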