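"""Water-occupancy and electric-field profiles along a channel coordinate.

Both profiles are evaluated at points sampled every ``step`` Å of arc
length along a fixed TunnelPath (the channel coordinate R, N-side = 0),
which presumes the trajectory has been superposed onto the reference
structure the path was computed in — :func:`superpose` does this.

Occupancy at a coordinate is the fraction of frames with at least one
water *oxygen* within the capture radius (2 Å default) of the point.
The electric field at a coordinate is the vacuum Coulomb field of all
non-solvent partial charges farther than the exclusion radius (2 Å
default) from the point, averaged over frames as a vector; the reported
magnitude is the magnitude of that average (per-frame-magnitude
averaging is available as an option).  Fields are in V/Å; multiply by
100 to get MV/cm.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .channel import TunnelPath
from .core import ChannelProfile, StructureModel, Trajectory

__all__ = [
    "water_occupancy",
    "aggregate_replicas",
    "electric_field",
    "superpose",
    "sample_coordinates",
    "COULOMB_V_ANG",
    "V_PER_ANG_TO_MV_PER_CM",
]

#: e/(4πε₀) in V·Å — the field of one elementary charge at 1 Å is this many V/Å.
COULOMB_V_ANG = 14.399645468667817

#: 1 V/Å = 100 MV/cm.
V_PER_ANG_TO_MV_PER_CM = 100.0


def sample_coordinates(path: TunnelPath, step: float = 1.0):
    """R grid (every ``step`` Å) and the centerline points at those R."""
    rgrid = np.arange(0.0, path.length + step / 2, step)
    points = np.array([path.point_at(r) for r in rgrid])
    return rgrid, points


def _water_oxygen_indices(structure: StructureModel) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(structure.atoms)
        if a.is_solvent and a.name.startswith("O")
    ]
    return np.array(idx, int)


def water_occupancy(
    traj: Trajectory,
    structure: StructureModel,
    path: TunnelPath,
    capture_radius: float = 2.0,
    step: float = 1.0,
) -> ChannelProfile:
    """Fraction of frames with a water oxygen near each channel coordinate.

    Water presence is keyed on the oxygen atom only.  With a periodic box
    the within-radius test uses minimum-image distances.
    """
    traj.check_against(structure)
    if traj.n_frames == 0:
        raise ValueError("trajectory has zero frames")
    ox = _water_oxygen_indices(structure)
    if len(ox) == 0:
        raise ValueError("no waters in system")
    rgrid, points = sample_coordinates(path, step)
    counts = np.zeros(len(rgrid), int)
    box = structure.box
    query = points if box is None else np.mod(points, box)
    for f in range(traj.n_frames):
        waters = traj.frames[f][ox]
        if box is not None:
            tree = cKDTree(np.mod(waters, box), boxsize=box)
        else:
            tree = cKDTree(waters)
        hits = tree.query_ball_point(query, capture_radius)
        counts += np.array([len(h) > 0 for h in hits], int)
    occ = counts / traj.n_frames
    return ChannelProfile(
        coordinate=rgrid,
        occupancy=occ,
        occupancy_sd=np.zeros_like(occ),
        n_frames=traj.n_frames,
        replicas=[traj.replica_id],
    )


def aggregate_replicas(profiles, normalize: bool = False) -> ChannelProfile:
    """Mean ± SD across replica profiles on a shared coordinate grid.

    SD uses the population convention (ddof=0) across replicas.  With
    ``normalize=True`` the mean occupancy is rescaled by its own maximum
    so the peak reads 1 (the SD is scaled by the same factor); this is
    the per-profile-max normalisation mode.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to aggregate")
    grid = profiles[0].coordinate
    for p in profiles[1:]:
        if len(p.coordinate) != len(grid) or not np.allclose(p.coordinate, grid):
            raise ValueError("profiles have mismatched coordinate grids; "
                             "resample before aggregating")
    out = ChannelProfile(
        coordinate=grid.copy(),
        n_frames=sum(p.n_frames for p in profiles),
        replicas=[r for p in profiles for r in p.replicas],
    )
    if all(p.occupancy is not None for p in profiles):
        occ = np.stack([p.occupancy for p in profiles])
        mean = occ.mean(axis=0)
        sd = occ.std(axis=0, ddof=0)
        if normalize:
            peak = mean.max()
            if peak > 0:
                mean = mean / peak
                sd = sd / peak
        out.occupancy = np.clip(mean, 0.0, None)
        out.occupancy_sd = sd
    if all(p.field_vector is not None for p in profiles):
        vec = np.stack([p.field_vector for p in profiles]).mean(axis=0)
        out.field_vector = vec
        mags = np.stack([p.field_magnitude for p in profiles])
        out.field_magnitude = mags.mean(axis=0)
    return out


def electric_field(
    traj: Trajectory,
    structure: StructureModel,
    path: TunnelPath,
    exclusion_radius: float = 2.0,
    step: float = 1.0,
    include_within_instead: bool = False,
    per_frame_magnitude: bool = False,
) -> ChannelProfile:
    """Coulomb field of the protein charges along the channel coordinate.

    E(point) = Σ_i k·q_i·(point − r_i)/|point − r_i|³ over non-solvent
    source atoms with |point − r_i| > ``exclusion_radius`` (sources inside
    the exclusion sphere are omitted to avoid near-singular contributions;
    ``include_within_instead`` flips the cutoff to keep only nearby
    sources).  No dielectric screening is applied.
    """
    traj.check_against(structure)
    if traj.n_frames == 0:
        raise ValueError("trajectory has zero frames")
    solvent = structure.solvent_mask
    src = np.flatnonzero(~solvent)
    q = structure.charges[src]
    if np.all(q == 0):
        warnings.warn("all partial charges are zero; field is identically zero")
    rgrid, points = sample_coordinates(path, step)
    acc = np.zeros((len(rgrid), 3))
    mag_acc = np.zeros(len(rgrid))
    box = structure.box
    for f in range(traj.n_frames):
        pos = traj.frames[f][src]
        diff = points[:, None, :] - pos[None, :, :]  # (n_pts, n_src, 3)
        if box is not None:
            diff -= box * np.rint(diff / box)
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        r = np.sqrt(r2)
        if include_within_instead:
            keep = (r <= exclusion_radius) & (r > 1e-9)
        else:
            keep = r > exclusion_radius
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(keep, COULOMB_V_ANG * q[None, :] / (r2 * r), 0.0)
        frame_field = np.einsum("ij,ijk->ik", w, diff)
        acc += frame_field
        mag_acc += np.linalg.norm(frame_field, axis=1)
    vec = acc / traj.n_frames
    if per_frame_magnitude:
        mag = mag_acc / traj.n_frames
    else:
        mag = np.linalg.norm(vec, axis=1)
    return ChannelProfile(
        coordinate=rgrid,
        field_vector=vec,
        field_magnitude=mag,
        n_frames=traj.n_frames,
        replicas=[traj.replica_id],
    )


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation+translation mapping mobile onto reference (SVD)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def superpose(
    traj: Trajectory,
    structure: StructureModel,
    selection,
) -> tuple[Trajectory, np.ndarray]:
    """Least-squares rigid-body fit of every frame onto the reference.

    ``selection`` is a list of residue selector strings or an explicit
    array of atom indices; the fit uses those atoms, the transform is
    applied to all.  Returns the superposed trajectory and per-frame RMSD
    (Å) over the selection.
    """
    from .core import resolve_residues

    if isinstance(selection, (list, tuple)) and selection and isinstance(
        selection[0], str
    ):
        keys = set(resolve_residues(structure, selection))
        idx = np.array(
            [
                i
                for i, a in enumerate(structure.atoms)
                if (a.chain, a.residue_id) in keys
            ],
            int,
        )
    else:
        idx = np.asarray(selection, int)
    if len(idx) < 3:
        raise ValueError("superposition selection must cover at least 3 atoms")
    ref = structure.positions[idx]
    frames = np.empty_like(traj.frames)
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans = _kabsch(traj.frames[f][idx], ref)
        frames[f] = traj.frames[f] @ rot.T + trans
        delta = frames[f][idx] - ref
        rmsd[f] = np.sqrt((delta**2).sum() / len(idx))
    return (
        Trajectory(frames, frame_interval=traj.frame_interval,
                   replica_id=traj.replica_id),
        rmsd,
    )
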