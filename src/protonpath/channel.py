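"""Membrane-spanning channel detection in sphere-approximated structures.

Heavy protein atoms are treated as hard spheres of their van der Waals
radii.  Free space is discretised on a regular grid; each voxel stores
its *clearance*, the distance to the nearest obstacle vdW surface, i.e.
the radius of the largest spherical probe centred there.  A channel from
a seed residue to bulk solvent on both membrane sides is found as the
widest path on the voxel graph: the path maximising the minimum
clearance along it (the bottleneck radius), with ties broken by shorter
arc length.  A voxel is passable only if its clearance is at least the
probe radius.

The voxel graph is 26-connected with Euclidean edge lengths.  Bulk
solvent is defined, by default, as the two slabs beyond the obstacle
z-extent (membrane normal taken as z); the plane offsets and the axis
are configurable.  Clearance is capped at ``CLEARANCE_CAP`` (10 Å):
distances beyond the cap can never be a bottleneck for channels of
interest and the cap bounds the per-atom update neighbourhood.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StructureModel, resolve_residues
from .io import load_residue_classes

__all__ = [
    "SearchSpec",
    "BulkDefinition",
    "CavityGrid",
    "TunnelPath",
    "build_grid",
    "find_channel",
    "extend_to_bulk",
    "lining_profile",
    "clearance_at",
    "ChannelBlockedError",
    "SeedBuriedError",
]

CLEARANCE_CAP = 10.0  # Å; documented maximum stored clearance

# 26-connected neighbourhood offsets and their Euclidean lengths (in voxels)
_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)
_OFFSET_LEN = np.linalg.norm(_OFFSETS, axis=1)


class ChannelBlockedError(RuntimeError):
    def __init__(self, side: str, best_bottleneck: float):
        self.side = side
        self.best_bottleneck = best_bottleneck
        super().__init__(
            f"channel blocked toward {side} side: best achievable bottleneck "
            f"{best_bottleneck:.3f} Å"
        )


class SeedBuriedError(RuntimeError):
    pass


@dataclass
class BulkDefinition:
    """Bulk-solvent rule: slabs beyond the obstacle extent along ``axis``.

    A voxel is N-side bulk if its coordinate along the axis is below
    (obstacle minimum − ``lower_offset``), and P-side bulk above
    (obstacle maximum + ``upper_offset``).  Negative offsets move the
    bulk planes into the protein extent, which is how solvent-exposed
    vestibules are claimed as exits.
    """

    axis: int = 2
    lower_offset: float = 0.0
    upper_offset: float = 0.0


@dataclass
class SearchSpec:
    """Parameters of one channel search.

    ``start`` is a residue selector (``"chain:resid"`` or
    ``"RESNAME+resid"``) resolving to exactly one residue, or an explicit
    seed point (3-vector, Å).  ``excluded_residues`` are removed from the
    obstacle set before clearance evaluation — protonatable residues and
    the bulky gating residues lining the channel are excluded so that
    their side chains do not sever the path they themselves gate.
    """

    start: object  # selector string or 3-vector
    probe_radius: float = 0.9
    excluded_residues: list = field(default_factory=list)
    bulk: BulkDefinition = field(default_factory=BulkDefinition)

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")


@dataclass
class TunnelPath:
    """Arc-length-parameterised channel centerline.

    ``arclength`` (the channel coordinate R, Å) starts at 0 at the N-side
    terminus; ``local_radius`` is the clearance at each centerline point
    evaluated against the obstacle set.  ``segments`` labels each point
    with its provenance (``n_leg``/``seed``/``p_leg``/``extension``).
    """

    points: np.ndarray
    local_radius: np.ndarray
    segments: list[str]
    reached_bulk: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.local_radius = np.asarray(self.local_radius, float)
        if len(self.points) < 2:
            raise ValueError("a path needs at least two points")

    @property
    def arclength(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def bottleneck_radius(self) -> float:
        return float(self.local_radius.min())

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "R": self.arclength,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "local_radius": self.local_radius,
                "segment": self.segments,
            }
        )

    def point_at(self, r: float) -> np.ndarray:
        """Centerline point at channel coordinate ``r`` (linear interp)."""
        s = self.arclength
        return np.array(
            [np.interp(r, s, self.points[:, i]) for i in range(3)]
        )


class CavityGrid:
    """Clearance field of the free space around an obstacle set."""

    def __init__(self, origin, spacing, clearance, obstacle_pos, obstacle_rad,
                 obstacle_extent):
        self.origin = np.asarray(origin, float)
        self.spacing = float(spacing)
        self.clearance = clearance  # (nx, ny, nz), negative inside atoms
        self.obstacle_positions = obstacle_pos
        self.obstacle_radii = obstacle_rad
        self.obstacle_extent = obstacle_extent  # (min_xyz, max_xyz) of surfaces

    @property
    def shape(self):
        return self.clearance.shape

    @property
    def included_mask(self) -> np.ndarray:
        """Voxels not inside any obstacle sphere."""
        return self.clearance > 0

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def voxel_centers(self, idxs: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idxs, float) * self.spacing

    def nearest_voxel(self, point) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point, float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.array(self.shape) - 1).astype(int)
        return tuple(idx)

    def bulk_masks(self, bulk: BulkDefinition) -> tuple[np.ndarray, np.ndarray]:
        """(n_side, p_side) boolean voxel masks for the bulk slabs."""
        ax = bulk.axis
        n = self.shape[ax]
        coords = self.origin[ax] + np.arange(n) * self.spacing
        lo = self.obstacle_extent[0][ax] - bulk.lower_offset
        hi = self.obstacle_extent[1][ax] + bulk.upper_offset
        line_n = coords < lo
        line_p = coords > hi
        shape = [1, 1, 1]
        shape[ax] = n
        n_mask = np.zeros(self.shape, bool) | line_n.reshape(shape)
        p_mask = np.zeros(self.shape, bool) | line_p.reshape(shape)
        return n_mask, p_mask


def clearance_at(points, positions, radii, cap: float = CLEARANCE_CAP):
    """Exact clearance of arbitrary points against an obstacle sphere set.

    Used both to build grids and to re-evaluate radii on smoothed
    centerlines; with no obstacles every point gets the cap.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(positions) == 0:
        return np.full(len(points), cap)
    d = np.linalg.norm(points[:, None, :] - positions[None, :, :], axis=2)
    return np.minimum((d - radii[None, :]).min(axis=1), cap)


def _obstacle_set(structure: StructureModel, spec: SearchSpec,
                  extra_excluded_keys: set | None = None):
    excluded = set(extra_excluded_keys or ())
    selectors = [s for s in spec.excluded_residues]
    if selectors:
        excluded |= set(resolve_residues(structure, selectors))
    keep = []
    for i, a in enumerate(structure.atoms):
        if a.is_solvent or not a.is_heavy:
            continue
        if (a.chain, a.residue_id) in excluded:
            continue
        keep.append(i)
    keep = np.array(keep, int)
    pos = structure.positions[keep] if len(keep) else np.empty((0, 3))
    rad = structure.vdw_radii[keep] if len(keep) else np.empty(0)
    return pos, rad


def build_grid(
    structure: StructureModel,
    spec: SearchSpec,
    spacing: float = 0.8,
    margin=4.0,
) -> CavityGrid:
    """Discretise clearance on a regular grid around the obstacle set.

    The grid covers the obstacle bounding box plus ``margin`` on every
    side (scalar, or per-axis 3-vector; a negative lateral margin trims
    the grid *inside* the obstacle extent, which prevents searches from
    walking around a finite membrane slab instead of through it).
    Clearance is computed per atom over its local influence cube
    (radius + cap), keeping the cost linear in the atom count.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    margin = np.broadcast_to(np.asarray(margin, float), (3,)).copy()
    pos, rad = _obstacle_set(structure, spec)
    if len(pos) == 0:
        origin = np.zeros(3)
        n = max(int(np.ceil(2 * abs(margin).max() / spacing)) + 1, 2)
        clearance = np.full((n, n, n), CLEARANCE_CAP)
        extent = (np.zeros(3), np.zeros(3))
        return CavityGrid(origin, spacing, clearance, pos, rad, extent)

    lo = (pos - rad[:, None]).min(axis=0)
    hi = (pos + rad[:, None]).max(axis=0)
    origin = lo - margin
    shape = np.ceil((hi + margin - origin) / spacing).astype(int) + 1
    if np.any(shape < 2):
        raise ValueError("margin trims the grid away entirely")
    clearance = np.full(tuple(shape), CLEARANCE_CAP)

    axes = [origin[d] + np.arange(shape[d]) * spacing for d in range(3)]
    for p, r in zip(pos, rad):
        reach = r + CLEARANCE_CAP
        sl = []
        ix = []
        for d in range(3):
            i0 = int(np.floor((p[d] - reach - origin[d]) / spacing))
            i1 = int(np.ceil((p[d] + reach - origin[d]) / spacing))
            i0 = max(i0, 0)
            i1 = min(i1, shape[d] - 1)
            sl.append(slice(i0, i1 + 1))
            ix.append(axes[d][i0 : i1 + 1] - p[d])
        dx, dy, dz = np.meshgrid(*ix, indexing="ij")
        d = np.sqrt(dx * dx + dy * dy + dz * dz) - r
        block = clearance[tuple(sl)]
        np.minimum(block, d, out=block)
    extent = (pos - rad[:, None]).min(axis=0), (pos + rad[:, None]).max(axis=0)
    return CavityGrid(origin, spacing, clearance, pos, rad, extent)


def _seed_voxel(grid: CavityGrid, structure: StructureModel, spec: SearchSpec,
                search_radius: float = 6.0) -> tuple[int, int, int]:
    if isinstance(spec.start, str):
        keys = resolve_residues(structure, [spec.start])
        if len(keys) != 1:
            raise ValueError(f"start selector {spec.start!r} must resolve to "
                             f"exactly one residue, got {len(keys)}")
        idxs = structure.residue_atoms()[keys[0]]
        point = structure.positions[idxs].mean(axis=0)
    else:
        point = np.asarray(spec.start, float).reshape(3)
    center = grid.nearest_voxel(point)
    if grid.clearance[center] >= spec.probe_radius:
        return center
    # search nearby voxels for the closest passable one
    reach = int(np.ceil(search_radius / grid.spacing))
    best = None
    best_d = np.inf
    shape = grid.shape
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            for dk in range(-reach, reach + 1):
                i, j, k = center[0] + di, center[1] + dj, center[2] + dk
                if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                    continue
                if grid.clearance[i, j, k] >= spec.probe_radius:
                    d = di * di + dj * dj + dk * dk
                    if d < best_d:
                        best_d, best = d, (i, j, k)
    if best is None:
        raise SeedBuriedError(
            f"seed buried: no passable voxel within {search_radius} Å of the "
            "start residue"
        )
    return best


def _widest_paths(grid: CavityGrid, seed: tuple[int, int, int],
                  passable: np.ndarray, stop_masks=None):
    """Lexicographic (max bottleneck, then min length) Dijkstra from seed.

    The bottleneck of a voxel is the best achievable minimum clearance
    over seed→voxel paths; among maximin paths the shortest arc length is
    kept.  Because the heap pops labels in (bottleneck desc, length asc)
    order, the first settled voxel inside each ``stop_masks`` entry is
    that region's lexicographic optimum; the search stops once every
    region has been hit.  Returns (bneck, dist, parent, strides, hits).
    """
    shape = grid.shape
    clear = grid.clearance
    n = int(np.prod(shape))
    bneck = np.full(n, -np.inf)
    dist = np.full(n, np.inf)
    parent = np.full(n, -1, dtype=np.int64)
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)

    if not passable[seed]:
        raise SeedBuriedError("seed voxel is not passable")
    s = int(seed[0] * strides[0] + seed[1] * strides[1] + seed[2])
    bneck[s] = clear[seed]
    dist[s] = 0.0
    heap = [(-clear[seed], 0.0, s)]
    edge_len = _OFFSET_LEN * grid.spacing
    off_flat = _OFFSETS @ strides
    shape_arr = np.array(shape)
    flat_masks = (
        [m.ravel() for m in stop_masks] if stop_masks is not None else None
    )
    hits = [None] * len(stop_masks) if stop_masks is not None else None
    while heap:
        nb, d, u = heapq.heappop(heap)
        if (-nb, d) != (bneck[u], dist[u]):
            continue
        if flat_masks is not None:
            for mi, fm in enumerate(flat_masks):
                if hits[mi] is None and fm[u]:
                    hits[mi] = u
            if all(h is not None for h in hits):
                break
        ui = np.array([u // strides[0], (u // strides[1]) % shape[1],
                       u % shape[2]])
        nbr_idx = ui[None, :] + _OFFSETS
        ok = np.all((nbr_idx >= 0) & (nbr_idx < shape_arr[None, :]), axis=1)
        for m in np.flatnonzero(ok):
            v = u + off_flat[m]
            vi = tuple(nbr_idx[m])
            if not passable[vi]:
                continue
            cand_b = min(-nb, clear[vi])
            cand_d = d + edge_len[m]
            if (cand_b > bneck[v]) or (
                cand_b == bneck[v] and cand_d < dist[v] - 1e-12
            ):
                bneck[v] = cand_b
                dist[v] = cand_d
                parent[v] = u
                heapq.heappush(heap, (-cand_b, cand_d, v))
    return bneck, dist, parent, strides, hits


def widest_voxel_path(
    grid: CavityGrid,
    seed: tuple[int, int, int],
    target_mask: np.ndarray,
    probe_radius: float,
):
    """Widest path from a seed voxel to a target voxel region.

    Returns ``(bottleneck, voxel_path)`` where ``bottleneck`` is the
    maximum over paths of the minimum clearance along the path, over
    voxels with clearance ≥ ``probe_radius``; among maximin paths the
    shortest (Euclidean edge lengths, 26-connectivity) is returned.
    Returns ``(best_achievable, None)`` when no passable path reaches the
    target region, where ``best_achievable`` is the bottleneck ignoring
    the probe threshold.
    """
    passable = grid.clearance >= probe_radius
    bneck, dist, parent, strides, hits = _widest_paths(
        grid, seed, passable, stop_masks=[target_mask]
    )
    if hits[0] is None:
        return _best_achievable(grid, seed, target_mask), None
    path = _trace_back(parent, strides, grid.shape, hits[0])
    return float(bneck[hits[0]]), path


def _trace_back(parent, strides, shape, target_flat):
    path = []
    u = target_flat
    while u >= 0:
        path.append(
            (u // strides[0], (u // strides[1]) % shape[1], u % shape[2])
        )
        u = parent[u]
    return path[::-1]


def _smooth(points: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; endpoints kept fixed."""
    if window <= 1 or len(points) < window:
        return points.copy()
    out = points.copy()
    half = window // 2
    for i in range(1, len(points) - 1):
        lo = max(0, i - half)
        hi = min(len(points), i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def find_channel(
    grid: CavityGrid,
    spec: SearchSpec,
    structure: StructureModel | None = None,
    smoothing_window: int = 3,
) -> TunnelPath:
    """Find the widest seed→bulk channel through both membrane sides.

    From the seed voxel, the widest (maximin-clearance) path is traced to
    the N-side and to the P-side bulk independently and the two legs are
    concatenated into one N→P path through the seed.  The voxel
    centerline is smoothed by a centered moving average (window
    ``smoothing_window``); local radii are then re-evaluated exactly
    against the obstacle spheres, and any smoothed point whose clearance
    would fall below the probe radius reverts to its raw voxel position.
    """
    if structure is not None:
        seed = _seed_voxel(grid, structure, spec)
    else:
        seed = _seed_voxel_from_point(grid, spec)
    n_mask, p_mask = grid.bulk_masks(spec.bulk)

    legs = []
    for side, mask in (("N", n_mask), ("P", p_mask)):
        bottleneck, leg = widest_voxel_path(grid, seed, mask, spec.probe_radius)
        if leg is None:
            raise ChannelBlockedError(side, bottleneck)
        legs.append(leg)

    n_leg, p_leg = legs
    voxels = n_leg[::-1] + p_leg[1:]  # N bulk -> seed -> P bulk
    seed_pos = n_leg[::-1].index(seed) if seed in n_leg else len(n_leg) - 1
    segments = (
        ["n_leg"] * seed_pos + ["seed"] + ["p_leg"] * (len(voxels) - seed_pos - 1)
    )
    points = grid.voxel_centers(np.array(voxels))
    smoothed = _smooth(points, smoothing_window)
    radii = clearance_at(smoothed, grid.obstacle_positions, grid.obstacle_radii)
    bad = radii < spec.probe_radius
    if np.any(bad):
        smoothed[bad] = points[bad]
        radii[bad] = clearance_at(
            points[bad], grid.obstacle_positions, grid.obstacle_radii
        )
    return TunnelPath(points=smoothed, local_radius=radii, segments=segments)


def _seed_voxel_from_point(grid: CavityGrid, spec: SearchSpec):
    if isinstance(spec.start, str):
        raise ValueError("a StructureModel is required to resolve a residue "
                         "selector seed")
    center = grid.nearest_voxel(np.asarray(spec.start, float))
    if grid.clearance[center] >= spec.probe_radius:
        return center
    fake = SearchSpec(start=np.asarray(spec.start, float),
                      probe_radius=spec.probe_radius)
    # reuse the neighbourhood scan with a structure-free path
    reach = int(np.ceil(6.0 / grid.spacing))
    shape = grid.shape
    best, best_d = None, np.inf
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            for dk in range(-reach, reach + 1):
                i, j, k = center[0] + di, center[1] + dj, center[2] + dk
                if not (0 <= i < shape[0] and 0 <= j < shape[1]
                        and 0 <= k < shape[2]):
                    continue
                if grid.clearance[i, j, k] >= fake.probe_radius:
                    d = di * di + dj * dj + dk * dk
                    if d < best_d:
                        best_d, best = d, (i, j, k)
    if best is None:
        raise SeedBuriedError("seed buried: no passable voxel near seed point")
    return best


def _best_achievable(grid: CavityGrid, seed, mask) -> float:
    """Best bottleneck toward a bulk mask ignoring the probe threshold."""
    passable = grid.clearance > 0
    if not passable[seed]:
        return 0.0
    bneck, _, _, _, _ = _widest_paths(grid, seed, passable)
    cand = bneck[mask.ravel()]
    cand = cand[np.isfinite(cand) & (cand > -np.inf)]
    return float(cand.max()) if len(cand) else 0.0


def extend_to_bulk(
    path: TunnelPath,
    grid: CavityGrid,
    spec: SearchSpec,
    max_extension: float = 10.0,
) -> TunnelPath:
    """Append minimal passable extensions from each terminus to bulk.

    Automated replacement for manual tunnel curation: each terminus not
    already in a bulk slab is connected to the nearest bulk voxel by a
    shortest passable path, capped at ``max_extension`` Å.  If a terminus
    cannot reach bulk a warning is emitted and the path is returned with
    ``reached_bulk=False``.
    """
    n_mask, p_mask = grid.bulk_masks(spec.bulk)
    passable = grid.clearance >= spec.probe_radius
    points = [path.points.copy()]
    segments = list(path.segments)
    reached = True

    def bfs_extension(terminus, mask):
        start = grid.nearest_voxel(terminus)
        if mask[start]:
            return []
        if not passable[start]:
            return None
        max_steps = int(np.ceil(max_extension / grid.spacing)) + 1
        prev = {start: None}
        frontier = [start]
        shape = grid.shape
        for _ in range(max_steps):
            nxt = []
            for u in frontier:
                for off in _OFFSETS:
                    v = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
                    if not all(0 <= v[d] < shape[d] for d in range(3)):
                        continue
                    if v in prev or not passable[v]:
                        continue
                    prev[v] = u
                    if mask[v]:
                        chain = [v]
                        while prev[chain[-1]] is not None:
                            chain.append(prev[chain[-1]])
                        return chain[::-1][1:]  # drop start voxel
                    nxt.append(v)
            frontier = nxt
            if not frontier:
                break
        return None

    head = bfs_extension(path.points[0], n_mask)
    tail = bfs_extension(path.points[-1], p_mask)
    if head:
        pts = grid.voxel_centers(np.array(head))[::-1]
        points.insert(0, pts)
        segments = ["extension"] * len(pts) + segments
    if tail:
        pts = grid.voxel_centers(np.array(tail))
        points.append(pts)
        segments = segments + ["extension"] * len(pts)
    if head is None or tail is None:
        warnings.warn("terminus sealed: could not extend path to bulk")
        reached = False
    if head == [] and tail == []:
        return path  # already reaching bulk on both sides: unchanged
    all_points = np.vstack(points)
    radii = clearance_at(all_points, grid.obstacle_positions, grid.obstacle_radii)
    return TunnelPath(points=all_points, local_radius=radii, segments=segments,
                      reached_bulk=reached)


def lining_profile(
    path: TunnelPath,
    structure: StructureModel,
    contact_cutoff: float = 4.0,
    step: float = 1.0,
) -> pd.DataFrame:
    """Residue lining and gate-free radius along the channel coordinate.

    For each coordinate sample, lists residues with any heavy atom within
    ``contact_cutoff`` of the centerline point, classified
    polar/nonpolar/titratable from the bundled residue-class table, and
    evaluates the channel radius with titratable residues removed from
    the obstacle set (so protonatable side chains do not mask the
    geometric lumen they line).
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    classes = load_residue_classes()
    rgrid = np.arange(0.0, path.length + step / 2, step)
    samples = np.array([path.point_at(r) for r in rgrid])

    heavy = [
        (i, a) for i, a in enumerate(structure.atoms)
        if a.is_heavy and not a.is_solvent
    ]
    pos = np.array([a.position for _, a in heavy]) if heavy else np.empty((0, 3))
    titratable_keys = {
        (a.chain, a.residue_id)
        for _, a in heavy
        if classes.get(a.residue_name, "nonpolar") == "titratable"
    }
    keep = np.array(
        [(a.chain, a.residue_id) not in titratable_keys for _, a in heavy],
        bool,
    ) if heavy else np.empty(0, bool)
    rad = np.array([a.vdw_radius for _, a in heavy]) if heavy else np.empty(0)
    radius = clearance_at(samples, pos[keep], rad[keep])

    rows = []
    for r, point, rad_val in zip(rgrid, samples, radius):
        residues = {}
        if len(pos):
            d = np.linalg.norm(pos - point, axis=1)
            for m in np.flatnonzero(d <= contact_cutoff):
                a = heavy[m][1]
                key = (a.chain, a.residue_id)
                residues[key] = a.residue_name
        counts = {"nonpolar": 0, "polar": 0, "titratable": 0}
        names = []
        for (chain, resid), resname in sorted(residues.items()):
            cls = classes.get(resname, "nonpolar")
            counts[cls] += 1
            names.append(f"{resname}{resid}:{chain}")
        total = max(sum(counts.values()), 1)
        rows.append(
            {
                "R": r,
                "radius": rad_val,
                "n_residues": sum(counts.values()),
                "n_nonpolar": counts["nonpolar"],
                "n_polar": counts["polar"],
                "n_titratable": counts["titratable"],
                "frac_nonpolar": counts["nonpolar"] / total,
                "frac_polar": counts["polar"] / total,
                "frac_titratable": counts["titratable"] / total,
                "residues": ";".join(names),
            }
        )
    return pd.DataFrame(rows)
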