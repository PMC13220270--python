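import numpy as np
import pytest

from protonpath.channel import (
    CLEARANCE_CAP,
    BulkDefinition,
    CavityGrid,
    ChannelBlockedError,
    SearchSpec,
    TunnelPath,
    build_grid,
    clearance_at,
    extend_to_bulk,
    find_channel,
    lining_profile,
    widest_voxel_path,
)
from protonpath.core import AtomRecord, StructureModel
from protonpath.synthetic import ChannelFixtureSpec, make_channel_structure

from oracles import brute_clearance, maximin_bottleneck_floodfill


def sphere(serial, pos, radius=2.0, resname="ALA", resid=None, chain="A"):
    return AtomRecord(serial, f"C{serial}", resname, resid or serial, chain,
                      np.array(pos, float), radius, 0.0)


class TestClearance:
    def test_single_atom_clearance(self):
        """A voxel 5 Å from the center of a 2 Å sphere clears 3 Å."""
        model = StructureModel([sphere(1, (0, 0, 0), 2.0)])
        spec = SearchSpec(start=np.array([5.0, 0, 0]))
        grid = build_grid(model, spec, spacing=1.0, margin=6.0)
        vox = grid.nearest_voxel([5.0, 0.0, 0.0])
        assert grid.clearance[vox] == pytest.approx(3.0, abs=1e-9)

    def test_empty_structure_capped_sentinel(self):
        grid = build_grid(StructureModel([]), SearchSpec(start=np.zeros(3)),
                          spacing=1.0)
        assert np.all(grid.clearance == CLEARANCE_CAP)

    def test_midpoint_between_two_atoms_matches_brute_force(self):
        positions = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        radii = np.array([2.0, 2.0])
        model = StructureModel([sphere(1, positions[0]), sphere(2, positions[1])])
        spec = SearchSpec(start=np.array([5.0, 0, 0]))
        grid = build_grid(model, spec, spacing=1.0, margin=4.0)
        vox = grid.nearest_voxel([5.0, 0.0, 0.0])
        expected = brute_clearance(grid.voxel_center(vox), positions, radii)
        assert grid.clearance[vox] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.0)

    def test_grid_clearance_matches_brute_force_everywhere(self):
        rng = np.random.default_rng(4)
        atoms = [sphere(i + 1, rng.uniform(0, 10, 3), rng.uniform(1, 2))
                 for i in range(15)]
        model = StructureModel(atoms)
        grid = build_grid(model, SearchSpec(start=np.zeros(3)), spacing=1.5,
                          margin=2.0)
        pos = model.positions
        rad = model.vdw_radii
        idxs = [(0, 0, 0), (3, 4, 2), (5, 5, 5), tuple(np.array(grid.shape) - 1)]
        for idx in idxs:
            expected = min(brute_clearance(grid.voxel_center(idx), pos, rad),
                           CLEARANCE_CAP)
            assert grid.clearance[idx] == pytest.approx(expected, abs=1e-9)


class TestFindChannel:
    def test_cylinder_bottleneck_and_orientation(self, straight_fixture,
                                                 straight_grid):
        """The straight 3 Å lumen is found with its analytic bottleneck,
        oriented N→P (increasing z), spanning the slab."""
        _, _, truth = straight_fixture
        grid, search = straight_grid
        path = find_channel(grid, search)
        assert path.bottleneck_radius == pytest.approx(
            truth.bottleneck_radius, abs=grid.spacing)
        assert path.points[0][2] < path.points[-1][2]
        assert path.points[0][2] < 0 and path.points[-1][2] > 40.0
        # centerline stays near the channel axis inside the slab
        inside = (path.points[:, 2] > 5) & (path.points[:, 2] < 35)
        lateral = np.linalg.norm(path.points[inside][:, :2], axis=1)
        assert lateral.max() < 1.5

    def test_blocked_channel_reports_best_bottleneck(self):
        spec = ChannelFixtureSpec(length=40.0, lumen_radius=3.0,
                                  blockers=[(20.0, 0.5)])
        model, truth = make_channel_structure(spec)
        search = SearchSpec(start=truth.point_at(5.0), probe_radius=0.9)
        grid = build_grid(model, search, spacing=0.8, margin=[-2, -2, 4])
        with pytest.raises(ChannelBlockedError, match="P side") as err:
            find_channel(grid, search)
        assert err.value.best_bottleneck == pytest.approx(0.5, abs=grid.spacing)

    def test_bend_arc_length_matches_ground_truth(self):
        spec = ChannelFixtureSpec(length=40.0, lumen_radius=3.0,
                                  geometry="l_bend")
        model, truth = make_channel_structure(spec)
        search = SearchSpec(start=truth.point_at(truth.length / 2))
        grid = build_grid(model, search, spacing=0.8, margin=[-2, -2, 4])
        path = find_channel(grid, search)
        # found arc length within a few voxels of the analytic centerline
        # (the found path also runs a little beyond the slab faces)
        assert path.length == pytest.approx(truth.length, abs=6 * grid.spacing)
        assert path.length > 40.0  # strictly longer than the z-extent

    def test_arc_length_bounds_euclidean_distance(self, straight_grid):
        grid, search = straight_grid
        path = find_channel(grid, search)
        euclid = np.linalg.norm(path.points[-1] - path.points[0])
        assert path.length >= euclid - 1e-9

    def test_smoothed_radius_never_below_probe(self, straight_grid):
        grid, search = straight_grid
        path = find_channel(grid, search)
        assert path.local_radius.min() >= search.probe_radius - 1e-9


def random_cavity_grid(rng, shape=(12, 12, 12), n_blobs=4):
    """A synthetic clearance field: soft blobs of free space in a solid."""
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                  indexing="ij"), axis=-1).astype(float)
    clearance = np.full(shape, -1.0)
    for _ in range(n_blobs):
        center = rng.uniform(0, np.array(shape) - 1)
        width = rng.uniform(1.5, 4.0)
        height = rng.uniform(1.0, 4.0)
        d2 = ((coords - center) ** 2).sum(axis=-1)
        clearance = np.maximum(clearance, height * np.exp(-d2 / (2 * width**2)))
    # quantise so ties exercise the tie-breaking logic
    clearance = np.round(clearance, 2)
    return CavityGrid(np.zeros(3), 1.0, clearance, np.empty((0, 3)),
                      np.empty(0), (np.zeros(3), np.array(shape, float)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(8))
    def test_widest_path_matches_floodfill_oracle(self, trial):
        """Dijkstra bottleneck equals brute-force maximin on random cavities."""
        rng = np.random.default_rng(100 + trial)
        grid = random_cavity_grid(rng)
        probe = 0.2
        passable = grid.clearance >= probe
        if not passable.any():
            pytest.skip("degenerate cavity")
        seed = tuple(np.argwhere(passable)[0])
        target = np.zeros(grid.shape, bool)
        target[:, :, -1] = True
        expected = maximin_bottleneck_floodfill(grid.clearance, passable,
                                                seed, target)
        got, path = widest_voxel_path(grid, seed, target, probe)
        if expected is None:
            assert path is None
        else:
            assert path is not None
            assert got == pytest.approx(expected, abs=0)
            # returned path is feasible and realises its bottleneck
            clear_on_path = [grid.clearance[v] for v in path]
            assert min(clear_on_path) == pytest.approx(got)

    @pytest.mark.parametrize("trial", range(4))
    def test_monotone_in_obstacle_radius(self, trial):
        """On a fixed lattice, growing any obstacle never raises the
        bottleneck and dropping an obstacle never lowers it."""
        rng = np.random.default_rng(300 + trial)
        positions = rng.uniform(2, 14, size=(10, 3))
        radii = rng.uniform(1.0, 2.5, size=10)
        shape = (16, 16, 16)
        coords = np.stack(np.meshgrid(*[np.arange(s, dtype=float)
                                        for s in shape], indexing="ij"),
                          axis=-1).reshape(-1, 3)

        def grid_for(pos, rad):
            clearance = clearance_at(coords, pos, rad).reshape(shape)
            return CavityGrid(np.zeros(3), 1.0, clearance, pos, rad,
                              (np.zeros(3), np.full(3, 15.0)))

        target = np.zeros(shape, bool)
        target[:, :, -1] = True
        probe = 0.3
        base_grid = grid_for(positions, radii)
        passable = base_grid.clearance >= probe
        seed = tuple(np.argwhere(passable)[np.argmax(
            base_grid.clearance[passable])])
        b0, _ = widest_voxel_path(base_grid, seed, target, probe)

        grown = radii.copy()
        grown[trial % len(grown)] += 0.8
        b_grown, _ = widest_voxel_path(grid_for(positions, grown), seed,
                                       target, probe)
        assert b_grown <= b0 + 1e-9

        keep = np.arange(len(radii)) != (trial % len(radii))
        b_drop, _ = widest_voxel_path(
            grid_for(positions[keep], radii[keep]), seed, target, probe)
        assert b_drop >= b0 - 1e-9

    def test_grid_refinement_consistency(self, straight_fixture):
        _, model, truth = straight_fixture
        search = SearchSpec(start=truth.point_at(truth.length / 2))
        bottlenecks = {}
        for spacing in (1.0, 0.5):
            grid = build_grid(model, search, spacing=spacing,
                              margin=[-2, -2, 4])
            bottlenecks[spacing] = find_channel(grid, search).bottleneck_radius
        assert abs(bottlenecks[1.0] - bottlenecks[0.5]) < 1.0


class TestExtendToBulk:
    def test_already_at_bulk_unchanged(self, straight_fixture, straight_grid):
        grid, search = straight_grid
        path = find_channel(grid, search)
        extended = extend_to_bulk(path, grid, search)
        np.testing.assert_array_equal(extended.points, path.points)

    def test_short_path_extended_and_flagged(self, straight_fixture,
                                             straight_grid):
        _, _, truth = straight_fixture
        grid, search = straight_grid
        # truncate the ground-truth path well inside the slab
        inner = TunnelPath(points=truth.points[20:-20],
                           local_radius=truth.local_radius[20:-20],
                           segments=["truth"] * (len(truth.points) - 40))
        extended = extend_to_bulk(inner, grid, search, max_extension=20.0)
        assert extended.length > inner.length
        assert "extension" in extended.segments
        assert extended.reached_bulk

    def test_sealed_terminus_warns_and_flags(self):
        spec = ChannelFixtureSpec(length=40.0, lumen_radius=3.0,
                                  blockers=[(5.0, 0.2), (35.0, 0.2)])
        model, truth = make_channel_structure(spec)
        search = SearchSpec(start=truth.point_at(20.0))
        grid = build_grid(model, search, spacing=0.8, margin=[-2, -2, 4])
        inner = TunnelPath(points=truth.points[60:100],
                           local_radius=truth.local_radius[60:100],
                           segments=["truth"] * 40)
        with pytest.warns(UserWarning, match="sealed"):
            out = extend_to_bulk(inner, grid, search, max_extension=30.0)
        assert not out.reached_bulk


class TestLiningProfile:
    def test_all_nonpolar_lining(self):
        spec = ChannelFixtureSpec(length=30.0, lumen_radius=3.0,
                                  lining=["nonpolar"])
        model, truth = make_channel_structure(spec)
        prof = lining_profile(truth, model, contact_cutoff=6.0)
        interior = prof[(prof.R > 4) & (prof.R < 26)]
        assert (interior.frac_nonpolar == 1.0).all()
        assert (interior.n_titratable == 0).all()

    def test_mixed_lining_classes_reported(self):
        spec = ChannelFixtureSpec(
            length=30.0, lumen_radius=3.0,
            lining=["titratable", "nonpolar", "polar"])
        model, truth = make_channel_structure(spec)
        prof = lining_profile(truth, model, contact_cutoff=6.0)
        assert prof[prof.R < 8].n_titratable.sum() > 0
        assert prof[(prof.R > 12) & (prof.R < 18)].n_nonpolar.sum() > 0
        assert prof[prof.R > 24].n_polar.sum() > 0

    def test_cylinder_radius_profile_constant(self, straight_fixture):
        _, model, truth = straight_fixture
        prof = lining_profile(truth, model, contact_cutoff=6.0)
        interior = prof[(prof.R > 4) & (prof.R < 36)]
        assert np.allclose(interior.radius, 3.0, atol=0.8)

    def test_titratable_residues_excluded_from_radius(self):
        """The gate-free radius ignores titratable side chains: a lysine
        ring narrowing the lumen does not show in the radius profile."""
        spec = ChannelFixtureSpec(length=30.0, lumen_radius=3.0,
                                  lining=["titratable"])
        model, truth = make_channel_structure(spec)
        prof = lining_profile(truth, model, contact_cutoff=6.0)
        interior = prof[(prof.R > 4) & (prof.R < 26)]
        # with the lysine shell removed, clearance exceeds the lumen radius
        assert (interior.radius >= 3.0 - 1e-9).all()
        assert interior.radius.max() > 3.5
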