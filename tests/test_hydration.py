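import numpy as np
import pytest

from protonpath.channel import TunnelPath
from protonpath.core import AtomRecord, ChannelProfile, StructureModel, Trajectory
from protonpath.hydration import (
    COULOMB_V_ANG,
    aggregate_replicas,
    electric_field,
    superpose,
    water_occupancy,
)
from protonpath.synthetic import (
    ChannelFixtureSpec,
    coulomb_field_oracle,
    make_channel_structure,
    make_charge_system,
    make_water_trajectory,
)

from oracles import kabsch_rmsd_scipy


def straight_path(length=10.0, offset=(0.0, 0.0, 0.0)):
    pts = np.array([[0, 0, 0.0], [0, 0, length]]) + np.asarray(offset)
    return TunnelPath(points=pts, local_radius=[3.0, 3.0],
                      segments=["a", "a"])


def water(serial, pos, resid):
    return AtomRecord(serial, "O", "HOH", resid, "W", np.array(pos, float),
                      1.52, 0.0, is_solvent=True)


def protein_atom(serial, pos, charge=0.0, resid=None):
    return AtomRecord(serial, f"C{serial}", "ALA", resid or serial, "A",
                      np.array(pos, float), 1.7, charge)


class TestWaterOccupancy:
    def test_always_present_water_gives_unit_occupancy(self):
        model = StructureModel([protein_atom(1, (5, 5, -5)),
                                water(2, (0, 0, 5), 100)])
        frames = np.repeat(model.positions[None], 10, axis=0)
        prof = water_occupancy(Trajectory(frames), model, straight_path(),
                               capture_radius=2.0, step=5.0)
        assert prof.occupancy[1] == 1.0  # grid point at R=5

    def test_dry_channel_zero_everywhere(self):
        model = StructureModel([protein_atom(1, (5, 5, -5)),
                                water(2, (500, 0, 0), 100)])
        frames = np.repeat(model.positions[None], 5, axis=0)
        prof = water_occupancy(Trajectory(frames), model, straight_path(),
                               step=5.0)
        assert np.all(prof.occupancy == 0.0)

    def test_fractional_occupancy_by_construction(self):
        """A water present in 3 of 10 frames at one point gives 0.3 there
        and 0 elsewhere."""
        model = StructureModel([protein_atom(1, (5, 5, -5)),
                                water(2, (0, 0, 5), 100)])
        frames = np.repeat(model.positions[None], 10, axis=0)
        for f in range(3, 10):  # absent in the last 7 frames
            frames[f, 1] = [900.0, 0, 0]
        prof = water_occupancy(Trajectory(frames), model, straight_path(),
                               capture_radius=2.0, step=5.0)
        np.testing.assert_allclose(prof.occupancy, [0.0, 0.3, 0.0])

    def test_no_waters_is_an_error(self):
        model = StructureModel([protein_atom(1, (5, 5, -5))])
        frames = np.repeat(model.positions[None], 5, axis=0)
        with pytest.raises(ValueError, match="no waters"):
            water_occupancy(Trajectory(frames), model, straight_path())

    def test_zero_frames_is_an_error(self):
        model = StructureModel([water(1, (0, 0, 5), 100)])
        with pytest.raises(ValueError, match="zero frames"):
            water_occupancy(Trajectory(np.empty((0, 1, 3))), model,
                            straight_path())

    def test_invariant_under_frame_reordering_and_rigid_motion(self):
        spec = ChannelFixtureSpec(length=30.0, lumen_radius=3.0)
        model, truth = make_channel_structure(spec)
        combined, traj = make_water_trajectory(
            model, truth, lambda r: 0.5, n_frames=40, seed=7)
        prof = water_occupancy(traj, combined, truth, step=4.5)

        shuffled = Trajectory(traj.frames[::-1].copy())
        prof_shuffled = water_occupancy(shuffled, combined, truth, step=4.5)
        np.testing.assert_array_equal(prof.occupancy, prof_shuffled.occupancy)

        # same rigid motion applied to waters, protein and path together
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 2.0])
        moved = Trajectory(traj.frames @ rot.T + shift)
        moved_path = TunnelPath(points=truth.points @ rot.T + shift,
                                local_radius=truth.local_radius,
                                segments=truth.segments)
        prof_moved = water_occupancy(moved, combined, moved_path, step=4.5)
        np.testing.assert_array_equal(prof.occupancy, prof_moved.occupancy)

    def test_doubling_identical_frames_changes_nothing(self):
        model = StructureModel([water(1, (0, 0, 5), 100)])
        frames = np.repeat(model.positions[None], 4, axis=0)
        doubled = np.repeat(model.positions[None], 8, axis=0)
        p1 = water_occupancy(Trajectory(frames), model, straight_path(),
                             step=5.0)
        p2 = water_occupancy(Trajectory(doubled), model, straight_path(),
                             step=5.0)
        np.testing.assert_array_equal(p1.occupancy, p2.occupancy)

    def test_minimum_image_capture_across_box(self):
        model = StructureModel([water(1, (0, 0, 19.5), 100)],
                               box=np.array([20.0, 20.0, 20.0]))
        frames = model.positions[None]
        path = TunnelPath(points=[[0, 0, 0], [0, 0, 4.0]],
                          local_radius=[3, 3], segments=["a", "a"])
        prof = water_occupancy(Trajectory(frames), model, path,
                               capture_radius=2.0, step=4.0)
        assert prof.occupancy[0] == 1.0  # water is 0.5 Å away through the face


class TestAggregateReplicas:
    def test_mean_and_population_sd(self):
        profs = [ChannelProfile(coordinate=np.arange(2.0),
                                occupancy=np.array([v, v]), n_frames=5,
                                replicas=[i])
                 for i, v in enumerate([0.2, 0.4])]
        agg = aggregate_replicas(profs)
        np.testing.assert_allclose(agg.occupancy, 0.3)
        np.testing.assert_allclose(agg.occupancy_sd, 0.1)
        assert agg.replicas == [0, 1]

    def test_single_replica_identity(self):
        prof = ChannelProfile(coordinate=np.arange(3.0),
                              occupancy=np.array([0.1, 0.2, 0.3]),
                              n_frames=5, replicas=[0])
        agg = aggregate_replicas([prof], normalize=False)
        np.testing.assert_array_equal(agg.occupancy, prof.occupancy)

    def test_normalization_rescales_peak_to_one(self):
        prof = ChannelProfile(coordinate=np.arange(3.0),
                              occupancy=np.array([0.1, 0.5, 0.25]),
                              n_frames=5, replicas=[0])
        agg = aggregate_replicas([prof], normalize=True)
        assert agg.occupancy.max() == pytest.approx(1.0)
        np.testing.assert_allclose(agg.occupancy, [0.2, 1.0, 0.5])

    def test_mismatched_grids_rejected(self):
        a = ChannelProfile(coordinate=np.arange(3.0), occupancy=np.zeros(3))
        b = ChannelProfile(coordinate=np.arange(4.0), occupancy=np.zeros(4))
        with pytest.raises(ValueError, match="grid"):
            aggregate_replicas([a, b])


class TestElectricField:
    def test_single_charge_closed_form(self):
        """+1 e at 5 Å gives k/25 ≈ 0.576 V/Å pointing away from the charge."""
        model = make_charge_system([((0.0, 0.0, 0.0), 1.0)])
        traj = Trajectory(model.positions[None])
        path = TunnelPath(points=[[5, 0, 0], [6, 0, 0]],
                          local_radius=[1, 1], segments=["a", "a"])
        prof = electric_field(traj, model, path, step=1.0)
        assert prof.field_magnitude[0] == pytest.approx(COULOMB_V_ANG / 25.0)
        assert prof.field_magnitude[0] == pytest.approx(0.576, abs=1e-3)
        np.testing.assert_allclose(prof.field_vector[0] /
                                   prof.field_magnitude[0], [1, 0, 0],
                                   atol=1e-12)

    def test_symmetric_charges_cancel(self):
        model = make_charge_system([((0, 0, -4.0), 1.0), ((0, 0, 4.0), 1.0)])
        traj = Trajectory(model.positions[None])
        path = TunnelPath(points=[[0, 0, 0], [0, 1e-6, 0]],
                          local_radius=[1, 1], segments=["a", "a"])
        prof = electric_field(traj, model, path, step=1.0)
        assert prof.field_magnitude[0] == pytest.approx(0.0, abs=1e-12)

    def test_source_inside_exclusion_radius_ignored(self):
        model = make_charge_system([((1.5, 0, 0), 1.0)])
        traj = Trajectory(model.positions[None])
        path = TunnelPath(points=[[0, 0, 0], [0, 0, 1]],
                          local_radius=[1, 1], segments=["a", "a"])
        prof = electric_field(traj, model, path, exclusion_radius=2.0, step=1.0)
        assert prof.field_magnitude[0] == 0.0

    def test_matches_independent_oracle_on_random_systems(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            placements = [(rng.normal(0, 8, 3), rng.normal())
                          for _ in range(rng.integers(2, 12))]
            model = make_charge_system(placements)
            traj = Trajectory(model.positions[None])
            path = TunnelPath(points=[[25, 0, 0], [25, 0, 8]],
                              local_radius=[1, 1], segments=["a", "a"])
            prof = electric_field(traj, model, path, exclusion_radius=2.0,
                                  step=2.0)
            for i, r in enumerate(prof.coordinate):
                expected = coulomb_field_oracle(placements, path.point_at(r),
                                                exclusion_radius=2.0)
                np.testing.assert_allclose(prof.field_vector[i], expected,
                                           rtol=1e-10, atol=1e-14)

    def test_superposition_of_charge_sets(self):
        rng = np.random.default_rng(3)
        set_a = [(rng.normal(0, 6, 3), rng.normal()) for _ in range(4)]
        set_b = [(rng.normal(0, 6, 3), rng.normal()) for _ in range(5)]
        path = TunnelPath(points=[[20, 0, 0], [20, 0, 5]],
                          local_radius=[1, 1], segments=["a", "a"])

        def field_of(placements):
            model = make_charge_system(placements)
            return electric_field(Trajectory(model.positions[None]), model,
                                  path, step=1.0).field_vector

        np.testing.assert_allclose(field_of(set_a + set_b),
                                   field_of(set_a) + field_of(set_b),
                                   rtol=1e-12, atol=1e-15)

    def test_inverse_square_decay(self):
        """log|E| vs log r from one charge has slope −2 within 1%."""
        model = make_charge_system([((0.0, 0.0, 0.0), 1.0)])
        traj = Trajectory(model.positions[None])
        path = TunnelPath(points=[[4, 0, 0], [40, 0, 0]],
                          local_radius=[1, 1], segments=["a", "a"])
        prof = electric_field(traj, model, path, step=2.0)
        r = 4.0 + prof.coordinate
        slope = np.polyfit(np.log(r), np.log(prof.field_magnitude), 1)[0]
        assert slope == pytest.approx(-2.0, rel=0.01)

    def test_uncharged_structure_warns_zero_field(self):
        model = StructureModel([protein_atom(1, (5, 0, 0), 0.0)])
        traj = Trajectory(model.positions[None])
        with pytest.warns(UserWarning, match="zero"):
            prof = electric_field(traj, model, straight_path(), step=5.0)
        assert np.all(prof.field_magnitude == 0.0)


class TestSuperpose:
    def build(self, n=12, seed=5):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 4, size=(n, 3))
        atoms = [protein_atom(i + 1, pos[i]) for i in range(n)]
        return StructureModel(atoms)

    def test_identity_frame_zero_rmsd(self):
        model = self.build()
        traj = Trajectory(model.positions[None])
        fitted, rmsd = superpose(traj, model, np.arange(len(model)))
        assert rmsd[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fitted.frames[0], model.positions,
                                   atol=1e-12)

    def test_rotated_frame_recovered(self):
        model = self.build()
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])  # 90° about z
        traj = Trajectory((model.positions @ rot.T + [3, 4, 5])[None])
        fitted, rmsd = superpose(traj, model, np.arange(len(model)))
        assert rmsd[0] == pytest.approx(0.0, abs=1e-9)

    def test_displaced_atom_matches_scipy_oracle(self):
        model = self.build(n=16)
        moved = model.positions.copy()
        moved[0] += [1.0, 0, 0]
        traj = Trajectory(moved[None])
        _, rmsd = superpose(traj, model, np.arange(len(model)))
        expected = kabsch_rmsd_scipy(moved, model.positions)
        assert rmsd[0] == pytest.approx(expected, abs=1e-9)

    def test_too_small_selection_rejected(self):
        model = self.build()
        traj = Trajectory(model.positions[None])
        with pytest.raises(ValueError, match="3 atoms"):
            superpose(traj, model, [0, 1])
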