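"""The species-decomposed, size-scaled spread statistic."""
import numpy as np
import pytest

import amorphmob as am
from amorphmob.errors import DomainError


def frame_of(positions, species, box=100.0, time=0.0):
    return am.Frame(time=time, positions=np.asarray(positions, float),
                    species=np.array(species, dtype=object), box_side=box)


def brute_force_spread(positions, species, r):
    """Direct-summation oracle for the spread statistic of one frame."""
    pos = np.asarray(positions, float)
    mu = sum(p for p in pos) / len(pos)
    total = 0.0
    for p, sp in zip(pos, species):
        d = p - mu
        if sp == am.LACTOSE:
            d = d / r
        total += d @ d
    return np.sqrt(total / len(pos))


class TestMeanPosition:
    def test_midpoint_of_two_molecules(self):
        f = frame_of([[0, 0, 0], [2, 2, 2]], [am.WATER, am.WATER])
        assert np.allclose(am.mean_position(f), [1, 1, 1])

    def test_single_molecule_is_its_own_centroid(self):
        f = frame_of([[3.0, 4.0, 5.0]], [am.LACTOSE])
        assert np.allclose(am.mean_position(f), [3, 4, 5])

    def test_matches_brute_force_mean_on_mixed_cell(self, small_mixed_frame):
        expected = small_mixed_frame.positions.sum(axis=0) / 100
        assert np.allclose(am.mean_position(small_mixed_frame), expected,
                           atol=1e-12)

    def test_empty_frame_rejected(self):
        with pytest.raises(DomainError):
            am.mean_position(am.Frame.empty(10.0))


class TestScaledDeviations:
    def test_water_at_centroid_is_zero(self):
        f = frame_of([[1, 1, 1]], [am.WATER])
        dev = am.scaled_deviations(f, np.array([1.0, 1.0, 1.0]))
        assert np.allclose(dev, 0)

    def test_lactose_deviation_divided_by_r(self):
        f = frame_of([[9.08, 0, 0]], [am.LACTOSE])
        dev = am.scaled_deviations(f, np.zeros(3), am.AnalysisParams(r=9.08))
        assert np.allclose(dev, [[1, 0, 0]])

    def test_hand_arithmetic_mixed_pair(self):
        f = frame_of([[2, 0, 0], [0, 0, 0]], [am.WATER, am.LACTOSE])
        mu = am.mean_position(f)
        dev = am.scaled_deviations(f, mu, am.AnalysisParams(r=9.08))
        assert np.allclose(dev[0], [1, 0, 0])
        assert np.allclose(dev[1], [-1 / 9.08, 0, 0], atol=1e-12)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(DomainError):
            am.AnalysisParams(r=0.0)


class TestTotalRmsd:
    def test_all_at_centroid_gives_zero(self):
        pos = np.tile([5.0, 5.0, 5.0], (4, 1))
        traj = am.trajectory_from_array(
            [0.0, 1.0], np.stack([pos, pos]),
            np.array([am.WATER] * 4, dtype=object), 10.0)
        assert np.allclose(am.total_rmsd(traj).values, 0)

    def test_symmetric_water_pair_is_one_angstrom(self):
        f = frame_of([[51, 50, 50], [49, 50, 50]], [am.WATER, am.WATER])
        series = am.total_rmsd(am.Trajectory([f]))
        assert series.values[0] == pytest.approx(1.0)

    def test_hand_arithmetic_water_lactose_pair(self):
        f = frame_of([[2, 0, 0], [0, 0, 0]], [am.WATER, am.LACTOSE])
        series = am.total_rmsd(am.Trajectory([f]), am.AnalysisParams(r=9.08))
        expect = np.sqrt((1 + (1 / 9.08) ** 2) / 2)
        assert series.values[0] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.7114, abs=5e-5)

    def test_matches_brute_force_oracle_on_small_fixtures(self, rng):
        for _ in range(10):
            n = rng.integers(1, 11)
            species = rng.choice([am.WATER, am.LACTOSE], size=n)
            pos = rng.uniform(0, 50, size=(n, 3))
            f = frame_of(pos, species)
            got = am.total_rmsd(am.Trajectory([f])).values[0]
            want = brute_force_spread(pos, species, 9.08)
            assert got == pytest.approx(want, abs=1e-12)

    def test_translation_invariance(self, tiny_trajectory, rng):
        shift = rng.uniform(-5, 5, size=3)
        shifted = am.trajectory_from_array(
            tiny_trajectory.times,
            tiny_trajectory.positions_array() + shift,
            tiny_trajectory.species, tiny_trajectory.box_side)
        a = am.total_rmsd(tiny_trajectory).values
        b = am.total_rmsd(shifted).values
        assert np.allclose(a, b, atol=1e-10)

    def test_single_molecule_degenerates_to_zero(self):
        f = frame_of([[1, 2, 3]], [am.LACTOSE])
        assert am.total_rmsd(am.Trajectory([f])).values[0] == 0.0

    def test_r_equal_one_single_species_is_rms_about_centroid(self, rng):
        """With r = 1 and one species the statistic is the classic
        radius-of-gyration-style spread."""
        pos = rng.uniform(0, 20, size=(8, 3))
        f = frame_of(pos, [am.LACTOSE] * 8)
        got = am.total_rmsd(am.Trajectory([f]), am.AnalysisParams(r=1.0))
        mu = pos.mean(axis=0)
        want = np.sqrt(((pos - mu) ** 2).sum(axis=1).mean())
        assert got.values[0] == pytest.approx(want, abs=1e-12)


class TestPerSpecies:
    def test_all_water_equals_total(self, rng):
        pos = rng.uniform(0, 30, size=(2, 6, 3))
        traj = am.trajectory_from_array(
            [0.0, 1.0], pos, np.array([am.WATER] * 6, dtype=object), 30.0)
        water, lactose = am.per_species_rmsd(traj)
        total = am.total_rmsd(traj)
        assert np.allclose(water.values, total.values, atol=1e-12)
        assert not lactose.defined
        assert np.all(np.isnan(lactose.values))

    def test_lone_molecule_species_at_centroid(self):
        f = frame_of([[5, 5, 5]], [am.WATER])
        water, _ = am.per_species_rmsd(am.Trajectory([f]))
        assert water.values[0] == 0.0

    def test_quadrature_recombination_identity(self, tiny_trajectory):
        """(N+M) total^2 == N water^2 + M lactose^2 per frame."""
        total = am.total_rmsd(tiny_trajectory)
        water, lactose = am.per_species_rmsd(tiny_trajectory)
        n, m = total.n_water, total.n_lactose
        lhs = (n + m) * total.values ** 2
        rhs = n * water.values ** 2 + m * lactose.values ** 2
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestUnwrapAndMsd:
    def test_unwrap_restores_a_boundary_crossing(self):
        L = 10.0
        pos = np.array([[[9.5, 5, 5]], [[0.5, 5, 5]]])  # +1 Å step across wall
        traj = am.trajectory_from_array([0.0, 1.0], pos,
                                        np.array([am.WATER], dtype=object), L)
        unwrapped = am.unwrap_trajectory(traj)
        assert unwrapped.frames[1].positions[0, 0] == pytest.approx(10.5)

    def test_msd_of_straight_line_motion(self):
        pos = np.array([[[1.0, 1, 1]], [[2.0, 1, 1]], [[3.0, 1, 1]]])
        traj = am.trajectory_from_array([0.0, 1.0, 2.0], pos,
                                        np.array([am.WATER], dtype=object),
                                        100.0)
        msd = am.msd_from_origin(traj)
        assert np.allclose(msd.values, [0, 1, 4])

    def test_msd_species_restriction_errors_when_absent(self, rng):
        pos = rng.uniform(0, 10, size=(2, 3, 3))
        traj = am.trajectory_from_array([0.0, 1.0], pos,
                                        np.array([am.WATER] * 3,
                                                 dtype=object), 10.0)
        with pytest.raises(DomainError):
            am.msd_from_origin(traj, species=am.LACTOSE)


def test_size_ratio_default_matches_printed_value():
    assert am.size_ratio() == pytest.approx(9.076923076923077)
    assert round(am.size_ratio(), 2) == 9.08
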