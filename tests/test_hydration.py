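"""g(r), solvent density profiles and region water counts."""

import numpy as np
import pytest

from solvbox import (
    CylinderRegion,
    SphereRegion,
    Trajectory,
    count_waters_in_region,
    density_profile,
    gen_ideal_gas,
    gen_layered_solute,
    radial_distribution,
    water_count_distribution,
)


class TestRadialDistribution:
    def test_ideal_gas_is_flat_at_one(self):
        # several independent uniform frames to beat down shot noise
        frames = np.concatenate(
            [gen_ideal_gas(N=2000, L=30.0, seed=s).frames for s in range(10)]
        )
        gas = Trajectory(frames=frames, box=30.0, dt=1.0, wrapped=True)
        rdf = radial_distribution(
            gas, np.arange(gas.n_atoms), np.arange(gas.n_atoms),
            r_max=gas.box / 4, dr=0.25,
        )
        window = (rdf.r >= 2.0) & (rdf.r <= gas.box / 4)
        # 3σ per bin; samples = unordered pairs landing in the bin
        rho = gas.n_atoms / gas.box**3
        pairs = rdf.n_frames * rdf.n_ref * 4 * np.pi * rdf.r**2 * rdf.dr * rho / 2
        tol = 3.0 / np.sqrt(pairs[window])
        assert np.all(np.abs(rdf.g[window] - 1.0) <= tol)

    def test_planted_shells_are_first_two_maxima(self):
        traj, _ = gen_layered_solute(
            R=1.0, shell_radii=[2.7, 4.1], shell_counts=[200, 200],
            bulk_N=500, L=50.0, seed=3,
        )
        rdf = radial_distribution(
            traj, np.array([0]), np.arange(1, traj.n_atoms), r_max=10.0, dr=0.1
        )
        peaks = rdf.first_maxima(2)
        assert abs(peaks[0] - 2.7) <= rdf.dr
        assert abs(peaks[1] - 4.1) <= rdf.dr

    def test_empty_target_is_an_error(self, ideal_gas):
        with pytest.raises(ValueError, match="target"):
            radial_distribution(ideal_gas, np.array([0]), np.array([], dtype=int),
                                r_max=5.0, dr=0.1)

    def test_r_max_beyond_half_box_rejected(self, ideal_gas):
        with pytest.raises(ValueError, match="half"):
            radial_distribution(ideal_gas, np.array([0]), np.arange(10),
                                r_max=ideal_gas.box, dr=0.1)

    def test_shell_integration_counts_neighbours(self, ideal_gas):
        # Σ g(r)·ρ·4πr²dr over (0, L/4] ≈ ideal-gas neighbour count in that range
        rdf = radial_distribution(
            ideal_gas, np.arange(ideal_gas.n_atoms), np.arange(ideal_gas.n_atoms),
            r_max=ideal_gas.box / 4, dr=0.25,
        )
        rho = ideal_gas.n_atoms / ideal_gas.box**3
        integral = np.sum(rdf.g * rho * 4 * np.pi * rdf.r**2 * rdf.dr)
        expected = rho * 4 / 3 * np.pi * (ideal_gas.box / 4) ** 3
        assert integral == pytest.approx(expected, rel=0.05)


class TestDensityProfile:
    def test_ideal_gas_pointlike_solute_flat(self):
        rng = np.random.default_rng(21)
        L, N = 40.0, 4000
        frames = rng.uniform(0, L, size=(20, N, 3))
        gas = Trajectory(frames=frames, box=L, dt=1.0, wrapped=True)
        prof = density_profile(gas, np.array([0]), np.arange(1, N),
                               dr=1.0, R=0.0)
        inner = prof.d > 4.0  # small-r bins have few samples
        assert np.all(np.abs(prof.ratio[inner] - 1.0) < 0.5)
        assert np.mean(prof.ratio[inner]) == pytest.approx(1.0, abs=0.1)

    def test_depleted_first_shell_then_bulk(self):
        # first 2 Å beyond the solute left empty: dewetted interface
        traj, _ = gen_layered_solute(
            R=3.0, shell_radii=[6.0], shell_counts=[150],
            bulk_N=3000, L=44.0, seed=8,
        )
        prof = density_profile(traj, np.array([0]), np.arange(1, traj.n_atoms),
                               dr=0.5, R=3.0)
        assert np.all(prof.ratio[prof.d < 2.0] == 0.0)
        far = prof.d > 10.0
        assert np.mean(prof.ratio[far]) == pytest.approx(1.0, abs=0.15)

    def test_single_shell_spike_integrates_to_count(self):
        traj, _ = gen_layered_solute(
            R=1.0, shell_radii=[5.0], shell_counts=[120], bulk_N=0,
            L=30.0, seed=2,
        )
        with pytest.warns(UserWarning, match="bulk"):
            prof = density_profile(traj, np.array([0]), np.arange(1, traj.n_atoms),
                                   dr=0.5, R=0.0)
        assert not prof.normalized  # no waters far out → no bulk reference
        shell_vol = 4 * np.pi * (prof.R + prof.d) ** 2 * prof.dr
        total = np.sum(prof.ratio * shell_vol)  # raw density integrates to count
        assert total == pytest.approx(120, rel=1e-6)

    def test_too_small_box_is_an_error(self):
        gas = gen_ideal_gas(N=50, L=10.0, seed=1)
        with pytest.raises(ValueError, match="too small"):
            density_profile(gas, np.array([0]), np.arange(1, 50), dr=0.5, R=4.9)


class TestRegionCounts:
    def test_planted_cylinder_population(self):
        # 150 waters planted well inside a cylinder of radius 8.5 Å
        rng = np.random.default_rng(15)
        L = 60.0
        center = np.full(3, L / 2)
        axial = rng.uniform(-9.0, 9.0, 150)
        radial = np.sqrt(rng.uniform(0, 1, 150)) * 7.0
        phi = rng.uniform(0, 2 * np.pi, 150)
        inside = center + np.column_stack(
            [radial * np.cos(phi), radial * np.sin(phi), axial]
        ) - [0, 0, 0]
        outside = rng.uniform(0, L, (300, 3))
        d_ax = np.abs(outside[:, 2] - center[2])
        d_rad = np.linalg.norm(outside[:, :2] - center[:2], axis=1)
        outside = outside[(d_ax > 12.0) | (d_rad > 10.5)]
        frame = np.vstack([inside, outside])
        region = CylinderRegion(center=tuple(center), axis=(0, 0, 1),
                                radius=8.5, half_height=10.0)
        assert count_waters_in_region(frame, region, L) == 150

    def test_empty_region_counts_zero(self):
        region = SphereRegion(center=(5.0, 5.0, 5.0), radius=1.0)
        frame = np.array([[0.0, 0.0, 0.0], [9.0, 9.0, 9.0]])
        assert count_waters_in_region(frame, region, 10.0) == 0

    def test_partition_of_box_conserves_total(self):
        gas = gen_ideal_gas(N=500, L=20.0, seed=30)
        frame = gas.frames[0]
        # partition box into two half-height cylinders of infinite radius
        top = CylinderRegion(center=(10, 10, 15), axis=(0, 0, 1),
                             radius=20.0, half_height=5.0)
        bottom = CylinderRegion(center=(10, 10, 5), axis=(0, 0, 1),
                                radius=20.0, half_height=5.0)
        n_top = count_waters_in_region(frame, top, 20.0)
        n_bottom = count_waters_in_region(frame, bottom, 20.0)
        assert n_top + n_bottom == 500

    def test_counts_invariant_under_rigid_translation(self):
        gas = gen_ideal_gas(N=300, L=20.0, seed=31)
        frame = gas.frames[0]
        region = SphereRegion(center=(10.0, 10.0, 10.0), radius=6.0)
        n0 = count_waters_in_region(frame, region, 20.0)
        shift = np.array([13.7, -4.2, 8.8])
        moved = np.mod(frame + shift, 20.0)
        region_moved = SphereRegion(
            center=tuple(np.mod(np.array(region.center) + shift, 20.0)), radius=6.0
        )
        assert count_waters_in_region(moved, region_moved, 20.0) == n0

    def test_zero_volume_region_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SphereRegion(center=(0, 0, 0), radius=0.0)
        with pytest.raises(ValueError, match="positive"):
            CylinderRegion(center=(0, 0, 0), axis=(0, 0, 1),
                           radius=1.0, half_height=0.0)


class TestWaterCountDistribution:
    def test_constant_count_is_point_mass(self):
        frames = np.tile(np.random.default_rng(0).uniform(0, 20, (1, 100, 3)),
                         (5, 1, 1))
        t = Trajectory(frames=frames, box=20.0, dt=1.0, wrapped=True)
        region = SphereRegion(center=(10, 10, 10), radius=5.0)
        dist = water_count_distribution(t, region)
        assert len(dist.values) == 1
        assert dist.probabilities[0] == 1.0
        assert dist.sd == 0.0

    def test_poissonian_counts_mean_matches_variance(self):
        # independent uniform re-draws → region count ~ Binomial ≈ Poisson
        rng = np.random.default_rng(40)
        L, N, n_frames = 30.0, 400, 300
        frames = rng.uniform(0, L, (n_frames, N, 3))
        t = Trajectory(frames=frames, box=L, dt=1.0, wrapped=True)
        region = SphereRegion(center=(15, 15, 15), radius=6.0)
        dist = water_count_distribution(t, region)
        assert dist.sd**2 == pytest.approx(dist.mean, rel=0.25)

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(41)
        frames = rng.uniform(0, 20, (30, 50, 3))
        t = Trajectory(frames=frames, box=20.0, dt=1.0, wrapped=True)
        dist = water_count_distribution(
            t, SphereRegion(center=(10, 10, 10), radius=7.0)
        )
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_needs_two_frames(self):
        t = Trajectory(frames=np.zeros((1, 5, 3)), box=10.0, dt=1.0, wrapped=True)
        with pytest.raises(ValueError, match="two frames"):
            water_count_distribution(t, SphereRegion(center=(5, 5, 5), radius=2.0))
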