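"""Voxel density maps: centering, binning oracle, projections, differences."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from membranekit import density, synthetic
from membranekit.containers import Trajectory

from conftest import uniform_cloud_trajectory


def brute_force_counts(positions, box, edge):
    """Independent per-atom binning loop (oracle for voxel_density)."""
    dims = tuple(max(int(round(b / edge)), 1) for b in box)
    counts = np.zeros(dims)
    for x, y, z in positions:
        i = int(np.floor(np.mod(x, box[0]) / edge)) % dims[0]
        j = int(np.floor(np.mod(y, box[1]) / edge)) % dims[1]
        k = int(np.floor(np.mod(z + box[2] / 2.0, box[2]) / edge)) % dims[2]
        counts[i, j, k] += 1
    return counts


class TestCenterAndWrap:
    def test_translation_in_z_removed(self, small_bilayer):
        shifted = small_bilayer.with_positions(small_bilayer.positions + [0, 0, 5.0])
        centered = density.center_and_wrap(shifted)
        head = centered.atoms["role"] == "headgroup"
        upper = head & (centered.atoms["leaflet"] == "upper")
        lower = head & (centered.atoms["leaflet"] == "lower")
        mid = 0.5 * (
            centered.positions[0][upper.to_numpy(), 2].mean()
            + centered.positions[0][lower.to_numpy(), 2].mean()
        )
        assert mid == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self, small_bilayer):
        once = density.center_and_wrap(small_bilayer)
        twice = density.center_and_wrap(once)
        np.testing.assert_allclose(twice.positions, once.positions, atol=1e-9)

    def test_lateral_wrap(self, small_bilayer):
        pos = small_bilayer.positions.copy()
        pos[0, 0, 0] = small_bilayer.boxes[0, 0] + 1.0
        wrapped = density.center_and_wrap(small_bilayer.with_positions(pos))
        assert wrapped.positions[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_missing_headgroup_errors(self, small_bilayer):
        atoms = small_bilayer.atoms.copy()
        atoms.loc[atoms["leaflet"] == "lower", "role"] = "chain"
        broken = Trajectory(
            positions=small_bilayer.positions, boxes=small_bilayer.boxes, atoms=atoms
        )
        with pytest.raises(ValueError, match="headgroup"):
            density.center_and_wrap(broken)


class TestVoxelDensity:
    def test_uniform_cloud_counting(self):
        traj = uniform_cloud_trajectory(1000, 10.0, seed=1)
        dmap = density.voxel_density(traj, voxel_edge=1.0)
        assert dmap.density.shape == (10, 10, 10)
        assert dmap.density.mean() == pytest.approx(1.0)
        assert dmap.total_atoms() == pytest.approx(1000.0)

    def test_matches_brute_force_oracle(self):
        traj = uniform_cloud_trajectory(10_000, 12.0, seed=2)
        dmap = density.voxel_density(traj, voxel_edge=1.0)
        oracle = brute_force_counts(traj.positions[0], traj.boxes[0], 1.0)
        np.testing.assert_array_equal(dmap.density, oracle)

    def test_mass_conservation(self, noisy_bilayer):
        traj = density.center_and_wrap(noisy_bilayer)
        dmap = density.voxel_density(traj)
        rel_err = abs(dmap.total_atoms() - traj.n_atoms) / traj.n_atoms
        assert rel_err < 1e-6

    def test_duplicated_frames_identical_map(self, small_bilayer):
        traj = density.center_and_wrap(small_bilayer)
        doubled = Trajectory(
            positions=np.concatenate([traj.positions, traj.positions]),
            boxes=np.concatenate([traj.boxes, traj.boxes]),
            atoms=traj.atoms,
        )
        np.testing.assert_array_equal(
            density.voxel_density(traj).density,
            density.voxel_density(doubled).density,
        )

    def test_zero_frames_rejected(self, small_bilayer):
        with pytest.raises(ValueError):
            Trajectory(
                positions=small_bilayer.positions[:0],
                boxes=small_bilayer.boxes[:0],
                atoms=small_bilayer.atoms,
            )

    def test_bad_voxel_edge(self, small_bilayer):
        with pytest.raises(ValueError):
            density.voxel_density(small_bilayer, voxel_edge=0.0)

    def test_include_flag_respected(self, small_bilayer):
        traj = density.center_and_wrap(small_bilayer)
        atoms = traj.atoms.copy()
        atoms["include_in_density"] = atoms["role"] == "chain"
        masked = Trajectory(positions=traj.positions, boxes=traj.boxes, atoms=atoms)
        dmap = density.voxel_density(masked)
        assert dmap.total_atoms() == pytest.approx((atoms["role"] == "chain").sum())


class TestProjectionsAndProfile:
    def test_projection_conserves_mean(self, noisy_bilayer):
        dmap = density.voxel_density(density.center_and_wrap(noisy_bilayer))
        map2d, _, _ = density.project_depth_lateral(dmap)
        assert map2d.mean() == pytest.approx(dmap.density.mean())

    def test_uniform_box_flat_profile(self):
        traj = uniform_cloud_trajectory(200_000, 10.0, seed=3)
        dmap = density.voxel_density(traj)
        _, profile = density.depth_profile(dmap)
        assert profile.std() / profile.mean() < 0.05

    def test_headgroup_band_maximum_center_minimum(self, small_bilayer):
        traj = density.center_and_wrap(small_bilayer)
        dmap = density.voxel_density(traj)
        z, profile = density.depth_profile(dmap, symmetrize=True)
        spec = synthetic.BilayerGenSpec(lipids_per_leaflet=16)
        assert abs(z[np.argmax(profile)] - spec.headgroup_z) < 1.5
        assert profile[z < 1.0].min() <= profile.min() + 1e-12

    def test_symmetrized_equals_raw_for_mirror_symmetric_map(self, small_bilayer):
        dmap = density.voxel_density(density.center_and_wrap(small_bilayer))
        z_raw, raw = density.depth_profile(dmap)
        z_sym, sym = density.depth_profile(dmap, symmetrize=True)
        upper = raw[z_raw > 0]
        np.testing.assert_allclose(sym, upper, atol=1e-12)


class TestDifferenceMap:
    def test_self_difference_is_zero(self, noisy_bilayer):
        dmap = density.voxel_density(density.center_and_wrap(noisy_bilayer))
        diff = density.difference_map(dmap, dmap)
        assert np.all(diff.density == 0.0)

    def test_antisymmetry(self, small_bilayer, noisy_bilayer):
        a = density.voxel_density(density.center_and_wrap(small_bilayer))
        b = density.voxel_density(density.center_and_wrap(noisy_bilayer))
        ab = density.difference_map(a, b)
        ba = density.difference_map(b, a)
        np.testing.assert_allclose(ab.density, -ba.density, atol=1e-15)

    def test_voxel_edge_mismatch_rejected(self, small_bilayer):
        traj = density.center_and_wrap(small_bilayer)
        a = density.voxel_density(traj, voxel_edge=1.0)
        b = density.voxel_density(traj, voxel_edge=2.0)
        with pytest.raises(ValueError, match="voxel edges"):
            density.difference_map(a, b)

    def test_saturated_minus_kinked_band_positive(self):
        maps = {}
        for f in (0.0, 1.0):
            spec = synthetic.BilayerGenSpec(
                lipids_per_leaflet=25, fraction_kinked_chains=f,
                thermal_noise_sd=0.3, seed=9,
            )
            traj = density.center_and_wrap(synthetic.generate_bilayer(spec, 2))
            maps[f] = density.voxel_density(traj)
        diff = density.difference_map(maps[0.0], maps[1.0])
        assert density.band_statistic(diff).mean > 0


class TestBandStatistic:
    def test_uniform_density(self):
        traj = uniform_cloud_trajectory(50_000, 20.0, seed=4)
        dmap = density.voxel_density(traj)
        stat = density.band_statistic(dmap, 3.0, 10.0)
        assert stat.mean == pytest.approx(50_000 / 20.0**3, rel=0.05)

    def test_zero_difference_map(self, small_bilayer):
        dmap = density.voxel_density(density.center_and_wrap(small_bilayer))
        diff = density.difference_map(dmap, dmap)
        stat = density.band_statistic(diff)
        assert stat.mean == 0.0 and stat.sd == 0.0

    def test_band_outside_grid_rejected(self):
        traj = uniform_cloud_trajectory(100, 8.0, seed=5)
        dmap = density.voxel_density(traj)
        with pytest.raises(ValueError, match="outside the grid"):
            density.band_statistic(dmap, 3.0, 50.0)

    def test_band_mean_monotone_in_saturation(self):
        """Band density rises monotonically as chains straighten (cis→trans)."""
        means = []
        for f in (1.0, 0.75, 0.5, 0.25, 0.0):
            spec = synthetic.BilayerGenSpec(
                lipids_per_leaflet=25, fraction_kinked_chains=f,
                thermal_noise_sd=0.3, seed=21,
            )
            traj = density.center_and_wrap(synthetic.generate_bilayer(spec, 2))
            means.append(density.band_statistic(density.voxel_density(traj)).mean)
        assert all(a < b for a, b in zip(means, means[1:]))

    @given(st.floats(min_value=0.1, max_value=5.0))
    def test_uniform_band_sd_zero(self, rho):
        n = 12
        dmap = density.DensityMap(
            density=np.full((n, n, n), rho),
            origin=np.array([0.0, 0.0, -n / 2.0]),
            voxel_edge=1.0,
            n_frames=1,
        )
        stat = density.band_statistic(dmap, 1.0, 5.0)
        assert stat.mean == pytest.approx(rho)
        assert stat.sd == pytest.approx(0.0, abs=1e-12)
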