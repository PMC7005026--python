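"""Dimer rotational-state analysis: axes, azimuths, classification, populations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from membranekit import rotamer, synthetic
from membranekit.containers import DimerTrajectory


def make_dimer(phi1_deg: float, phi2_deg: float, separation: float = 10.0):
    """Single-frame dimer with exactly prescribed sensor azimuths.

    Helices are straight rods along z with an off-axis sensor bead at the
    rod midpoint (z = 0), so the bead perturbs neither the principal axis
    direction nor the in-plane centroid-to-bead direction and the azimuth
    construction is exact.
    """
    n = 9
    z = np.linspace(-6.0, 6.0, n)
    a = np.zeros((n, 3))
    a[:, 2] = z
    b = a.copy()
    b[:, 0] = separation
    sensor = 4
    r = 2.0
    phi1, phi2 = np.radians(phi1_deg), np.radians(phi2_deg)

    def displace(rod, dx, dy):
        # keep the centroid on the rod axis so the connector stays along x
        rod[sensor, 0] += dx
        rod[sensor, 1] += dy
        others = np.arange(n) != sensor
        rod[others, 0] -= dx / (n - 1)
        rod[others, 1] -= dy / (n - 1)

    # protomer A: partner toward +x, in-plane basis (x, y)
    displace(a, r * np.cos(phi1), r * np.sin(phi1))
    # protomer B: partner toward -x, in-plane basis (-x, -y)
    displace(b, -r * np.cos(phi2), -r * np.sin(phi2))
    return DimerTrajectory(positions_a=a[None], positions_b=b[None], sensor_index=sensor)


class TestHelixAxis:
    def test_line_along_z(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        axis, centroid = rotamer.helix_axis(pts)
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(centroid, [0, 0, 2.5])

    def test_ideal_helix_axis_near_z(self):
        spec = synthetic.DimerGenSpec(n_frames=1, angular_sd=0.0)
        traj = synthetic.generate_dimer(spec)
        axis, _ = rotamer.helix_axis(traj.positions_a[0])
        angle = np.degrees(np.arccos(abs(axis[2])))
        assert angle < 1.0

    def test_orientation_follows_n_to_c(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), -np.arange(6.0)])
        axis, _ = rotamer.helix_axis(pts)
        np.testing.assert_allclose(axis, [0, 0, -1], atol=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(10, 3)), axis=0) + [0, 0, 20]
        axis, _ = rotamer.helix_axis(pts)
        theta = np.radians(40.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        axis_rot, _ = rotamer.helix_axis(pts @ rot.T)
        np.testing.assert_allclose(axis_rot, rot @ axis, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            rotamer.helix_axis(np.zeros((3, 3)))


class TestSensorAzimuth:
    @pytest.mark.parametrize("phi", [0.0, 180.0, 90.0, -90.0, 45.0])
    def test_prescribed_azimuth_recovered(self, phi):
        traj = make_dimer(phi, 0.0)
        assert rotamer.sensor_azimuth(traj, 0, 0) == pytest.approx(phi, abs=1e-6)

    @pytest.mark.parametrize("phi", [0.0, 180.0, 90.0])
    def test_partner_protomer_convention(self, phi):
        traj = make_dimer(0.0, phi)
        assert rotamer.sensor_azimuth(traj, 0, 1) == pytest.approx(phi, abs=1e-6)

    def test_rigid_motion_invariance(self):
        traj = make_dimer(35.0, -120.0)
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([3.0, -7.0, 11.0])
        moved = DimerTrajectory(
            positions_a=(traj.positions_a @ q.T) + shift,
            positions_b=(traj.positions_b @ q.T) + shift,
            sensor_index=traj.sensor_index,
        )
        for protomer in (0, 1):
            assert rotamer.sensor_azimuth(moved, 0, protomer) == pytest.approx(
                rotamer.sensor_azimuth(traj, 0, protomer), abs=1e-6
            )

    def test_coincident_axes_error(self):
        # phi pair chosen so both sensor beads shift the centroids identically
        traj = make_dimer(0.0, 180.0, separation=0.0)
        with pytest.raises(ValueError, match="coincident"):
            rotamer.sensor_azimuth(traj, 0, 0)


class TestClassifyState:
    @pytest.mark.parametrize(
        "phi1, phi2, expected",
        [
            (0.0, 0.0, "facing-facing"),
            (180.0, 180.0, "away-away"),
            (0.0, 180.0, "mixed"),
            (59.0, -59.0, "facing-facing"),
            (121.0, -121.0, "away-away"),
            (59.0, 121.0, "mixed"),
        ],
    )
    def test_partition(self, phi1, phi2, expected):
        assert rotamer.classify_state(phi1, phi2) == expected

    @given(
        st.floats(min_value=-180.0, max_value=180.0),
        st.floats(min_value=-180.0, max_value=180.0),
    )
    def test_labels_exhaustive_and_exclusive(self, phi1, phi2):
        assert rotamer.classify_state(phi1, phi2) in rotamer.STATE_LABELS


class TestStatePopulations:
    def test_pure_state_zero_width_ci(self):
        labels = np.array(["facing-facing"] * 100)
        pops = rotamer.state_populations(labels, n_boot=100, seed=0)
        assert pops["facing-facing"]["fraction"] == 1.0
        assert pops["facing-facing"]["ci"] == (1.0, 1.0)
        assert pops["away-away"]["fraction"] == 0.0

    def test_fractions_sum_to_one(self):
        spec = synthetic.DimerGenSpec(
            state_weights=(0.4, 0.35, 0.25), n_frames=500, seed=3
        )
        series = rotamer.analyze_dimer(synthetic.generate_dimer(spec), n_boot=50)
        total = sum(v["fraction"] for v in series.populations.values())
        assert total == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(rotamer.STATE_LABELS, size=300)
        a = rotamer.state_populations(labels, n_boot=10, seed=0)
        b = rotamer.state_populations(rng.permutation(labels), n_boot=10, seed=0)
        for s in rotamer.STATE_LABELS:
            assert a[s]["fraction"] == b[s]["fraction"]

    def test_invalid_boot_count(self):
        with pytest.raises(ValueError):
            rotamer.state_populations(np.array(["mixed"]), n_boot=0)

    def test_recovery_across_seeds(self):
        """Mixtures are recovered within binomial error across many seeds."""
        weights = np.array([0.5, 0.3, 0.2])
        n = 2000
        failures = 0
        for seed in range(20):
            spec = synthetic.DimerGenSpec(
                state_weights=tuple(weights), angular_sd=10.0, n_frames=n, seed=seed
            )
            series = rotamer.analyze_dimer(
                synthetic.generate_dimer(spec), n_boot=10, seed=seed
            )
            for w, s in zip(weights, rotamer.STATE_LABELS):
                se = np.sqrt(w * (1 - w) / n)
                if abs(series.populations[s]["fraction"] - w) > 3 * se:
                    failures += 1
        assert failures <= 1


class TestCrossingFlag:
    def test_steeply_crossed_axes_flagged(self):
        n = 9
        z = np.linspace(-6.0, 6.0, n)
        a = np.zeros((n, 3))
        a[:, 2] = z
        b = np.zeros((n, 3))
        b[:, 0] = 10.0 + z  # tilted 90° relative to A
        b[:, 2] = np.linspace(-0.5, 0.5, n)
        traj = DimerTrajectory(positions_a=a[None], positions_b=b[None], sensor_index=4)
        with pytest.raises(ValueError, match="flagged"):
            rotamer.analyze_dimer(traj, n_boot=10)
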