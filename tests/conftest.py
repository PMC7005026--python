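import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from membranekit import synthetic
from membranekit.containers import Trajectory

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bilayer() -> Trajectory:
    """A small noise-free straight-chain bilayer (deterministic geometry)."""
    spec = synthetic.BilayerGenSpec(
        lipids_per_leaflet=16, fraction_kinked_chains=0.0, thermal_noise_sd=0.0, seed=0
    )
    return synthetic.generate_bilayer(spec, n_frames=1)


@pytest.fixture(scope="session")
def noisy_bilayer() -> Trajectory:
    spec = synthetic.BilayerGenSpec(
        lipids_per_leaflet=16, fraction_kinked_chains=0.5, thermal_noise_sd=0.4, seed=3
    )
    return synthetic.generate_bilayer(spec, n_frames=3)


def uniform_cloud_trajectory(n_points: int, box_edge: float, seed: int) -> Trajectory:
    """Unlabeled-role uniform atom cloud in a cubic box (counting fixture)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(n_points, 3))
    pos[:, 2] -= box_edge / 2.0  # centered z convention
    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(n_points),
            "lipid_id": np.zeros(n_points, dtype=int),
            "leaflet": ["upper"] * n_points,
            "role": ["chain"] * n_points,
            "chain": np.zeros(n_points, dtype=int),
            "segment": np.arange(n_points),
            "include_in_density": True,
        }
    )
    return Trajectory(
        positions=pos[None, :, :],
        boxes=np.array([[box_edge] * 3]),
        atoms=atoms,
    )
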