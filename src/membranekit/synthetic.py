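"""Synthetic input generators with known ground truth.

Every downstream stage of the package (density maps, bilayer descriptors,
rotamer populations, spectroscopy reductions) can be exercised against data
whose generating parameters are known exactly.  The bilayer generator is a
deliberately minimal geometric model — jointed segment sticks, no physics —
built so that the qualitative depth-density signatures of chain saturation
and headgroup size are reproduced:

* a *straight* (saturated / trans-analog) acyl chain descends from the
  glycerol region to ~1 Å above the midplane, filling the 3–10 Å band where
  the sensory tryptophan of the lipid-saturation sensor sits;
* a *kinked* (cis-analog) chain bends by ``kink_angle`` at ``kink_position``
  and, for large angles, the distal segments run nearly flat and terminate
  above that band, depleting it;
* a PE-analog headgroup is emulated by fewer headgroup atoms and a slightly
  reduced area per lipid, which raises density mildly and uniformly along
  the whole chain region instead of sharply in the band.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CorrelationCurve,
    DimerTrajectory,
    EmissionSpectrum,
    EPRSpectrum,
    Trajectory,
)
from .spectroscopy import fcs_model

__all__ = [
    "SEGMENT_RISE",
    "BilayerGenSpec",
    "DimerGenSpec",
    "generate_bilayer",
    "generate_dimer",
    "generate_emission_spectrum",
    "generate_fcs_curve",
    "generate_epr_spectrum",
    "composition_preset",
    "COMPOSITION_PRESETS",
]

#: vertical rise per chain segment, Å (all-trans C–C projection analog)
SEGMENT_RISE = 1.27

#: z of the terminal segment of a straight chain, Å above the midplane
_CHAIN_END_Z = 1.0


@dataclass
class BilayerGenSpec:
    """Parameters of the toy bilayer generator.

    ``kink_angle`` is the tilt (degrees, from the bilayer normal) of the
    chain below the kink: large for a cis analog, small for a trans analog.
    ``kink_position`` is the segment index at which the bend occurs
    (a Δ6 analog kinks earlier/higher than a Δ9 analog).
    """

    lipids_per_leaflet: int = 64
    area_per_lipid: float = 64.0  # Å²
    chain_segments: int = 12
    chains_per_lipid: int = 2
    fraction_kinked_chains: float = 0.0
    kink_position: int = 4
    kink_angle: float = 80.0  # degrees
    headgroup_atom_count: int = 8
    thermal_noise_sd: float = 0.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise ValueError("lipids_per_leaflet must be >= 1")
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be positive")
        if self.chain_segments < 2:
            raise ValueError("chains need at least 2 segments")
        if self.chains_per_lipid < 1:
            raise ValueError("chains_per_lipid must be >= 1")
        if not 0.0 <= self.fraction_kinked_chains <= 1.0:
            raise ValueError("fraction_kinked_chains must lie in [0, 1]")
        if not 0 < self.kink_position < self.chain_segments:
            raise ValueError("kink_position must be an interior segment index")
        if not 0.0 <= self.kink_angle < 90.0:
            raise ValueError("kink_angle must lie in [0, 90) degrees")
        if self.headgroup_atom_count < 1:
            raise ValueError("headgroup_atom_count must be >= 1")
        if self.thermal_noise_sd < 0:
            raise ValueError("thermal_noise_sd must be nonnegative")

    # derived geometry -----------------------------------------------------
    @property
    def chain_top_z(self) -> float:
        """z of the first (glycerol-proximal) chain segment, Å."""
        return _CHAIN_END_Z + (self.chain_segments - 1) * SEGMENT_RISE

    @property
    def glycerol_z(self) -> float:
        return self.chain_top_z + 1.2

    @property
    def headgroup_z(self) -> float:
        """Mean z of the headgroup atom ring (thickness reference plane)."""
        return self.glycerol_z + 1.8

    @property
    def lateral_edge(self) -> float:
        """Edge length of the square lateral box, Å."""
        return math.sqrt(self.lipids_per_leaflet * self.area_per_lipid)

    @property
    def box_z(self) -> float:
        return 2.0 * math.ceil(self.headgroup_z + 3.0)


def _upper_leaflet_template(spec: BilayerGenSpec, rng: np.random.Generator):
    """Noise-free atom positions and labels of one leaflet (z > 0).

    Returns (positions, records); records are per-atom (role, chain, segment).
    Kink azimuths and the kinked-chain assignment are drawn once from ``rng``
    so they are shared by every frame and mirrored into the lower leaflet.
    """
    n = spec.lipids_per_leaflet
    ncols = math.ceil(math.sqrt(n))
    spacing = spec.lateral_edge / ncols

    n_chains = n * spec.chains_per_lipid
    n_kinked = int(round(spec.fraction_kinked_chains * n_chains))
    kinked = np.zeros(n_chains, dtype=bool)
    kinked[rng.permutation(n_chains)[:n_kinked]] = True
    kink_azimuth = rng.uniform(0.0, 2.0 * math.pi, size=n_chains)

    theta = math.radians(spec.kink_angle)
    positions: list[tuple[float, float, float]] = []
    records: list[tuple[int, str, int, int]] = []  # lipid, role, chain, segment

    for lip in range(n):
        cx = (lip % ncols + 0.5) * spacing
        cy = (lip // ncols + 0.5) * spacing
        # headgroup: ring of atoms, alternating small z offsets
        for k in range(spec.headgroup_atom_count):
            ang = 2.0 * math.pi * k / spec.headgroup_atom_count
            dz = 0.3 if k % 2 == 0 else -0.3
            if spec.headgroup_atom_count == 1:
                dz = 0.0
            positions.append(
                (cx + 1.2 * math.cos(ang), cy + 1.2 * math.sin(ang), spec.headgroup_z + dz)
            )
            records.append((lip, "headgroup", -1, -1))
        # glycerol: two atoms bridging head and chains
        for dx in (-0.5, 0.5):
            positions.append((cx + dx, cy, spec.glycerol_z))
            records.append((lip, "glycerol", -1, -1))
        # acyl chains
        for c in range(spec.chains_per_lipid):
            gidx = lip * spec.chains_per_lipid + c
            off = (c - (spec.chains_per_lipid - 1) / 2.0) * 1.8
            x, y, z = cx + off, cy, spec.chain_top_z
            psi = kink_azimuth[gidx]
            for s in range(spec.chain_segments):
                if s > 0:
                    if kinked[gidx] and s >= spec.kink_position:
                        x += SEGMENT_RISE * math.sin(theta) * math.cos(psi)
                        y += SEGMENT_RISE * math.sin(theta) * math.sin(psi)
                        z -= SEGMENT_RISE * math.cos(theta)
                    else:
                        z -= SEGMENT_RISE
                positions.append((x, y, z))
                records.append((lip, "chain", c, s))

    return np.asarray(positions, dtype=float), records


def generate_bilayer(spec: BilayerGenSpec, n_frames: int = 1) -> Trajectory:
    """Generate a two-leaflet bilayer trajectory from a :class:`BilayerGenSpec`.

    The lower leaflet mirrors the upper about z = 0 (exactly so in the
    noise-free limit); thermal noise is iid Gaussian per atom per frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    upper, records = _upper_leaflet_template(spec, rng)

    lower = upper.copy()
    lower[:, 2] *= -1.0

    base = np.vstack([upper, lower])
    n_per_leaflet = len(upper)
    n_atoms = len(base)

    rows = []
    for leaflet_idx, leaflet in enumerate(("upper", "lower")):
        for i, (lip, role, chain, seg) in enumerate(records):
            rows.append(
                {
                    "atom_id": leaflet_idx * n_per_leaflet + i,
                    "lipid_id": leaflet_idx * spec.lipids_per_leaflet + lip,
                    "leaflet": leaflet,
                    "role": role,
                    "chain": chain,
                    "segment": seg,
                    "include_in_density": True,
                }
            )
    atoms = pd.DataFrame(
        rows,
        columns=["atom_id", "lipid_id", "leaflet", "role", "chain", "segment",
                 "include_in_density"],
    )

    edge = spec.lateral_edge
    box = np.array([edge, edge, spec.box_z])
    positions = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        frame = base.copy()
        if spec.thermal_noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.thermal_noise_sd, size=frame.shape)
        positions[f] = frame
    boxes = np.tile(box, (n_frames, 1))
    return Trajectory(positions=positions, boxes=boxes, atoms=atoms)


#: generator specs loosely emulating the four studied bilayer compositions:
#: fully cis-unsaturated PC, a 50:50 cis/saturated-chain PC mix, the
#: half-saturated PC, and a 40 mol% PE-analog sharing the mixed acyl chains.
COMPOSITION_PRESETS: dict[str, dict] = {
    "cis_pc": {"fraction_kinked_chains": 1.0},
    "mixed_pc": {"fraction_kinked_chains": 0.75},
    "halfsat_pc": {"fraction_kinked_chains": 0.5},
    "trans_pc": {"fraction_kinked_chains": 1.0, "kink_angle": 15.0},
    "pe40": {
        "fraction_kinked_chains": 0.75,
        "headgroup_atom_count": 7,
        "area_per_lipid": 62.0,
    },
}


def composition_preset(name: str, **overrides) -> BilayerGenSpec:
    """A :class:`BilayerGenSpec` for one of the named composition analogs."""
    if name not in COMPOSITION_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(COMPOSITION_PRESETS)}"
        )
    params = dict(COMPOSITION_PRESETS[name])
    params.update(overrides)
    return BilayerGenSpec(**params)


# ---------------------------------------------------------------------------
# TMH dimer generator
# ---------------------------------------------------------------------------

_DEFAULT_STATE_CENTERS = ((0.0, 0.0), (0.0, 180.0), (180.0, 180.0))


@dataclass
class DimerGenSpec:
    """Parameters of the two-helix rotamer-mixture generator.

    ``state_center_angles`` holds one (phi1, phi2) azimuth pair per state;
    the defaults realize the facing-facing, mixed, and away-away
    configurations of the sensor residue.
    """

    state_weights: Sequence[float] = (1.0, 0.0, 0.0)
    state_center_angles: Sequence[Sequence[float]] = _DEFAULT_STATE_CENTERS
    angular_sd: float = 15.0  # degrees
    n_frames: int = 1000
    helix_separation: float = 10.0  # Å
    sensor_residue_index: int = 12
    n_residues: int = 26
    helix_radius: float = 2.3  # Å (C-alpha radius of an ideal alpha helix)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.state_weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.state_center_angles):
            raise ValueError("need one weight per state")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("state_weights must be nonnegative and sum to 1")
        for pair in self.state_center_angles:
            if len(pair) != 2:
                raise ValueError("each state center must be a (phi1, phi2) pair")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.angular_sd < 0:
            raise ValueError("angular_sd must be nonnegative")
        if self.helix_separation <= 2 * self.helix_radius:
            raise ValueError("helices overlap: increase helix_separation")
        if not 0 <= self.sensor_residue_index < self.n_residues:
            raise ValueError("sensor_residue_index out of range")


def _ideal_helix(n_residues: int, radius: float, phase_deg: float) -> np.ndarray:
    """C-alpha trace of an ideal alpha helix along +z (100°/residue, 1.5 Å rise)."""
    i = np.arange(n_residues)
    ang = np.radians(100.0 * i + phase_deg)
    z = 1.5 * i
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])
    pts[:, 2] -= pts[:, 2].mean()
    return pts


def generate_dimer(spec: DimerGenSpec) -> DimerTrajectory:
    """Sample a dimer trajectory with a prescribed rotational-state mixture.

    Per frame a state is drawn from ``state_weights``; each protomer's
    sensor azimuth is then drawn from a wrapped normal around that state's
    center and the whole helix is rotated about its own axis to realize it.
    Azimuths are measured toward the partner helix (0° = facing).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    w = np.asarray(spec.state_weights, dtype=float)
    states = rng.choice(len(w), size=n, p=w)
    centers = np.asarray(spec.state_center_angles, dtype=float)
    phi1 = centers[states, 0] + rng.normal(0.0, spec.angular_sd, size=n)
    phi2 = centers[states, 1] + rng.normal(0.0, spec.angular_sd, size=n)

    # base sensor azimuth of the template helix (relative to lab +x)
    theta_s = 100.0 * spec.sensor_residue_index

    helix = _ideal_helix(spec.n_residues, spec.helix_radius, 0.0)
    d = spec.helix_separation

    def rotz(deg: float) -> np.ndarray:
        a = math.radians(deg)
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    pos_a = np.empty((n, spec.n_residues, 3))
    pos_b = np.empty((n, spec.n_residues, 3))
    for f in range(n):
        # protomer A at the origin, partner toward +x: lab sensor angle = phi1
        pos_a[f] = helix @ rotz(phi1[f] - theta_s).T
        # protomer B at (d, 0, 0), partner toward -x: lab angle = phi2 + 180
        pos_b[f] = helix @ rotz(phi2[f] + 180.0 - theta_s).T
        pos_b[f, :, 0] += d

    return DimerTrajectory(
        positions_a=pos_a, positions_b=pos_b, sensor_index=spec.sensor_residue_index
    )


# ---------------------------------------------------------------------------
# spectroscopy fixtures
# ---------------------------------------------------------------------------

def generate_emission_spectrum(
    bands: Sequence[tuple[float, float, float]],
    grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    excitation: Optional[float] = None,
) -> EmissionSpectrum:
    """Sum of Gaussian emission bands plus optional noise, clipped at zero.

    ``bands`` holds (center nm, width nm, amplitude) triples; the default
    grid covers 400–600 nm at 0.5 nm, matching a typical recorded window.
    """
    if len(bands) == 0:
        raise ValueError("need at least one emission band")
    if grid is None:
        grid = np.arange(400.0, 600.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    intensity = np.zeros_like(grid)
    for center, width, amplitude in bands:
        if width <= 0:
            raise ValueError("band width must be positive")
        intensity += amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.shape)
    intensity = np.clip(intensity, 0.0, None)
    return EmissionSpectrum(
        wavelength=grid, intensity=intensity, excitation=excitation,
        blank_subtracted=True,
    )


def generate_fcs_curve(
    n_particles: float,
    tau_d_s: float,
    triplet_fraction: float = 0.0,
    tau_t_s: float = 5e-6,
    lag_grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CorrelationCurve:
    """Synthetic 2D-diffusion + triplet autocorrelation curve.

    G(tau) = (1 + T/(1-T) e^(-tau/tau_T)) (1/N) (1 + tau/tau_D)^-1, with
    multiplicative Gaussian noise of relative magnitude ``noise_sd``.
    """
    if n_particles <= 0 or tau_d_s <= 0 or tau_t_s <= 0:
        raise ValueError("N, tau_D and tau_T must be positive")
    if not 0.0 <= triplet_fraction < 1.0:
        raise ValueError("triplet fraction must lie in [0, 1)")
    if lag_grid is None:
        lag_grid = np.logspace(-6.5, 0.0, 140)
    lag_grid = np.asarray(lag_grid, dtype=float)
    g = fcs_model(lag_grid, n_particles, tau_d_s, triplet_fraction, tau_t_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=g.shape))
    return CorrelationCurve(lag=lag_grid, g=g)


# ---------------------------------------------------------------------------
# cwEPR fixtures
# ---------------------------------------------------------------------------

#: nitroxide triplet line centers, mT (frozen-solution A_zz-like splitting)
_EPR_CENTERS = (331.6, 335.0, 338.4)
#: relative broadening susceptibility of the low/mid/high-field lines; the
#: outer lines broaden faster, so the low/mid amplitude ratio falls with
#: increasing broadening by construction.
_EPR_KAPPA = (1.0, 0.3, 1.0)
_EPR_BASE_WIDTH = 0.35  # mT


def generate_epr_spectrum(
    broadening: float = 0.0,
    amplitudes: Sequence[float] = (0.5, 1.0, 0.3),
    field_grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    centers: Sequence[float] = _EPR_CENTERS,
) -> EPRSpectrum:
    """Three-line first-derivative spectrum with tunable broadening.

    ``amplitudes`` are the positive-lobe heights of the three lines at zero
    broadening; increasing ``broadening`` widens and flattens the outer
    lines more strongly than the central one.
    """
    if broadening < 0:
        raise ValueError("broadening must be nonnegative")
    if len(amplitudes) != 3 or any(a < 0 for a in amplitudes):
        raise ValueError("need three nonnegative line amplitudes")
    centers = tuple(float(c) for c in centers)
    if not (centers[0] < centers[1] < centers[2]):
        raise ValueError("line centers must be ordered low-field to high-field")
    if field_grid is None:
        field_grid = np.linspace(centers[0] - 4.0, centers[2] + 4.0, 1400)
    field_grid = np.asarray(field_grid, dtype=float)
    if not np.all(np.diff(field_grid) > 0):
        raise ValueError("field grid must be strictly increasing")

    amp = np.zeros_like(field_grid)
    lobe = math.exp(-0.5)  # positive-lobe max of the unit derivative shape
    for h, b0, kappa in zip(amplitudes, centers, _EPR_KAPPA):
        w = _EPR_BASE_WIDTH * (1.0 + kappa * broadening)
        shape = ((b0 - field_grid) / w) * np.exp(-0.5 * ((field_grid - b0) / w) ** 2)
        amp += (h / (lobe * (1.0 + kappa * broadening) ** 2)) * shape
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amp = amp + rng.normal(0.0, noise_sd, size=amp.shape)
    return EPRSpectrum(field=field_grid, amplitude=amp)
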