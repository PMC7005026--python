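"""Core in-memory containers shared across the package.

Coordinates are Ångström throughout; the bilayer normal is the z axis and,
after centering, the bilayer midplane sits at z = 0.  Atom metadata lives in
a pandas table so selections compose naturally with the rest of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ATOM_TABLE_COLUMNS",
    "BilayerFrame",
    "Trajectory",
    "DensityMap",
    "DifferenceMap",
    "DimerTrajectory",
    "EmissionSpectrum",
    "CorrelationCurve",
    "EPRSpectrum",
    "LiposomeSpec",
    "LipidSpecies",
]

#: required columns of the per-atom topology table
ATOM_TABLE_COLUMNS = (
    "atom_id",
    "lipid_id",
    "leaflet",
    "role",
    "chain",
    "segment",
    "include_in_density",
)

_LEAFLETS = {"upper", "lower"}
_ROLES = {"headgroup", "glycerol", "chain"}


def _validate_atom_table(atoms: pd.DataFrame) -> None:
    missing = [c for c in ATOM_TABLE_COLUMNS if c not in atoms.columns]
    if missing:
        raise ValueError(f"atom table is missing columns: {missing}")
    bad_leaflet = set(atoms["leaflet"].unique()) - _LEAFLETS
    if bad_leaflet:
        raise ValueError(f"unknown leaflet labels: {sorted(bad_leaflet)}")
    bad_role = set(atoms["role"].unique()) - _ROLES
    if bad_role:
        raise ValueError(f"unknown role labels: {sorted(bad_role)}")
    if atoms["lipid_id"].isna().any():
        raise ValueError("every atom must be assigned to a lipid")


@dataclass
class BilayerFrame:
    """One bilayer configuration: positions, an orthorhombic box, atom labels.

    ``positions`` is (n_atoms, 3) in Å.  ``box`` holds the three edge lengths;
    laterally the frame is periodic in [0, Lx) x [0, Ly), and the z interval
    is taken as [-Lz/2, Lz/2) once the frame has been centered.
    """

    positions: np.ndarray
    box: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")
        _validate_atom_table(self.atoms)
        if len(self.atoms) != len(self.positions):
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but positions has "
                f"{len(self.positions)} atoms"
            )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """A stack of bilayer frames sharing one atom table.

    ``positions``: (n_frames, n_atoms, 3) Å; ``boxes``: (n_frames, 3) Å.
    """

    positions: np.ndarray
    boxes: np.ndarray
    atoms: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        if self.positions.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.boxes.shape != (self.positions.shape[0], 3):
            raise ValueError("boxes must be (n_frames, 3)")
        if not np.all(self.boxes > 0):
            raise ValueError("box edges must be positive")
        _validate_atom_table(self.atoms)
        if len(self.atoms) != self.positions.shape[1]:
            raise ValueError("atom table does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> BilayerFrame:
        return BilayerFrame(self.positions[i], self.boxes[i], self.atoms)

    def with_positions(self, positions: np.ndarray) -> "Trajectory":
        return replace(self, positions=positions)


@dataclass
class DensityMap:
    """Frame-averaged lipid-atom number density on a regular voxel grid.

    ``density`` is a 3D array (nx, ny, nz) in atoms/Å³; the grid is anchored
    at ``origin`` with cubic voxels of ``voxel_edge`` Å, half-open [k, k+1).
    """

    density: np.ndarray
    origin: np.ndarray
    voxel_edge: float
    n_frames: int
    label: str = ""

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be a 3D array")
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_edge**3)

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.density.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_edge

    @property
    def z_centers(self) -> np.ndarray:
        return self.axis_centers(2)

    def total_atoms(self) -> float:
        """Integral of the density: the mean atom count per frame."""
        return float(self.density.sum() * self.voxel_volume)


@dataclass
class DifferenceMap(DensityMap):
    """Signed voxel-wise difference of two density maps (minuend - subtrahend)."""

    label_minuend: str = ""
    label_subtrahend: str = ""


@dataclass
class DimerTrajectory:
    """Backbone traces of a two-helix dimer with a designated sensor residue."""

    positions_a: np.ndarray  # (n_frames, n_residues, 3) Å
    positions_b: np.ndarray
    sensor_index: int
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions_a = np.asarray(self.positions_a, dtype=float)
        self.positions_b = np.asarray(self.positions_b, dtype=float)
        for p in (self.positions_a, self.positions_b):
            if p.ndim != 3 or p.shape[2] != 3:
                raise ValueError("positions must be (n_frames, n_residues, 3)")
        if self.positions_a.shape != self.positions_b.shape:
            raise ValueError("both protomers must have the same shape")
        if self.positions_a.shape[0] < 1:
            raise ValueError("dimer trajectory needs at least one frame")
        n_res = self.positions_a.shape[1]
        if not 0 <= self.sensor_index < n_res:
            raise ValueError(f"sensor index {self.sensor_index} out of range for {n_res} residues")
        if self.times is None:
            self.times = np.arange(self.positions_a.shape[0], dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions_a.shape[0]

    @property
    def n_residues(self) -> int:
        return self.positions_a.shape[1]


def _check_xy(x: np.ndarray, y: np.ndarray, xname: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"{xname} and values must be 1D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if not np.all(np.diff(x) > 0):
        raise ValueError(f"{xname} must be strictly increasing")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    return x, y


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum: wavelength (nm) vs intensity (a.u.)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation: Optional[float] = None
    blank_subtracted: bool = False

    def __post_init__(self) -> None:
        self.wavelength, self.intensity = _check_xy(
            self.wavelength, self.intensity, "wavelength"
        )

    def interp(self, wavelength_nm: float) -> float:
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if not lo <= wavelength_nm <= hi:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside grid [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength_nm, self.wavelength, self.intensity))


@dataclass
class CorrelationCurve:
    """FCS autocorrelation: lag time (s) vs G(tau), optional per-point SD."""

    lag: np.ndarray
    g: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lag, self.g = _check_xy(self.lag, self.g, "lag")
        if np.any(self.lag <= 0):
            raise ValueError("lag times must be positive")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.g.shape:
                raise ValueError("sd must match g in length")


@dataclass
class EPRSpectrum:
    """First-derivative cwEPR spectrum: field (mT) vs amplitude (a.u.)."""

    field: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.field, self.amplitude = _check_xy(self.field, self.amplitude, "field")


@dataclass
class LipidSpecies:
    """One lipid species of a liposome composition."""

    name: str
    fraction: float  # mol fraction
    chains_per_lipid: int = 2
    unsaturated_chains_per_lipid: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("mol fraction must lie in [0, 1]")
        if self.chains_per_lipid < 0 or self.unsaturated_chains_per_lipid < 0:
            raise ValueError("chain counts must be nonnegative")
        if self.unsaturated_chains_per_lipid > self.chains_per_lipid:
            raise ValueError("unsaturated chains cannot exceed chains per lipid")


@dataclass
class LiposomeSpec:
    """Vesicle geometry plus composition for the acyl-chain molarity model.

    Geometry defaults (4 nm bilayer, 0.65 nm² per lipid) are typical fluid
    phosphoglycerolipid values; explicit ``lipid_count`` / ``membrane_volume_l``
    override the geometric estimates when the counts themselves are known.
    """

    outer_diameter_nm: float = 200.0
    bilayer_thickness_nm: float = 4.0
    area_per_lipid_nm2: float = 0.65
    composition: list[LipidSpecies] = field(default_factory=list)
    lipid_count: Optional[float] = None
    membrane_volume_l: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outer_diameter_nm <= 0:
            raise ValueError("outer diameter must be positive")
        if self.bilayer_thickness_nm < 0:
            raise ValueError("bilayer thickness must be nonnegative")
        if self.bilayer_thickness_nm >= self.outer_diameter_nm / 2:
            raise ValueError("bilayer thickness must be smaller than the radius")
        if self.area_per_lipid_nm2 <= 0:
            raise ValueError("area per lipid must be positive")
        if self.composition:
            total = sum(s.fraction for s in self.composition)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"mol fractions must sum to 1 (got {total})")
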