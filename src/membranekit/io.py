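"""Readers and writers for trajectories, topology tables, spectra and maps.

Trajectories travel as multi-model PDB or XYZ frames plus a lipid-topology
CSV (atom_id, lipid_id, leaflet, role, chain, segment, include_in_density);
coordinate parsing is delegated to MDAnalysis (PDB, GRO, XYZ).  Internally
everything is Å; GRO files (nm) are converted by MDAnalysis on read.  XYZ
carries no box record, so the box edges are stored on each frame's comment
line as ``box <lx> <ly> <lz>``.

Spectra and correlation curves are two-column CSV with unit headers;
density maps serialize to long-format CSV plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import MDAnalysis as mda
import numpy as np
import pandas as pd

from .containers import (
    ATOM_TABLE_COLUMNS,
    CorrelationCurve,
    DensityMap,
    DimerTrajectory,
    EmissionSpectrum,
    EPRSpectrum,
    Trajectory,
)

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_topology",
    "read_topology",
    "write_dimer",
    "read_dimer",
    "write_spectrum",
    "read_emission_spectrum",
    "read_correlation_curve",
    "read_epr_spectrum",
    "write_density_map",
]


# ---------------------------------------------------------------------------
# topology table
# ---------------------------------------------------------------------------

def write_topology(atoms: pd.DataFrame, path: str | Path) -> None:
    atoms.loc[:, list(ATOM_TABLE_COLUMNS)].to_csv(path, index=False)


def read_topology(path: str | Path) -> pd.DataFrame:
    atoms = pd.read_csv(path)
    missing = [c for c in ATOM_TABLE_COLUMNS if c not in atoms.columns]
    if missing:
        raise ValueError(f"topology file {path} is missing columns {missing}")
    atoms["include_in_density"] = atoms["include_in_density"].astype(bool)
    return atoms


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _mda_universe(traj: Trajectory) -> mda.Universe:
    lipid_ids = traj.atoms["lipid_id"].to_numpy()
    _, resindex = np.unique(lipid_ids, return_inverse=True)
    n_res = int(resindex.max()) + 1
    u = mda.Universe.empty(
        traj.n_atoms,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", ["C"] * traj.n_atoms)
    u.add_TopologyAttr("elements", ["C"] * traj.n_atoms)
    u.add_TopologyAttr("resnames", ["LIP"] * n_res)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    return u


def write_trajectory(
    traj: Trajectory, path: str | Path, topology_path: str | Path | None = None
) -> None:
    """Write frames as multi-model PDB or XYZ (by extension) plus topology CSV."""
    path = Path(path)
    if topology_path is not None:
        write_topology(traj.atoms, topology_path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                box = traj.boxes[f]
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"box {box[0]:.6f} {box[1]:.6f} {box[2]:.6f}\n")
                for x, y, z in traj.positions[f]:
                    fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
        return
    if suffix != ".pdb":
        raise ValueError(f"unsupported trajectory format {suffix!r} (use .pdb or .xyz)")
    u = _mda_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as writer:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.positions[f]
                u.dimensions = [*traj.boxes[f], 90.0, 90.0, 90.0]
                writer.write(u.atoms)


def _xyz_boxes(path: Path, n_frames: int, n_atoms: int) -> np.ndarray:
    """Box edges from the per-frame comment lines of an XYZ file."""
    boxes = []
    with open(path) as fh:
        lines = fh.readlines()
    stride = n_atoms + 2
    for f in range(n_frames):
        comment = lines[f * stride + 1].split()
        if len(comment) != 4 or comment[0] != "box":
            raise ValueError(
                f"{path}: frame {f} comment line must read 'box lx ly lz'"
            )
        boxes.append([float(v) for v in comment[1:]])
    return np.asarray(boxes)


def _pdb_header_boxes(path: Path, n_frames: int) -> np.ndarray:
    """Box edges from CRYST1 records placed outside the MODEL blocks.

    Multi-model files commonly carry a single header CRYST1 that frame
    readers do not attach to every model; one record is tiled across all
    frames, and one record per frame is used as-is.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                records.append([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])])
    if len(records) == 1:
        return np.tile(records[0], (n_frames, 1))
    if len(records) == n_frames:
        return np.asarray(records)
    raise ValueError(f"{path}: no usable CRYST1 box records")


def read_trajectory(path: str | Path, topology_path: str | Path) -> Trajectory:
    """Read a coordinate file (PDB, GRO or XYZ) plus its topology CSV."""
    path = Path(path)
    atoms = read_topology(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if len(u.atoms) != len(atoms):
        first_bad = min(len(u.atoms), len(atoms))
        raise ValueError(
            f"{path} has {len(u.atoms)} atoms but topology lists {len(atoms)}; "
            f"first mismatch at atom index {first_bad}"
        )
    positions = []
    boxes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            positions.append(ts.positions.astype(float).copy())
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes.append(ts.dimensions[:3].astype(float).copy())
    positions = np.asarray(positions)
    if len(boxes) == len(positions):
        boxes = np.asarray(boxes)
    elif path.suffix.lower() == ".xyz":
        boxes = _xyz_boxes(path, len(positions), len(atoms))
    elif path.suffix.lower() == ".pdb":
        boxes = _pdb_header_boxes(path, len(positions))
    else:
        raise ValueError(f"{path}: no box information in coordinate file")
    return Trajectory(positions=positions, boxes=boxes, atoms=atoms)


# ---------------------------------------------------------------------------
# dimer trajectories (two-chain multi-model PDB)
# ---------------------------------------------------------------------------

def write_dimer(traj: DimerTrajectory, path: str | Path) -> None:
    """Write a dimer as multi-model PDB with one CA per residue, chains A/B."""
    n_res = traj.n_residues
    n_atoms = 2 * n_res
    resindex = np.arange(n_atoms)
    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_atoms,
        atom_resindex=resindex,
        residue_segindex=np.repeat([0, 1], n_res),
        n_segments=2,
        trajectory=True,
    )
    u.add_TopologyAttr("names", ["CA"] * n_atoms)
    u.add_TopologyAttr("resnames", ["ALA"] * n_atoms)
    u.add_TopologyAttr("resids", np.tile(np.arange(1, n_res + 1), 2))
    u.add_TopologyAttr("chainIDs", ["A"] * n_res + ["B"] * n_res)
    u.add_TopologyAttr("segids", ["A", "B"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n_atoms, multiframe=True) as writer:
            for f in range(traj.n_frames):
                u.atoms.positions = np.vstack(
                    [traj.positions_a[f], traj.positions_b[f]]
                )
                writer.write(u.atoms)


def read_dimer(path: str | Path, sensor_index: int) -> DimerTrajectory:
    """Read a two-chain multi-model PDB into a :class:`DimerTrajectory`."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    chain_a = u.select_atoms("chainID A")
    chain_b = u.select_atoms("chainID B")
    if len(chain_a) == 0 or len(chain_b) == 0:
        raise ValueError(f"{path}: expected two chains with IDs A and B")
    if len(chain_a) != len(chain_b):
        raise ValueError(
            f"{path}: chains differ in length ({len(chain_a)} vs {len(chain_b)})"
        )
    pos_a, pos_b = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in u.trajectory:
            pos_a.append(chain_a.positions.astype(float).copy())
            pos_b.append(chain_b.positions.astype(float).copy())
    return DimerTrajectory(
        positions_a=np.asarray(pos_a),
        positions_b=np.asarray(pos_b),
        sensor_index=sensor_index,
    )


# ---------------------------------------------------------------------------
# spectra and curves
# ---------------------------------------------------------------------------

_SPECTRUM_HEADERS = {
    EmissionSpectrum: ("wavelength_nm", "intensity_au"),
    CorrelationCurve: ("lag_s", "g"),
    EPRSpectrum: ("field_mT", "amplitude_au"),
}


def write_spectrum(spectrum, path: str | Path) -> None:
    """Write any 2-column trace (emission, FCS, EPR) as CSV with unit headers."""
    for cls, headers in _SPECTRUM_HEADERS.items():
        if isinstance(spectrum, cls):
            x, y = headers
            arrays = {
                EmissionSpectrum: lambda s: (s.wavelength, s.intensity),
                CorrelationCurve: lambda s: (s.lag, s.g),
                EPRSpectrum: lambda s: (s.field, s.amplitude),
            }[cls](spectrum)
            pd.DataFrame({x: arrays[0], y: arrays[1]}).to_csv(path, index=False)
            return
    raise TypeError(f"unsupported spectrum type {type(spectrum)}")


def _read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_emission_spectrum(path: str | Path) -> EmissionSpectrum:
    wl, inten = _read_two_column(path)
    return EmissionSpectrum(wavelength=wl, intensity=inten)


def read_correlation_curve(path: str | Path) -> CorrelationCurve:
    lag, g = _read_two_column(path)
    return CorrelationCurve(lag=lag, g=g)


def read_epr_spectrum(path: str | Path) -> EPRSpectrum:
    field, amp = _read_two_column(path)
    return EPRSpectrum(field=field, amplitude=amp)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def write_density_map(dmap: DensityMap, csv_path: str | Path) -> None:
    """Serialize a map as long-format CSV (x,y,z,density) + JSON metadata."""
    csv_path = Path(csv_path)
    nx, ny, nz = dmap.density.shape
    xi, yi, zi = np.meshgrid(
        dmap.axis_centers(0), dmap.axis_centers(1), dmap.axis_centers(2),
        indexing="ij",
    )
    pd.DataFrame(
        {
            "x": xi.ravel(),
            "y": yi.ravel(),
            "z": zi.ravel(),
            "density": dmap.density.ravel(),
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "origin": list(dmap.origin),
        "voxel_edge": dmap.voxel_edge,
        "shape": [int(nx), int(ny), int(nz)],
        "n_frames": dmap.n_frames,
        "label": dmap.label,
        "units": "atoms/A^3",
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
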