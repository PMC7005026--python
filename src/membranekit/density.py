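"""Local lipid-atom number-density maps on a voxel grid.

The packing-density representation: lipid-atom counts in cubic voxels
(1 Å edge by default), averaged over frames and normalized to atoms/Å³,
projected to depth × lateral maps or 1D depth profiles, and compared
between compositions through signed difference maps.  The depth band
3–10 Å from the bilayer center is the region probed by the sensory
tryptophan of the saturation sensor and gets a dedicated band statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BilayerFrame, DensityMap, DifferenceMap, Trajectory

__all__ = [
    "center_and_wrap",
    "voxel_density",
    "project_depth_lateral",
    "depth_profile",
    "difference_map",
    "band_statistic",
    "BandStatistic",
]

SENSOR_BAND = (3.0, 10.0)  # Å from the bilayer center


def _midplane_z(positions: np.ndarray, atoms: pd.DataFrame) -> float:
    """Midplane as the mean of the per-leaflet mean headgroup z."""
    head = atoms["role"].to_numpy() == "headgroup"
    means = []
    for leaflet in ("upper", "lower"):
        sel = head & (atoms["leaflet"].to_numpy() == leaflet)
        if not sel.any():
            raise ValueError(f"{leaflet} leaflet has no headgroup atoms")
        means.append(positions[sel, 2].mean())
    return float(np.mean(means))


def _center_and_wrap_positions(
    positions: np.ndarray, box: np.ndarray, atoms: pd.DataFrame
) -> np.ndarray:
    out = positions.copy()
    out[:, 2] -= _midplane_z(positions, atoms)
    out[:, 0] = np.mod(out[:, 0], box[0])
    out[:, 1] = np.mod(out[:, 1], box[1])
    # z is periodic about the midplane: wrap into [-Lz/2, Lz/2)
    lz = box[2]
    out[:, 2] = np.mod(out[:, 2] + lz / 2.0, lz) - lz / 2.0
    return out


def center_and_wrap(obj: BilayerFrame | Trajectory):
    """Translate the bilayer midplane to z = 0 and wrap into the box.

    The midplane is the mean of the two per-leaflet mean headgroup z
    coordinates.  Lateral coordinates are wrapped into [0, L); z into
    [-Lz/2, Lz/2).  Idempotent on already-centered input.
    """
    if isinstance(obj, BilayerFrame):
        pos = _center_and_wrap_positions(obj.positions, obj.box, obj.atoms)
        return BilayerFrame(pos, obj.box.copy(), obj.atoms)
    new = np.empty_like(obj.positions)
    for f in range(obj.n_frames):
        new[f] = _center_and_wrap_positions(obj.positions[f], obj.boxes[f], obj.atoms)
    return obj.with_positions(new)


def _frame_counts(
    positions: np.ndarray, box: np.ndarray, voxel_edge: float
) -> np.ndarray:
    """Per-voxel atom counts for one frame on the frame's own box grid.

    Voxels are half-open [k, k+1) in units of ``voxel_edge``; coordinates
    are wrapped so atoms exactly on the upper box face land in voxel 0.
    The grid spans the box to the nearest whole voxel per axis, so that a
    composition with a smaller lateral box is denser per voxel rather than
    spread over a grid larger than its box.
    """
    dims = np.maximum(np.round(box / voxel_edge).astype(int), 1)
    shifted = positions.copy()
    shifted[:, 2] += box[2] / 2.0  # grid origin at (0, 0, -Lz/2)
    idx = np.floor(shifted / voxel_edge).astype(int)
    idx = np.mod(idx, dims)  # wraps the upper-face edge case
    counts = np.zeros(dims, dtype=float)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return counts


def voxel_density(traj: Trajectory, voxel_edge: float = 1.0) -> DensityMap:
    """Frame-averaged lipid-atom number density, atoms/Å³.

    Only atoms with ``include_in_density`` set contribute.  Frames are
    binned on their own box and averaged on the common (cropped) grid, so
    the integral of the density times the voxel volume equals the mean
    in-grid atom count per frame.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    mask = traj.atoms["include_in_density"].to_numpy().astype(bool)
    if not mask.any():
        raise ValueError("no atoms flagged for density calculation")

    per_frame = [
        _frame_counts(traj.positions[f][mask], traj.boxes[f], voxel_edge)
        for f in range(traj.n_frames)
    ]
    dims = np.array([c.shape for c in per_frame])
    common = dims.min(axis=0)
    if not np.all(dims == common):
        # crop laterally from the far face, symmetrically about z = 0 in z
        cropped = []
        for c in per_frame:
            dz = c.shape[2] - common[2]
            if dz % 2 != 0:
                raise ValueError(
                    "frame z extents differ by an odd voxel count; cannot "
                    "crop symmetrically about the midplane"
                )
            lo = dz // 2
            cropped.append(c[: common[0], : common[1], lo: lo + common[2]])
        per_frame = cropped

    mean_counts = np.mean(per_frame, axis=0)
    lz = common[2] * voxel_edge
    origin = np.array([0.0, 0.0, -lz / 2.0])
    return DensityMap(
        density=mean_counts / voxel_edge**3,
        origin=origin,
        voxel_edge=voxel_edge,
        n_frames=traj.n_frames,
        label=traj.label,
    )


def project_depth_lateral(dmap: DensityMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project a 3D map to depth × lateral by averaging over the y axis.

    Returns (map2d, z_centers, x_centers) with map2d of shape (nz, nx):
    rows are distance from the bilayer center, columns lateral position.
    """
    map2d = dmap.density.mean(axis=1).T  # (nx, nz) -> (nz, nx)
    return map2d, dmap.z_centers, dmap.axis_centers(0)


def depth_profile(dmap: DensityMap, symmetrize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Laterally averaged density per z bin.

    Returns (z_centers, profile).  With ``symmetrize`` the +z and −z bins
    are averaged and the profile is reported over |z|.
    """
    profile = dmap.density.mean(axis=(0, 1))
    z = dmap.z_centers
    if not symmetrize:
        return z, profile
    folded = 0.5 * (profile + profile[::-1])
    half = len(z) // 2
    return np.abs(z[half:]), folded[half:]


def difference_map(map_a: DensityMap, map_b: DensityMap) -> DifferenceMap:
    """Signed voxel-wise difference map (a − b) on the common grid.

    Both maps must share the voxel edge; grids of unequal extent are
    cropped to the common extent (laterally from the far face, z
    symmetrically about the midplane).
    """
    if abs(map_a.voxel_edge - map_b.voxel_edge) > 1e-12:
        raise ValueError(
            f"voxel edges differ: {map_a.voxel_edge} vs {map_b.voxel_edge}"
        )
    da, db = map_a.density, map_b.density
    common = np.minimum(da.shape, db.shape)

    def crop(d):
        dz = d.shape[2] - common[2]
        if dz % 2 != 0:
            raise ValueError("z extents differ by an odd voxel count")
        lo = dz // 2
        return d[: common[0], : common[1], lo: lo + common[2]]

    da, db = crop(da), crop(db)
    lz = common[2] * map_a.voxel_edge
    return DifferenceMap(
        density=da - db,
        origin=np.array([0.0, 0.0, -lz / 2.0]),
        voxel_edge=map_a.voxel_edge,
        n_frames=map_a.n_frames,
        label=f"{map_a.label} - {map_b.label}",
        label_minuend=map_a.label,
        label_subtrahend=map_b.label,
    )


@dataclass
class BandStatistic:
    """Mean ± SD of the (difference) density over a |z| band."""

    mean: float
    sd: float
    n_voxels: int
    z_min: float
    z_max: float


def band_statistic(
    dmap: DensityMap, z_min: float = SENSOR_BAND[0], z_max: float = SENSOR_BAND[1]
) -> BandStatistic:
    """Density statistic over voxels with z_min ≤ |z| ≤ z_max (both leaflets)."""
    if z_min >= z_max:
        raise ValueError("z_min must be smaller than z_max")
    z = dmap.z_centers
    if z_max > np.max(np.abs(z)) + dmap.voxel_edge / 2.0:
        raise ValueError(
            f"band upper edge {z_max} Å lies outside the grid "
            f"(|z| up to {np.max(np.abs(z)):.1f} Å)"
        )
    sel = (np.abs(z) >= z_min) & (np.abs(z) <= z_max)
    if not sel.any():
        raise ValueError("no voxel centers inside the requested band")
    vals = dmap.density[:, :, sel].ravel()
    return BandStatistic(
        mean=float(vals.mean()),
        sd=float(vals.std()),
        n_voxels=int(vals.size),
        z_min=z_min,
        z_max=z_max,
    )
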