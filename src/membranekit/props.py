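"""Standard bilayer descriptors: area per lipid, thickness, chain order.

These summarize each composition alongside the voxel density maps.  The
order parameter uses S = ⟨(3 cos²θ − 1)/2⟩ with θ measured against the
bilayer normal (+z after centering), evaluated per chain segment either
from the segment(i−1)→segment(i+1) vector (default, robust for reduced
chain representations) or from consecutive-segment bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Trajectory

__all__ = ["area_per_lipid", "thickness", "order_parameters", "OrderProfile"]


def _lipids_per_leaflet(atoms: pd.DataFrame) -> dict[str, int]:
    return {
        leaflet: atoms.loc[atoms["leaflet"] == leaflet, "lipid_id"].nunique()
        for leaflet in ("upper", "lower")
    }


def area_per_lipid(traj: Trajectory):
    """Lateral box area divided by lipids per leaflet, frame-averaged (Å²).

    Returns (mean, sd) when both leaflets hold the same lipid count, else a
    per-leaflet dict {leaflet: (mean, sd)}.
    """
    counts = _lipids_per_leaflet(traj.atoms)
    if min(counts.values()) == 0:
        raise ValueError("a leaflet contains no lipids")
    areas = traj.boxes[:, 0] * traj.boxes[:, 1]
    if counts["upper"] == counts["lower"]:
        apl = areas / counts["upper"]
        return float(apl.mean()), float(apl.std())
    return {
        leaflet: (float((areas / n).mean()), float((areas / n).std()))
        for leaflet, n in counts.items()
    }


def thickness(traj: Trajectory, reference_role: str = "headgroup"):
    """Membrane thickness (Å ± SD): distance between reference-atom planes.

    Per frame, the mean z of ``reference_role`` atoms in the upper leaflet
    minus that of the lower leaflet; averaged over frames.  Translation of
    whole frames in z leaves the result unchanged.
    """
    roles = traj.atoms["role"].to_numpy()
    leaflets = traj.atoms["leaflet"].to_numpy()
    upper = (roles == reference_role) & (leaflets == "upper")
    lower = (roles == reference_role) & (leaflets == "lower")
    if not upper.any() or not lower.any():
        raise ValueError(f"missing {reference_role!r} reference atoms in a leaflet")
    per_frame = traj.positions[:, upper, 2].mean(axis=1) - traj.positions[
        :, lower, 2
    ].mean(axis=1)
    return float(per_frame.mean()), float(per_frame.std())


@dataclass
class OrderProfile:
    """Per-segment order parameter profile.

    ``segment`` indexes chain positions; ``s`` is the order parameter in
    [−0.5, 1]; ``sem`` is the standard error over frames.  ``n_degenerate``
    counts zero-length vectors that were skipped.
    """

    segment: np.ndarray
    s: np.ndarray
    sem: np.ndarray
    n_degenerate: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"segment": self.segment, "S": self.s, "sem": self.sem})


def order_parameters(
    traj: Trajectory, vector_convention: str = "segment"
) -> OrderProfile:
    """Acyl-chain order parameter S per segment index.

    S = ⟨(3 cos²θ − 1)/2⟩, θ against +z, averaged over chains and frames.
    The ``segment`` convention uses the vector segment(i−1)→segment(i+1)
    (defined for interior segments); ``bond`` uses segment(i)→segment(i+1).
    """
    if vector_convention not in ("segment", "bond"):
        raise ValueError("vector_convention must be 'segment' or 'bond'")
    atoms = traj.atoms
    chain_sel = atoms["role"].to_numpy() == "chain"
    if not chain_sel.any():
        raise ValueError("trajectory has no chain atoms")

    atoms_pos = atoms.reset_index(drop=True)
    chain_atoms = atoms_pos.loc[chain_sel].copy()
    chain_atoms["row"] = chain_atoms.index  # positional row into the positions array
    chain_atoms = chain_atoms.sort_values(["lipid_id", "chain", "segment"])
    counts = chain_atoms.groupby(["lipid_id", "chain"]).size()
    if counts.nunique() != 1:
        raise ValueError("chains have unequal segment counts")
    n_seg = int(counts.iloc[0])
    if vector_convention == "segment" and n_seg < 3:
        raise ValueError("segment convention needs chains with >=3 segments")
    rows = chain_atoms["row"].to_numpy().reshape(-1, n_seg)

    pos = traj.positions[:, rows, :]  # (n_frames, n_chains, n_seg, 3)
    if vector_convention == "segment":
        vec = pos[:, :, 2:, :] - pos[:, :, :-2, :]
        seg_index = np.arange(1, n_seg - 1)
    else:
        vec = pos[:, :, 1:, :] - pos[:, :, :-1, :]
        seg_index = np.arange(0, n_seg - 1)

    norm = np.linalg.norm(vec, axis=-1)
    degenerate = norm < 1e-12
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        warnings.warn(f"skipped {n_degenerate} zero-length chain vectors")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = np.where(degenerate, np.nan, (vec[..., 2] / norm) ** 2)
    s_frame = np.nanmean(0.5 * (3.0 * cos2 - 1.0), axis=1)  # (n_frames, n_vec)
    s_mean = np.nanmean(s_frame, axis=0)
    nf = traj.n_frames
    s_sem = (
        np.nanstd(s_frame, axis=0, ddof=1) / np.sqrt(nf) if nf > 1
        else np.zeros_like(s_mean)
    )
    return OrderProfile(segment=seg_index, s=s_mean, sem=s_sem, n_degenerate=n_degenerate)
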