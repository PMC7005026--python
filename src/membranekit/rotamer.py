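"""Rotational-state analysis of a two-helix transmembrane dimer.

The sensor residue of each protomer is assigned an azimuth φ in the plane
normal to its helix axis, measured from the connector pointing toward the
partner helix (0° = facing the partner).  Frames are classified into three
configurations — both sensors facing the interface, both pointing away, or
mixed — and state populations are estimated with bootstrap confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DimerTrajectory

__all__ = [
    "helix_axis",
    "sensor_azimuth",
    "classify_state",
    "state_populations",
    "analyze_dimer",
    "RotamerStateSeries",
    "STATE_LABELS",
]

STATE_LABELS = ("facing-facing", "mixed", "away-away")

#: helices crossing at more than this angle get flagged, not classified
MAX_CROSSING_ANGLE = 45.0  # degrees


def helix_axis(backbone: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis and centroid of an ordered backbone trace.

    The axis is the dominant right-singular vector of the centered point
    cloud, oriented from the N terminus (first point) toward the C terminus
    (last point).  Returns (unit_axis, centroid).
    """
    pts = np.asarray(backbone, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("backbone must be an (n>=4, 3) point set")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis, centroid


def _azimuth_frame(
    own_axis: np.ndarray, own_centroid: np.ndarray, partner_centroid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis (u, v): u toward the partner, v = axis × u."""
    connector = partner_centroid - own_centroid
    u = connector - np.dot(connector, own_axis) * own_axis
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise ValueError("helix axes are coincident: azimuth undefined")
    u /= norm
    v = np.cross(own_axis, u)
    return u, v


def sensor_azimuth(traj: DimerTrajectory, frame: int, protomer: int) -> float:
    """Azimuth (degrees, (−180, 180]) of the sensor residue of one protomer.

    The sensor position is projected off the helix axis; the angle is
    measured from the connector toward the partner helix, with positive
    rotation right-handed about the N→C axis.
    """
    if protomer not in (0, 1):
        raise ValueError("protomer must be 0 or 1")
    own = traj.positions_a[frame] if protomer == 0 else traj.positions_b[frame]
    other = traj.positions_b[frame] if protomer == 0 else traj.positions_a[frame]
    axis, centroid = helix_axis(own)
    _, partner_centroid = helix_axis(other)
    u, v = _azimuth_frame(axis, centroid, partner_centroid)
    sensor = own[traj.sensor_index]
    r = sensor - centroid
    r = r - np.dot(r, axis) * axis
    phi = np.degrees(np.arctan2(np.dot(r, v), np.dot(r, u)))
    if phi <= -180.0:
        phi += 360.0
    return float(phi)


def classify_state(phi1: float, phi2: float, facing_threshold: float = 60.0) -> str:
    """Three-state classification of a pair of sensor azimuths.

    Both |φ| below the threshold → facing-facing; both |φ| above
    180° − threshold → away-away; anything else → mixed.
    """
    a1, a2 = abs(phi1), abs(phi2)
    if a1 < facing_threshold and a2 < facing_threshold:
        return "facing-facing"
    if a1 > 180.0 - facing_threshold and a2 > 180.0 - facing_threshold:
        return "away-away"
    return "mixed"


@dataclass
class RotamerStateSeries:
    """Per-frame azimuths and state labels with population estimates."""

    phi1: np.ndarray
    phi2: np.ndarray
    labels: np.ndarray  # array of state-label strings
    crossing_flags: np.ndarray  # frames where the axes cross too steeply
    populations: dict = field(default_factory=dict)
    facing_threshold: float = 60.0


def state_populations(
    labels: np.ndarray | RotamerStateSeries,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Empirical state fractions with percentile-bootstrap CIs over frames.

    Returns {state: {"fraction": f, "ci": (lo, hi)}}; fractions sum to 1.
    """
    if isinstance(labels, RotamerStateSeries):
        labels = labels.labels
    labels = np.asarray(labels)
    if labels.size < 1:
        raise ValueError("need at least one frame")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = labels.size
    onehot = np.column_stack([labels == s for s in STATE_LABELS]).astype(float)
    fractions = onehot.mean(axis=0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = onehot[idx].mean(axis=1)  # (n_boot, 3)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    return {
        s: {"fraction": float(fractions[i]), "ci": (float(lo[i]), float(hi[i]))}
        for i, s in enumerate(STATE_LABELS)
    }


def analyze_dimer(
    traj: DimerTrajectory,
    facing_threshold: float = 60.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> RotamerStateSeries:
    """Full per-frame rotamer analysis of a dimer trajectory.

    Computes both sensor azimuths per frame, flags frames whose helix axes
    cross at more than 45° (the azimuth definition degrades there), labels
    the remaining frames, and estimates state populations with bootstrap
    CIs.  Flagged frames keep their azimuths but carry the label
    ``"flagged"`` and are excluded from the populations.
    """
    n = traj.n_frames
    phi1 = np.empty(n)
    phi2 = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    labels = np.empty(n, dtype=object)
    for f in range(n):
        axis_a, _ = helix_axis(traj.positions_a[f])
        axis_b, _ = helix_axis(traj.positions_b[f])
        crossing = np.degrees(
            np.arccos(np.clip(abs(np.dot(axis_a, axis_b)), -1.0, 1.0))
        )
        phi1[f] = sensor_azimuth(traj, f, 0)
        phi2[f] = sensor_azimuth(traj, f, 1)
        if crossing > MAX_CROSSING_ANGLE:
            flags[f] = True
            labels[f] = "flagged"
        else:
            labels[f] = classify_state(phi1[f], phi2[f], facing_threshold)

    usable = labels[~flags]
    if usable.size == 0:
        raise ValueError("all frames flagged: no classifiable configurations")
    populations = state_populations(usable.astype(str), n_boot=n_boot, seed=seed)
    return RotamerStateSeries(
        phi1=phi1,
        phi2=phi2,
        labels=labels.astype(str),
        crossing_flags=flags,
        populations=populations,
        facing_threshold=facing_threshold,
    )
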