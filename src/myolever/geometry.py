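"""Crossbridge-centric coordinate system and lever-arm (tail) angles.

The coordinate system is built from a weakly-bound actomyosin reference
geometry: the origin sits at the centroid of an actin pentamer, axis 2 (e2)
runs along the thin filament (the dominant principal axis of the actin
coordinates), axis 1 (e1) points from the filament toward the myosin anchor
(interfilament direction), and axis 3 (e3) completes a right-handed triad.

The lever-arm orientation is a unit "tail vector" joining the backbone
(N, CA, C) centroids of two residue groups at the start of the tail helix.
Its orientation is summarized by three angles:

* elevation — rise of the tail toward +e1 out of the e2-e3 plane,
  ``90° − angle(v, e1)``, in [−90°, 90°];
* azimuth — position around e1, measured from +e2 toward +e3,
  ``atan2(v·e3, v·e2)``, in (−180°, 180°];
* tilt — ``angle(v, e3)`` in [0°, 180°].

For a single unit vector the tilt is determined by elevation and azimuth
(``cos tilt = cos el · sin az``); it is reported as a redundant diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alignment import apply_transform, kabsch_superpose
from .model_io import BACKBONE_ATOMS, MolecularModel, Selection, Trajectory

__all__ = [
    "CrossbridgeFrame",
    "TailAngles",
    "AngleDensity",
    "build_crossbridge_frame",
    "superpose_to_reference",
    "tail_vector",
    "compute_tail_angles",
    "angle_density",
    "angle_timeseries",
    "angle_summary",
]

DEFAULT_PROXIMAL = (769, 771)
DEFAULT_DISTAL = (784, 787)


@dataclass
class CrossbridgeFrame:
    """Right-handed orthonormal triad anchored at the thin-filament centroid."""

    origin: np.ndarray
    e1: np.ndarray   # interfilament direction
    e2: np.ndarray   # thin-filament direction
    e3: np.ndarray   # normal to the 1-2 plane

    def __post_init__(self) -> None:
        for v in (self.e1, self.e2, self.e3):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("frame axes must be unit vectors")
        dots = (
            abs(self.e1 @ self.e2), abs(self.e1 @ self.e3), abs(self.e2 @ self.e3),
        )
        if max(dots) > 1e-9:
            raise ValueError("frame axes must be pairwise orthogonal")
        if np.linalg.det(np.column_stack([self.e1, self.e2, self.e3])) < 0:
            raise ValueError("frame must be right-handed (det +1)")


@dataclass
class TailAngles:
    """Elevation/azimuth/tilt of the tail vector, in degrees."""

    elevation: float   # [-90, 90]
    azimuth: float     # (-180, 180]
    tilt: float        # [0, 180]
    degenerate: bool = False  # azimuth undefined at |elevation| = 90


@dataclass
class AngleDensity:
    """Normalized histogram of angle samples (1-D or 2-D)."""

    edges: np.ndarray                   # bin edges, degrees, uniform width
    density: np.ndarray                 # per-bin density (per degree / degree^2)
    edges2: np.ndarray | None = None    # second-dimension edges for 2-D

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def build_crossbridge_frame(
    reference_complex: MolecularModel,
    actin_selection: Selection,
    anchor_selection: Selection,
) -> CrossbridgeFrame:
    """Construct the crossbridge frame from a reference actomyosin complex.

    ``actin_selection`` supplies the thin-filament atoms (centroid -> origin,
    dominant principal axis -> e2, oriented from the first toward the last
    selected atom); ``anchor_selection`` supplies the myosin lever-arm anchor
    whose direction from the origin, orthogonalized against e2, gives e1.
    """
    if len(actin_selection) < 3:
        raise ValueError("actin selection must contain at least 3 atoms")
    if len(anchor_selection) == 0:
        raise ValueError("anchor selection is empty")
    pts = reference_complex.coords[actin_selection.indices]
    origin = pts.mean(axis=0)
    centered = pts - origin
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:
        raise ValueError("degenerate actin geometry: all atoms coincide")
    if evals[-1] - evals[-2] < 1e-9 * evals[-1]:
        raise ValueError("degenerate actin geometry: no unique principal axis")
    e2 = evecs[:, -1]
    span = pts[-1] - pts[0]
    if e2 @ span < 0:
        e2 = -e2
    anchor_com = reference_complex.coords[anchor_selection.indices].mean(axis=0)
    w = anchor_com - origin
    w_perp = w - (w @ e2) * e2
    norm = np.linalg.norm(w_perp)
    if norm < 1e-9:
        raise ValueError("anchor lies on the e2 line; e1 is undefined")
    e1 = w_perp / norm
    e3 = np.cross(e1, e2)
    e3 /= np.linalg.norm(e3)
    return CrossbridgeFrame(origin=origin, e1=e1, e2=e2 / np.linalg.norm(e2), e3=e3)


def superpose_to_reference(
    traj: Trajectory,
    hlh_selection: Selection,
    reference: MolecularModel,
    reference_selection: Selection,
) -> Trajectory:
    """Rigid-body fit every frame onto the reference via the HLH motif.

    The two selections must have equal atom counts in corresponding order.
    Internal geometry of each frame is unchanged (pure rotation+translation).
    """
    if len(hlh_selection) != len(reference_selection):
        raise ValueError(
            f"selection length mismatch: {len(hlh_selection)} mobile vs "
            f"{len(reference_selection)} reference atoms"
        )
    ref = reference.coords[reference_selection.indices]
    out = np.empty_like(traj.frames)
    for i, f in enumerate(traj.frames):
        rot, tr, _ = kabsch_superpose(f[hlh_selection.indices], ref)
        out[i] = apply_transform(f, rot, tr)
    return replace(traj, frames=out)


def _backbone_centroid(
    coords: np.ndarray, topology: MolecularModel, resid_range: tuple[int, int]
) -> np.ndarray:
    lo, hi = resid_range
    missing = []
    idx = []
    for r in range(lo, hi + 1):
        for name in BACKBONE_ATOMS:
            hit = np.where((topology.resid == r) & (topology.name == name))[0]
            if len(hit) == 0:
                missing.append(f"{name}@{r}")
            else:
                idx.append(hit[0])
    if missing:
        raise ValueError(
            f"missing backbone atoms for tail vector: {', '.join(missing)}"
        )
    return coords[np.array(idx)].mean(axis=0)


def tail_vector(
    coords: np.ndarray,
    topology: MolecularModel,
    proximal: tuple[int, int] = DEFAULT_PROXIMAL,
    distal: tuple[int, int] = DEFAULT_DISTAL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vector from the proximal to the distal backbone-centroid group.

    Returns ``(unit vector, proximal centroid, distal centroid)``.
    """
    p = _backbone_centroid(coords, topology, proximal)
    d = _backbone_centroid(coords, topology, distal)
    v = d - p
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("tail endpoints coincide; vector has zero length")
    return v / norm, p, d


def compute_tail_angles(v: np.ndarray, frame: CrossbridgeFrame) -> TailAngles:
    """Elevation/azimuth/tilt of a unit vector in the crossbridge frame."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("zero tail vector")
    v = v / norm
    c1 = float(np.clip(v @ frame.e1, -1.0, 1.0))
    c2 = float(v @ frame.e2)
    c3 = float(v @ frame.e3)
    elevation = 90.0 - np.degrees(np.arccos(c1))
    degenerate = bool(np.hypot(c2, c3) < 1e-9)
    azimuth = 0.0 if degenerate else float(np.degrees(np.arctan2(c3, c2)))
    if azimuth <= -180.0:
        azimuth = 180.0
    tilt = float(np.degrees(np.arccos(np.clip(c3, -1.0, 1.0))))
    return TailAngles(
        elevation=float(elevation), azimuth=azimuth, tilt=tilt, degenerate=degenerate
    )


def angle_density(
    samples,
    bin_width: float = 2.0,
    samples2=None,
    bin_width2: float | None = None,
) -> AngleDensity:
    """Probability density over uniform angle bins (default 2°; 2°×2° in 2-D).

    Densities integrate to one: Σ density·width = 1 (1-D) or
    Σ density·area = 1 (2-D).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no angle samples")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")

    def _edges(x, w):
        lo = w * np.floor(x.min() / w)
        n = max(1, int(np.ceil((x.max() - lo) / w)))
        if lo + n * w <= x.max():
            n += 1
        return lo + w * np.arange(n + 1)

    e1 = _edges(samples, bin_width)
    if samples2 is None:
        dens, _ = np.histogram(samples, bins=e1, density=True)
        return AngleDensity(edges=e1, density=dens)
    samples2 = np.asarray(samples2, dtype=float)
    if samples2.shape != samples.shape:
        raise ValueError("paired angle series must have equal length")
    w2 = bin_width if bin_width2 is None else bin_width2
    e2 = _edges(samples2, w2)
    dens, _, _ = np.histogram2d(samples, samples2, bins=(e1, e2), density=True)
    return AngleDensity(edges=e1, density=dens, edges2=e2)


def angle_timeseries(
    traj: Trajectory,
    frame: CrossbridgeFrame,
    proximal: tuple[int, int] = DEFAULT_PROXIMAL,
    distal: tuple[int, int] = DEFAULT_DISTAL,
) -> pd.DataFrame:
    """Per-frame tail angles for a trajectory already placed in the frame.

    Columns: frame, time_ps, elevation, azimuth, tilt, degenerate,
    replicate, condition.
    """
    rows = []
    for i, coords in enumerate(traj.frames):
        v, _, _ = tail_vector(coords, traj.topology, proximal, distal)
        a = compute_tail_angles(v, frame)
        rows.append((i, i * traj.timestep, a.elevation, a.azimuth, a.tilt, a.degenerate))
    df = pd.DataFrame(
        rows, columns=["frame", "time_ps", "elevation", "azimuth", "tilt", "degenerate"]
    )
    df["replicate"] = traj.replicate
    df["condition"] = traj.condition
    return df


def angle_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and standard deviation of each angle.

    Ordinary (non-circular) moments are used: observed tail-angle ranges sit
    far from the ±180° wrap, so circular corrections are unnecessary; this is
    a documented limitation for data near the wrap-around.
    """
    out = (
        series.groupby("condition")[["elevation", "azimuth", "tilt"]]
        .agg(["mean", "std"])
    )
    return out
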