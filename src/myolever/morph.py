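"""Elevation-binned ensemble averaging and interpolated morph trajectories.

Frames are re-aligned on a motor-domain/lever-arm junction selection,
assigned to twenty 5°-wide elevation bins (half-open [lo, hi) intervals,
anchored at 5°·floor(min/5°)), and averaged per bin.  A morph trajectory
linearly interpolates atom coordinates between consecutive occupied bin
averages.  The interpolation is deliberately Cartesian and nonphysical — it
visualizes the range of motion, not a dynamical pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alignment import apply_transform, kabsch_superpose
from .model_io import MolecularModel, Selection, Trajectory

__all__ = ["BinnedEnsemble", "bin_by_elevation", "interpolate_morph"]

N_BINS = 20
BIN_WIDTH = 5.0  # degrees


@dataclass
class BinnedEnsemble:
    """Per-elevation-bin averaged conformers."""

    edges: np.ndarray                       # N_BINS + 1 uniform edges, degrees
    conformers: dict[int, np.ndarray]       # bin index -> (n_atoms, 3) average
    counts: np.ndarray                      # frames per bin
    topology: MolecularModel

    @property
    def occupied(self) -> list[int]:
        return sorted(self.conformers)

    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def bin_by_elevation(
    traj: Trajectory,
    angles: pd.DataFrame,
    junction_selection: Selection,
    n_bins: int = N_BINS,
    bin_width: float = BIN_WIDTH,
) -> BinnedEnsemble:
    """Align frames on the junction and average coordinates per elevation bin.

    ``angles`` must carry one row per frame (an ``elevation`` column).  The
    bin grid is anchored at ``bin_width·floor(min elevation / bin_width)``;
    frames at a bin edge go to the right-hand bin (half-open convention).
    Frames beyond the grid are left unassigned.
    """
    if len(angles) != traj.n_frames:
        raise ValueError(
            f"angle series has {len(angles)} rows for {traj.n_frames} frames"
        )
    elev = angles["elevation"].to_numpy()
    anchor = bin_width * np.floor(elev.min() / bin_width)
    edges = anchor + bin_width * np.arange(n_bins + 1)
    which = np.floor((elev - anchor) / bin_width).astype(int)
    valid = (which >= 0) & (which < n_bins)

    ref = traj.topology.coords[junction_selection.indices]
    sums: dict[int, np.ndarray] = {}
    counts = np.zeros(n_bins, dtype=int)
    for i, f in enumerate(traj.frames):
        if not valid[i]:
            continue
        rot, tr, _ = kabsch_superpose(f[junction_selection.indices], ref)
        aligned = apply_transform(f, rot, tr)
        b = which[i]
        if b in sums:
            sums[b] += aligned
        else:
            sums[b] = aligned.copy()
        counts[b] += 1
    conformers = {b: sums[b] / counts[b] for b in sums}
    if len(conformers) == 1:
        warnings.warn("all frames fall in a single elevation bin", stacklevel=2)
    return BinnedEnsemble(
        edges=edges, conformers=conformers, counts=counts, topology=traj.topology
    )


def interpolate_morph(binned: BinnedEnsemble, steps_per_transition: int = 10) -> Trajectory:
    """Linear coordinate morph through the occupied bin averages.

    Consecutive occupied bins (ordered by bin center) are joined by
    ``steps_per_transition`` intermediate frames; endpoints equal the bin
    averages exactly, so B occupied bins with s steps yield
    (B−1)·s + B frames.
    """
    occ = binned.occupied
    if len(occ) < 2:
        raise ValueError("need at least 2 occupied bins to morph")
    if steps_per_transition < 0:
        raise ValueError("steps_per_transition must be >= 0")
    s = steps_per_transition
    frames = [binned.conformers[occ[0]]]
    for a, b in zip(occ[:-1], occ[1:]):
        start, end = binned.conformers[a], binned.conformers[b]
        for k in range(1, s + 1):
            t = k / (s + 1)
            frames.append((1 - t) * start + t * end)
        frames.append(end)
    return Trajectory(
        topology=binned.topology,
        frames=np.stack(frames),
        timestep=1.0,
        replicate="morph",
        condition="other",
    )
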