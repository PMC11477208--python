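"""Rigid-body superposition, average structures, LOVO core selection, RMSD/RMSF.

The LOVO (Low-Order-Value-Optimization) fit separates a trajectory into a
least-mobile rigid core and mobile subdomains: frames are iteratively aligned
on the current core to the evolving average structure, per-atom time-averaged
deviations are ranked, and the lowest fraction φ becomes the new core until
membership reaches a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_io import MolecularModel, Selection, Trajectory

__all__ = [
    "kabsch_superpose",
    "apply_transform",
    "superpose_frames",
    "average_structure",
    "lovo_fit",
    "rmsd_series",
    "rmsf_profile",
    "AlignmentResult",
    "RMSFProfile",
]


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``target``.
    The rotation is proper (det +1; reflections are excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both have shape (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    x, y = mobile - cm, target - ct
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 0 or (s[1] < 1e-12 * s[0]):
        raise ValueError("degenerate (rank-deficient) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    diff = x @ rot.T - y
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


@dataclass
class AlignmentResult:
    """Outcome of :func:`lovo_fit`."""

    rotations: np.ndarray        # (F, 3, 3) proper rotations
    translations: np.ndarray     # (F, 3)
    subset: Selection            # least-mobile Cα atoms (indices into topology)
    per_atom_rmsd: np.ndarray    # time-averaged deviation per Cα atom, Å
    per_frame_subset_rmsd: np.ndarray  # Å
    fraction: float
    iterations: int
    converged: bool
    average: np.ndarray          # (n_ca, 3) converged average Cα coordinates

    @property
    def mean_subset_rmsd(self) -> float:
        return float(self.per_atom_rmsd[self._subset_pos].mean())

    @property
    def _subset_pos(self) -> np.ndarray:
        # positions of subset atoms within the Cα selection used for the fit
        return self._pos

    _pos: np.ndarray = None  # set by lovo_fit


def superpose_frames(
    frames: np.ndarray, sel_idx: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Superpose every frame on ``sel_idx`` atoms onto ``reference`` coordinates.

    Returns (transformed frames, rotations, translations).
    """
    out = np.empty_like(frames)
    rots = np.empty((len(frames), 3, 3))
    trans = np.empty((len(frames), 3))
    for i, f in enumerate(frames):
        r, t, _ = kabsch_superpose(f[sel_idx], reference)
        out[i] = apply_transform(f, r, t)
        rots[i], trans[i] = r, t
    return out, rots, trans


def average_structure(traj: Trajectory, selection: Selection | None = None) -> MolecularModel:
    """Per-atom arithmetic mean of coordinates over frames.

    The trajectory is assumed to be pre-aligned; no fitting is done here.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    coords = traj.frames.mean(axis=0)
    if selection is None:
        return traj.topology.with_coords(coords)
    return traj.topology.subset(selection.indices).with_coords(coords[selection.indices])


def lovo_fit(
    traj: Trajectory,
    fraction: float = 0.35,
    ca_selection: Selection | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> AlignmentResult:
    """Identify the fraction-φ least-mobile Cα atoms and align on them.

    Iteration: (i) align every frame on the current subset to the current
    average structure, (ii) recompute the average, (iii) rank Cα atoms by
    time-averaged deviation from the average, (iv) keep the round(φ·N) lowest
    as the new subset.  The initial subset is all Cα atoms; the initial
    average comes from aligning all frames to the first frame.  Convergence
    is subset-membership fixed point; ``tol`` on average-structure drift is a
    secondary stop within each alignment pass.  Ties at the subset boundary
    go to the lower atom index.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if ca_selection is None:
        idx = np.where(traj.topology.name == "CA")[0]
        ca_selection = Selection(idx, provenance="name CA")
    ca = ca_selection.indices
    n_ca = len(ca)
    n_keep = int(round(fraction * n_ca))
    if n_keep < 3:
        raise ValueError(f"fraction {fraction} keeps {n_keep} atoms; need >= 3")

    frames = traj.frames[:, ca, :].copy()
    # bootstrap: align to first frame on all Cα, then average
    frames, _, _ = superpose_frames(frames, np.arange(n_ca), frames[0])
    avg = frames.mean(axis=0)

    subset_pos = np.arange(n_ca)  # positions within the Cα set
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # inner align-to-average until the average stops drifting
        for _ in range(50):
            frames, _, _ = superpose_frames(frames, subset_pos, avg[subset_pos])
            new_avg = frames.mean(axis=0)
            drift = float(np.abs(new_avg - avg).max())
            avg = new_avg
            if drift < tol:
                break
        per_atom = np.sqrt(((frames - avg) ** 2).sum(axis=2).mean(axis=0))
        # stable sort => boundary ties resolved toward the lower index
        new_subset = np.sort(np.argsort(per_atom, kind="stable")[:n_keep])
        if np.array_equal(new_subset, subset_pos) and iterations > 1:
            converged = True
            break
        subset_pos = new_subset

    # final transforms computed on the original full frames
    rots = np.empty((traj.n_frames, 3, 3))
    trans = np.empty((traj.n_frames, 3))
    for i, f in enumerate(traj.frames):
        rots[i], trans[i], _ = kabsch_superpose(f[ca[subset_pos]], avg[subset_pos])
    per_frame = np.sqrt(
        ((frames[:, subset_pos, :] - avg[subset_pos]) ** 2).sum(axis=2).mean(axis=1)
    )
    result = AlignmentResult(
        rotations=rots,
        translations=trans,
        subset=Selection(ca[subset_pos], provenance=f"lovo fraction={fraction}"),
        per_atom_rmsd=per_atom,
        per_frame_subset_rmsd=per_frame,
        fraction=fraction,
        iterations=iterations,
        converged=converged,
        average=avg,
    )
    result._pos = subset_pos
    return result


def rmsd_series(
    traj: Trajectory,
    align_sel: Selection,
    measure_sel: Selection,
    reference: MolecularModel,
) -> np.ndarray:
    """Per-frame RMSD after superposing on ``align_sel`` to ``reference``.

    The RMSD is evaluated over ``measure_sel``, which may differ from the
    alignment mask (e.g. align on a rigid core, measure over all Cα atoms).
    """
    if reference.n_atoms != traj.n_atoms:
        raise ValueError(
            f"reference has {reference.n_atoms} atoms, trajectory has {traj.n_atoms}"
        )
    a, m = align_sel.indices, measure_sel.indices
    ref_a, ref_m = reference.coords[a], reference.coords[m]
    out = np.empty(traj.n_frames)
    for i, f in enumerate(traj.frames):
        rot, tr, _ = kabsch_superpose(f[a], ref_a)
        moved = apply_transform(f[m], rot, tr)
        out[i] = np.sqrt(((moved - ref_m) ** 2).sum(axis=1).mean())
    return out


@dataclass
class RMSFProfile:
    """Per-residue Cα root-mean-square fluctuation about the time average."""

    resid: np.ndarray       # residue numbers
    chain: np.ndarray
    rmsf: np.ndarray        # Å, >= 0
    replicate: str = "1"
    condition: str = "other"


def rmsf_profile(traj: Trajectory, selection: Selection | None = None) -> RMSFProfile:
    """RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>) over frames; pre-aligned input.

    A single-frame trajectory yields all zeros (with a warning).
    """
    import warnings

    if selection is None:
        idx = np.where(traj.topology.name == "CA")[0]
        selection = Selection(idx, provenance="name CA")
    coords = traj.frames[:, selection.indices, :]
    if traj.n_frames == 1:
        warnings.warn("single-frame trajectory: RMSF is identically zero", stacklevel=2)
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    top = traj.topology
    return RMSFProfile(
        resid=top.resid[selection.indices],
        chain=top.chain[selection.indices],
        rmsf=rmsf,
        replicate=traj.replicate,
        condition=traj.condition,
    )
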