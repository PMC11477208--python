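"""Shared fixtures: tiny structures, oracles, and small synthetic scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from myolever.model_io import MolecularModel, Selection, Trajectory
from myolever.synthetic import apo_spec, holo_spec, make_hinged_system, simulate_trajectories


def make_model(coords, resid=None, name=None, chain=None, element=None, resname=None):
    """Convenience constructor for small hand-built models."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    resid = np.asarray(resid if resid is not None else np.arange(1, n + 1))
    name = np.asarray(name if name is not None else ["CA"] * n, dtype=object)
    chain = np.asarray(chain if chain is not None else ["A"] * n, dtype=object)
    element = np.asarray(
        element if element is not None else [nm[0] for nm in name], dtype=object
    )
    resname = np.asarray(resname if resname is not None else ["GLY"] * n, dtype=object)
    return MolecularModel(
        chain=chain, resid=resid, icode=np.full(n, "", dtype=object),
        resname=resname, name=name, element=element, coords=coords,
    )


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent superposition oracle via the Kearsley quaternion eigenvalue
    method: the minimal RMSD comes from the smallest eigenvalue of the 4x4
    Kearsley matrix, with no SVD involved."""
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    d = x - y
    s = x + y
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    sx, sy, sz = s[:, 0], s[:, 1], s[:, 2]
    mat = np.empty((4, 4))
    mat[0, 0] = (dx ** 2 + dy ** 2 + dz ** 2).sum()
    mat[1, 1] = (dx ** 2 + sy ** 2 + sz ** 2).sum()
    mat[2, 2] = (sx ** 2 + dy ** 2 + sz ** 2).sum()
    mat[3, 3] = (sx ** 2 + sy ** 2 + dz ** 2).sum()
    mat[0, 1] = mat[1, 0] = (sy * dz - dy * sz).sum()
    mat[0, 2] = mat[2, 0] = (dx * sz - sx * dz).sum()
    mat[0, 3] = mat[3, 0] = (sx * dy - dx * sy).sum()
    mat[1, 2] = mat[2, 1] = (dx * dy - sx * sy).sum()
    mat[1, 3] = mat[3, 1] = (dx * dz - sx * sz).sum()
    mat[2, 3] = mat[3, 2] = (dy * dz - sy * sz).sum()
    lam = np.linalg.eigvalsh(mat)[0]
    return float(np.sqrt(max(lam, 0.0) / len(mobile)))


def brute_force_contacts(coords, res_keys, cutoff):
    """All-pairs contact oracle: canonical residue pairs with min distance
    <= cutoff."""
    out = set()
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            if res_keys[i] != res_keys[j] and d[i, j] <= cutoff:
                a, b = sorted((res_keys[i], res_keys[j]))
                out.add((a, b))
    return out


@pytest.fixture(scope="session")
def small_apo():
    """A fast apo-like scenario: 1 replicate, 300 frames, planted features on."""
    spec = apo_spec(n_frames=300, n_replicates=1, seed=11)
    system = make_hinged_system(spec)
    trajs, rec = simulate_trajectories(spec, system)
    return spec, system, trajs, rec


@pytest.fixture(scope="session")
def small_holo():
    spec = holo_spec(n_frames=300, n_replicates=1, seed=12)
    system = make_hinged_system(spec)
    trajs, rec = simulate_trajectories(spec, system)
    return spec, system, trajs, rec


@pytest.fixture(scope="session")
def zero_noise_apo():
    """Deterministic geometry: no thermal noise, fixed angles."""
    spec = apo_spec(
        n_frames=5, n_replicates=1, seed=1, noise_sigma=0.0,
        elevation_sd=0.0, azimuth_sd=0.0, saltbridge_break_elevation=None,
    )
    system = make_hinged_system(spec)
    trajs, rec = simulate_trajectories(spec, system)
    return spec, system, trajs, rec
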