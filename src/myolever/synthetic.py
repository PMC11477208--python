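"""Synthetic hinged-domain trajectory generator with known ground truth.

Real pre-powerstroke myosin MD ensembles are multi-microsecond archives; this
module builds a geometric stand-in that exercises every pipeline stage with a
planted, fully recoverable truth:

* a rigid pseudo-motor domain (151 residues on a lattice blob) with a short
  relay segment and a helix-loop-helix surrogate for alignment;
* a converter + tail + pseudo-ELC rigid body hinged at the motor-tail
  junction, whose orientation per frame realizes sampled (elevation, azimuth)
  angles exactly in the crossbridge frame (the tilt of a single direction
  vector is determined by those two and is reported as derived truth);
* a pseudo-actin pentamer for constructing the crossbridge frame;
* dedicated switch-residue pairs whose proximity is Bernoulli-gated to plant
  differential contact occupancies;
* a multi-moiety pseudo-ligand whose terminal groups sample a discrete pose
  mixture around a rigid central ring;
* an elevation-gated salt-bridge pair and residue ranges with inflated
  thermal noise in the apo condition.

Geometry and statistics only: no force field, no solvent, no dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import CrossbridgeFrame, build_crossbridge_frame
from .model_io import MolecularModel, Selection, Trajectory, select

__all__ = [
    "SyntheticSpec",
    "HingedSystem",
    "Truth",
    "make_hinged_system",
    "simulate_trajectories",
    "truth",
    "simulate_contact_tables",
    "apo_spec",
    "holo_spec",
]

# Geometry constants (Å / degrees)
_MOTOR_CENTER = np.array([45.0, 0.0, 0.0])
_HINGE = np.array([66.0, 0.0, 0.0])
_BASE_ELEVATION = 28.0
_BASE_AZIMUTH = 40.0
_TAIL_RISE = 1.5
_SWITCH_NEAR = 3.5
_SWITCH_FAR = 12.0

# Default pose library: rotations (deg) of the two terminal moieties about
# their bond axes.  Poses are far apart relative to the jitter, so mixture
# components are cleanly separable.
DEFAULT_POSES = ((0.0, 0.0), (140.0, 60.0), (250.0, 180.0), (60.0, 300.0))
DEFAULT_POSE_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic condition (apo-like or holo-like).

    Angle means/sds are in degrees; the apo-like condition is broad with mean
    elevation 23°, the holo-like condition narrow with mean 33°, emulating
    the reported OM-induced priming and entropy reduction.  ``tilt_mean`` /
    ``tilt_sd`` are recorded metadata only: for a single direction vector the
    tilt is determined by elevation and azimuth.
    """

    condition: str = "apo"                 # apo | holo
    elevation_mean: float = 23.0
    elevation_sd: float = 6.0
    azimuth_mean: float = 34.0
    azimuth_sd: float = 8.0
    tilt_mean: float | None = None
    tilt_sd: float | None = None
    noise_sigma: float = 0.5               # per-atom isotropic thermal noise, Å
    n_frames: int = 4000                   # emulates 400 ns at 100 ps granularity
    n_replicates: int = 3
    timestep: float = 100.0                # ps
    seed: int = 0
    # planted features
    planted_contacts: tuple = (
        ((300, 301), 0.90, 0.40),
        ((302, 303), 0.60, 0.10),
        ((304, 305), 0.75, 0.25),
        ((306, 307), 0.50, 0.50),          # null pair
    )
    rmsf_inflation: tuple = ((240, 250, 1.5775),)  # apo-only extra sigma -> ΔRMSF ≈ 2 Å
    saltbridge_break_elevation: float | None = 30.0
    pose_library: tuple = DEFAULT_POSES
    pose_weights: tuple = DEFAULT_POSE_WEIGHTS
    pose_jitter: float = 0.05              # Å
    ar1_rho: float = 0.0                   # optional frame-to-frame correlation
    global_motion: bool = True             # random rigid motion per frame

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if abs(sum(self.pose_weights) - 1.0) > 1e-9:
            raise ValueError("pose weights must sum to 1")
        if len(self.pose_weights) != len(self.pose_library):
            raise ValueError("pose weights and library lengths differ")
        for (pair, qa, qh) in self.planted_contacts:
            for q in (qa, qh):
                if not (0.0 <= q <= 1.0):
                    raise ValueError(f"planted occupancy {q} for pair {pair} not in [0, 1]")

    @property
    def is_holo(self) -> bool:
        return self.condition == "holo"


def apo_spec(**overrides) -> SyntheticSpec:
    """The default apo-like condition (broad, mean elevation 23°)."""
    return SyntheticSpec(condition="apo", **overrides)


def holo_spec(**overrides) -> SyntheticSpec:
    """The default holo-like condition (narrow, mean elevation 33°)."""
    defaults = dict(
        condition="holo",
        elevation_mean=33.0, elevation_sd=2.5,
        azimuth_mean=45.0, azimuth_sd=4.0,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

def _direction(elevation_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector with the given elevation/azimuth in the lab (= crossbridge)
    frame e1=x, e2=y, e3=z."""
    el, az = np.radians(elevation_deg), np.radians(azimuth_deg)
    return np.array(
        [np.sin(el), np.cos(el) * np.cos(az), np.cos(el) * np.sin(az)]
    )


def _lattice_blob(n: int, spacing: float, center: np.ndarray) -> np.ndarray:
    """First n cubic-lattice points by distance from the center; deterministic."""
    r = int(np.ceil((n * 3) ** (1 / 3))) + 2
    grid = np.array(
        [(i, j, k) for i in range(-r, r + 1) for j in range(-r, r + 1) for k in range(-r, r + 1)],
        dtype=float,
    )
    d2 = (grid ** 2).sum(axis=1)
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], d2))
    return grid[order[:n]] * spacing + center


_BB_OFFSETS = {
    "N": np.array([1.0, 0.4, 0.0]),
    "CA": np.zeros(3),
    "C": np.array([-1.0, 0.4, 0.0]),
    "O": np.array([-1.2, 1.4, 0.0]),
}


@dataclass
class HingedSystem:
    """The synthetic topology plus everything needed to drive it."""

    model: MolecularModel               # myosin + ELC (+ ligand if holo)
    reference_complex: MolecularModel   # actin pentamer + myosin, canonical pose
    hinge: np.ndarray
    base_direction: np.ndarray          # tail direction of the canonical pose
    rigid_indices: np.ndarray           # atoms rotating with the lever arm
    switch_atoms: dict                  # pair -> (mobile atom idx array, near xyz, far xyz)
    saltbridge_atom: int | None         # gated OE1 atom index (residue 500)
    saltbridge_anchor: int | None       # NZ atom index (residue 762)
    ligand_group_atoms: tuple           # (terminal-moiety atom index array,) or ()
    ligand_pose_coords: np.ndarray | None  # (K, n_group_atoms, 3) library coords
    frame: CrossbridgeFrame = None      # crossbridge frame of the reference complex
    hlh_expression: str = "chain A and resid 200-230"
    junction_expression: str = "chain A and resid 704-723"

    def hlh_selection(self, model: MolecularModel | None = None) -> Selection:
        return select(model if model is not None else self.model, self.hlh_expression)


def _add_residue(rows, chain, resid, resname, center, theta=0.0, names=_BB_OFFSETS):
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    for name, off in names.items():
        el = "X" if not name else ("N" if name[0] == "N" else "O" if name[0] == "O" else "C")
        rows.append((chain, resid, resname, name, el, center + rot @ off))


def make_hinged_system(spec: SyntheticSpec) -> HingedSystem:
    """Build the deterministic pseudo-protein and its actin reference.

    Residue numbering is compatible with the field's myosin conventions:
    converter 712-766, tail 769-810 (tail-vector groups 769-771 and 784-787
    carry complete N/CA/C backbones), pseudo-ELC on chain E, switch residues
    300-307, relay segment 492-503.
    """
    rows: list[tuple] = []

    # motor core (rigid body)
    motor_ca = _lattice_blob(151, 5.0, _MOTOR_CENTER)
    for k, center in enumerate(motor_ca):
        _add_residue(rows, "A", 100 + k, "GLY", center, theta=0.7 * k)

    # relay segment 492-503, motor-fixed, near the hinge underside
    for j, resid in enumerate(range(492, 504)):
        center = np.array([50.0 + 1.2 * j, -4.0 + 2.0 * np.cos(1.7 * j), -6.0 + 2.0 * np.sin(1.7 * j)])
        _add_residue(rows, "A", resid, "GLY", center, theta=1.7 * j)

    u0 = _direction(_BASE_ELEVATION, _BASE_AZIMUTH)

    # converter 712-766, rigid with the tail
    for j, resid in enumerate(range(712, 767)):
        center = _HINGE + np.array(
            [-7.0 + 7.0 * j / 54.0, 2.5 * np.cos(1.75 * j), 2.5 * np.sin(1.75 * j)]
        )
        _add_residue(rows, "A", resid, "GLY", center, theta=1.75 * j)

    # tail helix 769-810: backbone (N, CA, C) centroids sit exactly on the axis
    p1 = np.array([0.0, -u0[2], u0[1]])
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(u0, p1)
    for j, resid in enumerate(range(769, 811)):
        axis_pt = _HINGE + (j + 1) * _TAIL_RISE * u0
        th = np.radians(100.0) * j
        off = 1.2 * (np.cos(th) * p1 + np.sin(th) * p2)
        # CA sits on a small helix; N and C compensate so the per-residue
        # backbone (N, CA, C) centroid lies exactly on the tail axis
        w = 0.8 * (np.cos(th + 1.0) * p1 + np.sin(th + 1.0) * p2)
        rows.append(("A", resid, "GLY", "N", "N", axis_pt + off - w / 2))
        rows.append(("A", resid, "GLY", "CA", "C", axis_pt + w))
        rows.append(("A", resid, "GLY", "C", "C", axis_pt - off - w / 2))
        rows.append(("A", resid, "GLY", "O", "O", axis_pt + 1.0 * p2 + 0.5 * u0))

    # pseudo-ELC, rigid with the tail, riding mid-tail
    elc_center = _HINGE + 40.0 * u0 + 9.0 * p1
    for k, center in enumerate(_lattice_blob(40, 5.0, elc_center)):
        _add_residue(rows, "E", 39 + k, "GLY", center, theta=0.9 * k)

    # switch residue pairs on an isolated shelf below the motor
    switch_meta: dict = {}
    n_pairs = len(spec.planted_contacts)
    for k, (pair, _, _) in enumerate(spec.planted_contacts):
        static_id, mobile_id = pair
        base = np.array([45.0, -10.0 * (n_pairs - 1) + 20.0 * k, -45.0])
        _add_residue(rows, "A", static_id, "GLY", base, theta=0.3)
        _add_residue(rows, "A", mobile_id, "GLY", base + np.array([_SWITCH_NEAR, 0, 0]))
        switch_meta[pair] = base

    # salt-bridge side-chain atoms: NZ on converter residue 762 (rotates),
    # OE1 on relay residue 500 (gated per frame)
    rows.append(("A", 762, "GLY", "NZ", "N", _HINGE + np.array([-2.0, 3.5, 0.5])))
    rows.append(("A", 500, "GLY", "OE1", "O", np.array([56.0, -2.0, -5.0])))

    # pseudo-ligand: rigid central ring + two pose-sampled terminal moieties
    lig_groups: tuple = ()
    pose_coords = None
    if spec.is_holo:
        lig_center = np.array([45.0, 0.0, 20.0])
        ring = []
        for m in range(6):
            th = np.pi / 3 * m
            ring.append(lig_center + 1.4 * np.array([np.cos(th), np.sin(th), 0.0]))
            rows.append(("L", 900, "OMC", f"C{m+1}", "C", ring[-1]))
        rows.append(("L", 900, "OMC", "F1", "F", lig_center + np.array([0.0, 0.0, 1.3])))

        def _terminal(base_atom, axis, phi, names):
            """Branch atoms rotated by phi about the bond axis."""
            perp = np.array([0.0, 0.0, 1.0])
            perp = perp - (perp @ axis) * axis
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(axis, perp)
            c, s = np.cos(phi), np.sin(phi)
            rotp = c * perp + s * perp2
            pts = {
                names[0]: base_atom + 1.4 * axis,
                names[1]: base_atom + 2.6 * axis + 1.2 * rotp,
                names[2]: base_atom + 2.6 * axis - 1.2 * rotp,
            }
            return pts

        axis_a = np.array([1.0, 0.0, 0.0])
        axis_b = np.array([-1.0, 0.0, 0.0])
        ga_names, gb_names = ("C7", "O1", "O2"), ("C8", "N1", "C9")
        lib = []
        for (phi_a, phi_b) in spec.pose_library:
            pts_a = _terminal(ring[0], axis_a, np.radians(phi_a), ga_names)
            pts_b = _terminal(ring[3], axis_b, np.radians(phi_b), gb_names)
            lib.append(np.array(list(pts_a.values()) + list(pts_b.values())))
        pose_coords = np.stack(lib)
        # canonical pose = library entry 0
        for name, xyz in zip(ga_names + gb_names, pose_coords[0]):
            el = "N" if name[0] == "N" else "O" if name[0] == "O" else "C"
            rows.append(("L", 900, "OMC", name, el, xyz))

    chain = np.array([r[0] for r in rows], dtype=object)
    resid = np.array([r[1] for r in rows], dtype=int)
    resname = np.array([r[2] for r in rows], dtype=object)
    name = np.array([r[3] for r in rows], dtype=object)
    element = np.array([r[4] for r in rows], dtype=object)
    coords = np.array([r[5] for r in rows], dtype=float)
    model = MolecularModel(
        chain=chain, resid=resid, icode=np.full(len(rows), "", dtype=object),
        resname=resname, name=name, element=element, coords=coords,
        source=f"synthetic hinged system ({spec.condition})",
    )

    # rigid (lever-arm) group: converter + tail + ELC + NZ(762)
    rigid = np.where(
        ((model.chain == "A") & (model.resid >= 712) & (model.resid <= 810))
        | (model.chain == "E")
    )[0]

    switch_atoms = {}
    for pair, base in switch_meta.items():
        _, mobile_id = pair
        idx = np.where((model.chain == "A") & (model.resid == mobile_id))[0]
        near = coords[idx].copy()
        far = near + np.array([_SWITCH_FAR - _SWITCH_NEAR, 0.0, 0.0])
        switch_atoms[pair] = (idx, near, far)

    sb_gated = int(np.where((model.chain == "A") & (model.name == "OE1"))[0][0])
    sb_anchor = int(np.where((model.chain == "A") & (model.name == "NZ"))[0][0])

    if spec.is_holo:
        group_idx = np.where(np.isin(model.name, ("C7", "O1", "O2", "C8", "N1", "C9")))[0]
        lig_groups = (group_idx,)

    # actin pentamer reference: helical subunit rings along e2 (= y)
    arows: list[tuple] = []
    for su in range(5):
        y = (su - 2) * 27.3
        for m in range(10):
            th = 2 * np.pi * m / 10 - np.radians(166.7) * su
            arows.append(
                ("F", su + 1, "ACT", f"A{m}", "C",
                 np.array([8.0 * np.cos(th), y, 8.0 * np.sin(th)]))
            )
    ref_rows = arows + rows
    reference = MolecularModel(
        chain=np.array([r[0] for r in ref_rows], dtype=object),
        resid=np.array([r[1] for r in ref_rows], dtype=int),
        icode=np.full(len(ref_rows), "", dtype=object),
        resname=np.array([r[2] for r in ref_rows], dtype=object),
        name=np.array([r[3] for r in ref_rows], dtype=object),
        element=np.array([r[4] for r in ref_rows], dtype=object),
        coords=np.array([r[5] for r in ref_rows], dtype=float),
        source="synthetic actomyosin reference complex",
    )
    # the crossbridge frame the generator plants angles in is the same one
    # the measurement pipeline will compute from this reference complex, so
    # zero-noise round trips are exact
    frame = build_crossbridge_frame(
        reference,
        select(reference, "chain F"),
        select(reference, "chain A and resid 712-766"),
    )
    return HingedSystem(
        model=model,
        reference_complex=reference,
        frame=frame,
        hinge=_HINGE.copy(),
        base_direction=u0,
        rigid_indices=rigid,
        switch_atoms=switch_atoms,
        saltbridge_atom=sb_gated,
        saltbridge_anchor=sb_anchor,
        ligand_group_atoms=lig_groups,
        ligand_pose_coords=pose_coords,
    )


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class Truth:
    """Planted ground truth for one simulated condition."""

    spec: SyntheticSpec
    elevation: dict[str, np.ndarray] = field(default_factory=dict)   # per replicate
    azimuth: dict[str, np.ndarray] = field(default_factory=dict)
    tilt: dict[str, np.ndarray] = field(default_factory=dict)        # derived
    contact_state: dict[str, dict] = field(default_factory=dict)     # rep -> pair -> bool array
    pose_labels: dict[str, np.ndarray] = field(default_factory=dict)
    saltbridge_state: dict[str, np.ndarray] = field(default_factory=dict)

    def differential_pairs(self) -> list[tuple[int, int]]:
        """Planted pairs whose apo/holo occupancies genuinely differ."""
        return [
            pair for (pair, qa, qh) in self.spec.planted_contacts if qa != qh
        ]

    def inflated_ranges(self) -> list[tuple[int, int, float]]:
        return list(self.spec.rmsf_inflation)


def _minimal_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u to unit vector v about u×v."""
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.clip(u @ v, -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        perp = perp - (perp @ u) * u
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ u) * u
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    return Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()


def _derived_tilt(elevation: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
    el, az = np.radians(elevation), np.radians(azimuth)
    return np.degrees(np.arccos(np.clip(np.cos(el) * np.sin(az), -1.0, 1.0)))


def _sample_angles(rng, mean, sd, n, rho) -> np.ndarray:
    if rho == 0.0:
        return mean + sd * rng.standard_normal(n)
    out = np.empty(n)
    out[0] = mean + sd * rng.standard_normal()
    innov = sd * np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    for t in range(1, n):
        out[t] = mean + rho * (out[t - 1] - mean) + innov[t]
    return out


def simulate_trajectories(
    spec: SyntheticSpec, system: HingedSystem | None = None
) -> tuple[list[Trajectory], Truth]:
    """Generate one trajectory per replicate plus the planted truth record.

    Per frame: sample (elevation, azimuth) from the condition's Gaussians
    (optionally AR(1)-correlated), rigid-rotate the lever-arm group about the
    hinge so the tail vector realizes those angles exactly in the crossbridge
    frame, gate switch residues by Bernoulli draws at the planted
    occupancies, gate the salt bridge on the sampled elevation, draw a ligand
    pose from the mixture, add isotropic thermal noise, then (optionally)
    apply a random global rigid motion that downstream superposition must
    remove.  All randomness derives from ``spec.seed``.
    """
    if system is None:
        system = make_hinged_system(spec)
    base = system.model.coords
    truth_rec = Truth(spec=spec)
    trajs: list[Trajectory] = []
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(children[r])
        label = str(r + 1)
        n, n_atoms = spec.n_frames, base.shape[0]
        elev = _sample_angles(rng, spec.elevation_mean, spec.elevation_sd, n, spec.ar1_rho)
        azim = _sample_angles(rng, spec.azimuth_mean, spec.azimuth_sd, n, spec.ar1_rho)
        frames = np.empty((n, n_atoms, 3))
        contact_states = {
            pair: rng.random(n) < (qh if spec.is_holo else qa)
            for (pair, qa, qh) in spec.planted_contacts
        }
        if system.ligand_pose_coords is not None:
            labels = rng.choice(
                len(spec.pose_weights), size=n, p=np.asarray(spec.pose_weights)
            )
        else:
            labels = np.full(n, -1)
        sb_state = np.zeros(n, dtype=bool)

        inflate_mask = np.zeros(n_atoms, dtype=bool)
        inflate_sigma = np.zeros(n_atoms)
        if not spec.is_holo:
            for lo, hi, extra in spec.rmsf_inflation:
                m = (system.model.chain == "A") & (system.model.resid >= lo) & (system.model.resid <= hi)
                inflate_mask |= m
                inflate_sigma[m] = extra

        fr = system.frame
        for t in range(n):
            coords = base.copy()
            el_r, az_r = np.radians(elev[t]), np.radians(azim[t])
            d = (
                np.sin(el_r) * fr.e1
                + np.cos(el_r) * (np.cos(az_r) * fr.e2 + np.sin(az_r) * fr.e3)
            )
            rot = _minimal_rotation(system.base_direction, d)
            rigid = system.rigid_indices
            coords[rigid] = (coords[rigid] - system.hinge) @ rot.T + system.hinge
            # planted contacts: park the mobile residue near or far
            for pair, states in contact_states.items():
                idx, near, far = system.switch_atoms[pair]
                coords[idx] = near if states[t] else far
            # elevation-gated salt bridge
            if spec.saltbridge_break_elevation is not None:
                nz = coords[system.saltbridge_anchor]
                present = elev[t] < spec.saltbridge_break_elevation
                sb_state[t] = present
                offset = _SWITCH_NEAR if present else _SWITCH_FAR
                coords[system.saltbridge_atom] = nz + np.array([0.0, offset, 0.0])
            # ligand pose mixture
            if labels[t] >= 0:
                (group_idx,) = system.ligand_group_atoms
                pose = system.ligand_pose_coords[labels[t]]
                jitter = spec.pose_jitter * rng.standard_normal(pose.shape)
                coords[group_idx] = pose + jitter
            if spec.noise_sigma > 0:
                coords += spec.noise_sigma * rng.standard_normal((n_atoms, 3))
                if inflate_mask.any():
                    coords[inflate_mask] += (
                        inflate_sigma[inflate_mask, None]
                        * rng.standard_normal((int(inflate_mask.sum()), 3))
                    )
            if spec.global_motion:
                q = rng.standard_normal(4)
                gr = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
                gt = rng.uniform(-20.0, 20.0, size=3)
                coords = coords @ gr.T + gt
            frames[t] = coords

        trajs.append(
            Trajectory(
                topology=system.model, frames=frames, timestep=spec.timestep,
                replicate=label, condition=spec.condition,
            )
        )
        truth_rec.elevation[label] = elev
        truth_rec.azimuth[label] = azim
        truth_rec.tilt[label] = _derived_tilt(elev, azim)
        truth_rec.contact_state[label] = contact_states
        truth_rec.pose_labels[label] = labels
        truth_rec.saltbridge_state[label] = sb_state
    return trajs, truth_rec


def truth(spec: SyntheticSpec, outputs: tuple[list[Trajectory], Truth]) -> Truth:
    """Return the truth record for generator outputs, validating the match."""
    trajs, rec = outputs
    if rec.spec is not spec and rec.spec != spec:
        raise ValueError("truth record does not belong to this spec")
    if len(trajs) != spec.n_replicates:
        raise ValueError("output replicate count does not match spec")
    for traj in trajs:
        if traj.n_frames != spec.n_frames or traj.condition != spec.condition:
            raise ValueError("trajectory does not match spec")
    return rec


def simulate_contact_tables(
    occupancies: list[tuple[tuple[int, int], float, float]],
    n_frames: int,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Occupancy-level generator: replicate contact tables without coordinates.

    Each pair's per-replicate occupancy is Binomial(n_frames, q)/n_frames —
    the sampling noise a frame-counted contact would show.  Returns
    (apo tables, holo tables) shaped like ``residue_contact_tables`` output;
    used for large-scale statistical calibration of the differential test.
    """
    rng = np.random.default_rng(seed)
    apo, holo = [], []
    for rep in range(n_replicates):
        for cond, store in (("apo", apo), ("holo", holo)):
            rows = []
            for (i, j), qa, qh in occupancies:
                q = qa if cond == "apo" else qh
                occ = rng.binomial(n_frames, q) / n_frames
                rows.append(
                    {
                        "chain_i": "A", "resid_i": min(i, j),
                        "chain_j": "A", "resid_j": max(i, j),
                        "occupancy": occ, "frames": n_frames,
                    }
                )
            tab = pd.DataFrame(rows)
            tab["replicate"] = str(rep + 1)
            tab["condition"] = cond
            store.append(tab)
    return apo, holo
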