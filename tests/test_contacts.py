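"""Contact detection, occupancancy tables, differentials, salt bridges."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from myolever.contacts import (
    differential_contacts,
    frame_contacts,
    ligand_occupancy,
    residue_contact_tables,
    saltbridge_series,
    xray_ligand_contacts,
)
from myolever.model_io import Selection, Trajectory, select
from myolever.synthetic import simulate_contact_tables

from conftest import brute_force_contacts, make_model


def two_residue_model(separation):
    coords = np.array([[0.0, 0, 0], [separation, 0.0, 0.0]])
    return make_model(coords, resid=[1, 2], name=["CA", "CA"], element=["C", "C"])


class TestFrameContacts:
    @pytest.mark.parametrize("sep, expected", [(4.99, 1), (5.0, 1), (5.01, 0)])
    def test_cutoff_boundary_inclusive(self, sep, expected):
        model = two_residue_model(sep)
        out = frame_contacts(model.coords, model,
                             Selection([0]), Selection([1]))
        assert len(out) == expected

    def test_grid_equals_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = 200
            coords = rng.uniform(0, 40, size=(n, 3))
            resid = rng.integers(1, 40, size=n)
            model = make_model(coords, resid=resid,
                               name=[f"X{i}" for i in range(n)],
                               element=["C"] * n)
            sel = Selection(np.arange(n))
            got = frame_contacts(coords, model, sel, sel)
            keys = [("A", int(r)) for r in resid]
            expected = brute_force_contacts(coords, keys, 5.0)
            assert got == expected

    def test_empty_group_rejected(self):
        model = two_residue_model(3.0)
        with pytest.raises(ValueError):
            frame_contacts(model.coords, model, Selection([]), Selection([1]))


class TestResidueContactTables:
    def _traj(self, frames, resid, timestep=100.0):
        top = make_model(frames[0], resid=resid,
                         name=[f"X{i}" for i in range(frames.shape[1])],
                         element=["C"] * frames.shape[1])
        return Trajectory(topology=top, frames=frames, timestep=timestep)

    def test_permanent_contact_full_occupancy(self):
        frames = np.repeat(np.array([[[0.0, 0, 0], [3.0, 0, 0]]]), 4, axis=0)
        tab = residue_contact_tables(self._traj(frames, [1, 2]))
        assert len(tab) == 1
        assert tab.occupancy.iloc[0] == 1.0

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 20, size=(30, 3))
        resid = rng.integers(1, 10, size=30)
        frames = np.stack([coords, coords @ Rotation.from_euler("y", 77, degrees=True).as_matrix().T])
        tab = residue_contact_tables(self._traj(frames, resid))
        assert set(tab.occupancy) == {1.0}  # every pair present in both frames

    def test_pair_set_matches_brute_force(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 30, size=(60, 3))
        resid = np.repeat(np.arange(1, 21), 3)
        frames = coords[None]
        tab = residue_contact_tables(self._traj(frames, resid))
        got = {(r.resid_i, r.resid_j) for r in tab.itertuples()}
        keys = [("A", int(r)) for r in resid]
        expected = {(a[1], b[1]) for a, b in brute_force_contacts(coords, keys, 5.0)}
        assert got == expected

    def test_oversized_stride_rejected(self):
        frames = np.repeat(np.array([[[0.0, 0, 0], [3.0, 0, 0]]]), 4, axis=0)
        with pytest.raises(ValueError, match="stride"):
            residue_contact_tables(self._traj(frames, [1, 2]), stride_ps=10_000.0)


class TestLigandOccupancy:
    def _ligand_system(self, n_frames, contact_fraction, seed=0):
        """Ligand at origin; residue 2 toggles inside/outside the cutoff."""
        rng = np.random.default_rng(seed)
        base = np.array([
            [0.0, 0.0, 0.0],     # ligand atom (chain L)
            [4.0, 0.0, 0.0],     # residue 1, always in contact
            [20.0, 0.0, 0.0],    # residue 2, toggling
        ])
        frames = np.repeat(base[None], n_frames, axis=0)
        in_contact = np.zeros(n_frames, dtype=bool)
        k = int(round(contact_fraction * n_frames))
        in_contact[:k] = True
        frames[in_contact, 2, 0] = 4.5
        top = make_model(base, resid=[900, 1, 2], chain=["L", "A", "A"],
                         name=["C1", "CA", "CA"], element=["C", "C", "C"])
        return Trajectory(topology=top, frames=frames, condition="holo"), in_contact

    def test_exact_occupancy_counting(self):
        traj, _ = self._ligand_system(50, 0.40)
        occ = ligand_occupancy([traj], select(traj.topology, "chain L"))
        table = occ.average.reset_index()
        assert float(table.loc[table.resid == 2, "occupancy"].iloc[0]) == 0.40

    def test_low_occupancy_excluded(self):
        traj, _ = self._ligand_system(100, 0.04)
        occ = ligand_occupancy([traj], select(traj.topology, "chain L"))
        kept = set(occ.average.reset_index().resid)
        assert 2 not in kept and 1 in kept
        assert 2 in set(occ.excluded.reset_index().resid)

    def test_single_pose_reference_counts(self):
        traj, _ = self._ligand_system(1, 1.0)
        ref_set = xray_ligand_contacts(
            traj.topology.with_coords(traj.frames[0]),
            select(traj.topology, "chain L"),
        )
        assert ref_set == {("A", 1), ("A", 2)}

    def test_novel_contacts_vs_reference(self):
        traj, _ = self._ligand_system(60, 0.5)
        ref = traj.topology  # base coordinates: residue 2 out of contact
        occ = ligand_occupancy([traj], select(traj.topology, "chain L"),
                               xray_reference=ref,
                               xray_ligand=select(ref, "chain L"))
        assert occ.novel == [("A", 2)]


class TestDifferentialContacts:
    def _table(self, occupancies, condition, rep):
        rows = [
            {"chain_i": "A", "resid_i": i, "chain_j": "A", "resid_j": j,
             "occupancy": occ, "frames": 100}
            for (i, j), occ in occupancies.items()
        ]
        tab = pd.DataFrame(rows)
        tab["replicate"], tab["condition"] = rep, condition
        return tab

    def test_full_flip_flagged_apo_dominant(self):
        apo = [self._table({(1, 2): 1.0}, "apo", r) for r in "123"]
        holo = [self._table({}, "holo", r) for r in "123"]
        out = differential_contacts(apo, holo)
        assert len(out) == 1
        assert out.iloc[0].dominant == "apo"
        assert out.iloc[0].delta == pytest.approx(1.0)

    def test_identical_occupancies_not_flagged(self):
        tabs = [self._table({(1, 2): 0.7, (3, 4): 0.2}, "apo", r) for r in "123"]
        out = differential_contacts(tabs, [t.assign(condition="holo") for t in tabs])
        assert len(out) == 0

    def test_threshold_nesting(self):
        apo, holo = simulate_contact_tables(
            [((10 + 2 * k, 11 + 2 * k), 0.5 + 0.4 * np.sin(k), 0.5) for k in range(30)],
            n_frames=200, seed=5,
        )
        sets = {}
        for thr in (0.05, 0.10, 0.20):
            out = differential_contacts(apo, holo, delta_threshold=thr)
            sets[thr] = {(r.resid_i, r.resid_j) for r in out.itertuples()}
        assert sets[0.20] <= sets[0.10] <= sets[0.05]

    def test_planted_recovery_and_type_i_rate(self):
        planted = [((100 + 2 * k, 101 + 2 * k), 0.75, 0.25) for k in range(20)]
        nulls = [((500 + 2 * k, 501 + 2 * k), 0.5, 0.5) for k in range(1000)]
        apo, holo = simulate_contact_tables(planted + nulls, n_frames=100, seed=7)
        out = differential_contacts(apo, holo, alpha=0.05, delta_threshold=0.10)
        got = {(r.resid_i, r.resid_j) for r in out.itertuples()}
        for (pair, _, _) in planted:
            assert pair in got
        null_out = differential_contacts(apo, holo, alpha=0.05, delta_threshold=0.0)
        null_hits = {(r.resid_i, r.resid_j) for r in null_out.itertuples()}
        false_rate = len([p for (p, _, _) in nulls if p in null_hits]) / len(nulls)
        assert abs(false_rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / len(nulls))


class TestSaltBridge:
    def _system(self, elevations, threshold=40.0):
        base = np.array([
            [0.0, 0.0, 0.0],   # NZ of residue 10
            [3.0, 0.0, 0.0],   # OE1 of residue 20 (position toggled)
        ])
        frames = np.repeat(base[None], len(elevations), axis=0)
        broken = np.asarray(elevations) <= threshold
        frames[broken, 1, 0] = 9.0
        top = make_model(base, resid=[10, 20], name=["NZ", "OE1"],
                         element=["N", "O"])
        traj = Trajectory(topology=top, frames=frames)
        angles = pd.DataFrame({"elevation": elevations})
        return traj, angles

    def test_stratified_occupancy_by_construction(self):
        elevations = [20.0, 25.0, 45.0, 50.0]
        traj, angles = self._system(elevations, threshold=40.0)
        out = saltbridge_series(traj, [(("A", 10), ("A", 20))], angles,
                                elevation_edges=(30.0, 40.0))
        occ = out.set_index("stratum")["occupancy"]
        assert occ["low"] == 0.0
        assert occ["high"] == 1.0

    def test_strata_recombine_to_global_occupancy(self):
        rng = np.random.default_rng(8)
        elevations = rng.uniform(0, 60, size=50)
        traj, angles = self._system(elevations, threshold=35.0)
        out = saltbridge_series(traj, [(("A", 10), ("A", 20))], angles,
                                elevation_edges=(20.0, 40.0))
        out = out.set_index("stratum")
        weighted = sum(
            out.loc[s, "occupancy"] * out.loc[s, "n_frames"]
            for s in ("low", "average", "high") if out.loc[s, "n_frames"] > 0
        ) / traj.n_frames
        assert weighted == pytest.approx(out.loc["all", "occupancy"])

    def test_unknown_residue_rejected(self):
        traj, angles = self._system([10.0, 50.0])
        with pytest.raises(ValueError, match="side-chain"):
            saltbridge_series(traj, [(("A", 10), ("A", 99))], angles)
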