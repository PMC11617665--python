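"""Superposition, RMSD/RMSF, contact occupancy, and MM/PBSA aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from repurpose.errors import ParameterError
from repurpose.structural import (
    CoordinateSet,
    EnergyComponentTable,
    Trajectory,
    contact_residues,
    kabsch_superpose,
    mmpbsa_combine,
    read_pdb,
    rmsd,
    rmsd_series,
    rmsf,
    write_pdb,
)
from repurpose.synthetic import (
    EnergyConfig,
    TrajectoryConfig,
    gen_energy_components,
    gen_trajectory,
)

from oracles import quaternion_rmsd_oracle


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def random_points(rng, n=8):
    return rng.normal(size=(n, 3)) * 3.0


class TestKabsch:
    def test_identity_on_equal_sets(self):
        x = random_points(np.random.default_rng(0))
        sup = kabsch_superpose(x, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_exactly(self):
        x = random_points(np.random.default_rng(1))
        rot = rotation_matrix([0, 0, 1], np.pi / 2)
        y = x @ rot.T + np.array([1.0, -2.0, 3.0])
        sup = kabsch_superpose(x, y)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle_on_toy_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = random_points(rng, n=4)
            y = x.copy()
            y[0] += rng.normal(size=3)
            assert kabsch_superpose(x, y).rmsd == pytest.approx(
                quaternion_rmsd_oracle(x, y), abs=1e-6
            )

    def test_never_returns_a_reflection(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = random_points(rng, n=5)
            y = x.copy()
            y[:, 0] *= -1  # mirrored target tempts an improper solution
            y += rng.normal(size=y.shape) * 0.1
            sup = kabsch_superpose(x, y)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_superposition_never_increases_rmsd(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = random_points(rng), random_points(rng)
            assert kabsch_superpose(x, y).rmsd <= rmsd(x, y) + 1e-12

    def test_too_few_atoms_raise(self):
        with pytest.raises(ParameterError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection_warns(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            kabsch_superpose(x, x + 1.0)


class TestRMSD:
    def test_identical_sets_zero(self):
        x = random_points(np.random.default_rng(5))
        assert rmsd(x, x) == 0.0

    def test_single_displaced_atom_definition(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[2.0, 0.0, 0.0]])
        assert rmsd(a, b) == pytest.approx(2.0)

    def test_two_atoms_hand_arithmetic(self):
        a = np.zeros((2, 3))
        b = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        assert rmsd(a, b) == pytest.approx(np.sqrt(5.0))

    def test_mismatched_counts_raise(self):
        with pytest.raises(ParameterError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @settings(deadline=None, max_examples=30)
    @given(
        arrays(float, (5, 3), elements=st.floats(-10, 10)),
        arrays(float, (5, 3), elements=st.floats(-10, 10)),
        arrays(float, (5, 3), elements=st.floats(-10, 10)),
    )
    def test_pseudometric_properties(self, a, b, c):
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        assert rmsd(a, a) == 0.0
        assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-9


class TestTrajectoryStatistics:
    def test_static_trajectory_zero_series_and_rmsf(self):
        traj, ref, _ = gen_trajectory(
            TrajectoryConfig(base_amplitude=0.0, tail_amplitude=0.0, n_frames=10), seed=0
        )
        series = rmsd_series(traj, ref)
        assert max(v for _, v in series) < 1e-10
        assert max(v for _, v in rmsf(traj)) < 1e-10

    def test_translated_frame_gives_zero_after_superposition(self):
        traj, ref, _ = gen_trajectory(
            TrajectoryConfig(base_amplitude=0.0, tail_amplitude=0.0, n_frames=10), seed=0
        )
        traj.coords[3] += np.array([5.0, -1.0, 2.0])
        series = rmsd_series(traj, ref)
        assert series[3][1] == pytest.approx(0.0, abs=1e-10)

    def test_wobble_series_matches_closed_form(self):
        # every residue hops +/-a: per-frame RMSD vs the base structure is
        # sqrt(mean a_i^2) once superposition leakage is kept small
        amps = [0.0] * 47 + [1.0, 1.0, 1.0]
        traj, ref, _ = gen_trajectory(
            TrajectoryConfig(n_residues=50, amplitudes=amps, n_frames=20), seed=1
        )
        core = (traj.template.res_ids <= 47) & traj.template.backbone_mask()
        series = rmsd_series(traj, ref)
        expected = np.sqrt(np.mean(np.array(amps) ** 2))
        assert np.mean([v for _, v in series]) == pytest.approx(expected, rel=0.05)

    def test_rmsf_recovers_planted_amplitude_with_core_alignment(self):
        amps = [0.0] * 20
        amps[9] = 1.25
        traj, _, _ = gen_trajectory(
            TrajectoryConfig(n_residues=20, amplitudes=amps), seed=2
        )
        core = (traj.template.res_ids != 10) & traj.template.backbone_mask()
        values = dict(rmsf(traj, align_selection=core))
        assert values[10] == pytest.approx(1.25, rel=1e-9)
        assert values[1] == pytest.approx(0.0, abs=1e-9)

    def test_rmsf_invariant_under_global_rigid_motion(self):
        traj, _, truth = gen_trajectory(TrajectoryConfig(n_frames=20), seed=3)
        base = dict(rmsf(traj))
        rot = rotation_matrix([1, 1, 0], 0.7)
        moved = Trajectory(
            traj.coords @ rot.T + np.array([3.0, 4.0, -1.0]), traj.template
        )
        for rid, value in rmsf(moved):
            assert value == pytest.approx(base[rid], abs=1e-8)

    def test_rigid_rotating_trajectory_rmsf_zero(self):
        traj, _, _ = gen_trajectory(
            TrajectoryConfig(base_amplitude=0.0, tail_amplitude=0.0, n_frames=10), seed=0
        )
        for f in range(traj.n_frames):
            rot = rotation_matrix([0, 1, 0], 0.1 * f)
            traj.coords[f] = traj.coords[f] @ rot.T + f * np.array([0.5, 0.0, 0.0])
        assert max(v for _, v in rmsf(traj)) < 1e-8

    def test_single_frame_rmsf_raises(self):
        traj, _, _ = gen_trajectory(TrajectoryConfig(n_frames=2), seed=0)
        single = Trajectory(traj.coords[:1], traj.template)
        with pytest.raises(ParameterError):
            rmsf(single)


class TestContacts:
    def _lig_traj(self, contact_frames, n_frames=100):
        traj, _, truth = gen_trajectory(
            TrajectoryConfig(
                include_ligand=True,
                ligand_contact_frames=contact_frames,
                n_frames=n_frames,
            ),
            seed=0,
        )
        return traj, truth

    def test_persistent_contact_full_occupancy(self):
        traj, truth = self._lig_traj(100)
        occ = contact_residues(traj, traj.template.mask_by_residue_name(["LIG"]))
        assert occ == {truth["contact_residue"]: 1.0}

    def test_no_contact_empty_map(self):
        traj, _ = self._lig_traj(0)
        occ = contact_residues(traj, traj.template.mask_by_residue_name(["LIG"]))
        assert occ == {}

    def test_partial_occupancy_is_exact(self):
        traj, truth = self._lig_traj(25)
        occ = contact_residues(traj, traj.template.mask_by_residue_name(["LIG"]))
        assert occ == {truth["contact_residue"]: 0.25}

    def test_frame_window_restriction(self):
        traj, truth = self._lig_traj(25)
        lig = traj.template.mask_by_residue_name(["LIG"])
        early = contact_residues(traj, lig, frame_range=(0, 25))
        late = contact_residues(traj, lig, frame_range=(25, 100))
        assert early == {truth["contact_residue"]: 1.0}
        assert late == {}

    def test_empty_selection_raises(self):
        traj, _ = self._lig_traj(10)
        with pytest.raises(ParameterError):
            contact_residues(traj, np.zeros(len(traj.template), dtype=bool))


class TestPDBRoundTrip:
    def test_trajectory_survives_write_and_read(self, tmp_path):
        traj, _, _ = gen_trajectory(
            TrajectoryConfig(n_frames=4, include_ligand=True, ligand_contact_frames=2),
            seed=0,
        )
        path = tmp_path / "traj.pdb"
        write_pdb(path, traj)
        back = read_pdb(path)
        assert back.n_frames == 4
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)
        assert list(back.template.atom_names) == list(traj.template.atom_names)
        assert list(back.template.res_ids) == list(traj.template.res_ids)


def _energy_table(deltas, n_frames=3, minus_tds=None):
    rows = []
    base = {"receptor": 100.0, "ligand": 10.0}
    for f in range(n_frames):
        for system in ("complex", "receptor", "ligand"):
            row = {"frame": f, "system": system}
            for comp, delta in deltas.items():
                if system == "complex":
                    row[comp] = base["receptor"] + base["ligand"] + delta
                else:
                    row[comp] = base[system]
            if minus_tds is not None and system == "complex":
                row["minus_TdS"] = minus_tds
            rows.append(row)
    return EnergyComponentTable(pd.DataFrame(rows))


DELTAS = {"E_internal": 0.0, "E_elec": -20.0, "E_vdw": -30.0, "G_PB": 15.0, "G_SA": -5.0}


class TestMMPBSA:
    def test_direct_arithmetic_with_entropy(self):
        summary = mmpbsa_combine(_energy_table(DELTAS, minus_tds=10.0))
        assert summary.entropy_included
        assert summary.dg_bind == pytest.approx(-30.0)
        assert summary.dg_bind_sd == pytest.approx(0.0, abs=1e-10)
        assert summary.components["dE_MM"][0] == pytest.approx(-50.0)
        assert summary.components["dG_solv"][0] == pytest.approx(10.0)

    def test_enthalpy_only_flagged_without_entropy(self):
        summary = mmpbsa_combine(_energy_table(DELTAS))
        assert not summary.entropy_included
        assert summary.dg_bind == pytest.approx(-40.0)

    def test_scalar_entropy_argument(self):
        summary = mmpbsa_combine(_energy_table(DELTAS), minus_TdS=10.0)
        assert summary.dg_bind == pytest.approx(-30.0)

    def test_gaussian_table_matches_per_frame_oracle(self):
        table, _ = gen_energy_components(EnergyConfig(n_frames=100), seed=7)
        summary = mmpbsa_combine(table)
        df = table.frame.pivot(index="frame", columns="system")
        per_frame = np.zeros(100)
        for comp in ("E_internal", "E_elec", "E_vdw", "G_PB", "G_SA"):
            per_frame += (
                df[(comp, "complex")] - df[(comp, "receptor")] - df[(comp, "ligand")]
            ).to_numpy()
        assert summary.dg_bind == pytest.approx(per_frame.mean(), rel=1e-12)
        assert summary.dg_bind_sd == pytest.approx(per_frame.std(), rel=1e-12)

    def test_linearity_and_frame_permutation_invariance(self):
        table, _ = gen_energy_components(EnergyConfig(n_frames=50), seed=8)
        summary = mmpbsa_combine(table)
        scaled = EnergyComponentTable(
            table.frame.assign(
                **{
                    c: table.frame[c] * 2.0
                    for c in ("E_internal", "E_elec", "E_vdw", "G_PB", "G_SA")
                }
            )
        )
        assert mmpbsa_combine(scaled).dg_bind == pytest.approx(2 * summary.dg_bind)
        permuted = EnergyComponentTable(
            table.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        assert mmpbsa_combine(permuted).dg_bind == pytest.approx(summary.dg_bind)

    def test_missing_triple_raises(self):
        broken = _energy_table(DELTAS).frame
        broken = broken[~((broken["frame"] == 1) & (broken["system"] == "ligand"))]
        with pytest.raises(ParameterError):
            mmpbsa_combine(EnergyComponentTable(broken))
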