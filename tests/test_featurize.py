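"""Alignment, RMSD/RMSF, hydration and respawn-selection operations."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

import lipidmsm as lm
from lipidmsm.featurize import PointSet, Trajectory, reimage_frame, rmsd


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def random_pointset(rng, n, prefix="atom"):
    return PointSet(
        labels=[f"{prefix}{i}/X" for i in range(n)],
        coords=rng.uniform(-10, 10, (n, 3)),
    )


class TestKabsch:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        ps = random_pointset(rng, 10)
        sup = lm.kabsch_superpose(ps, ps, ps.labels)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(sup.translation, 0, atol=1e-12)
        assert sup.rmsd_after == pytest.approx(0, abs=1e-12)

    def test_recovers_known_rigid_transform(self):
        rng = np.random.default_rng(1)
        ps = random_pointset(rng, 12)
        R = rotation_matrix([1, 2, 3], np.deg2rad(30))
        t = np.array([4.0, -2.0, 7.0])
        moved = PointSet(labels=ps.labels, coords=ps.coords @ R.T + t)
        sup = lm.kabsch_superpose(ps, moved, ps.labels)
        assert np.allclose(sup.rotation, R, atol=1e-6)
        assert np.allclose(sup.translation, t, atol=1e-6)
        assert sup.rmsd_after < 1e-6

    def test_noise_floor_reached(self):
        rng = np.random.default_rng(2)
        ps = random_pointset(rng, 200)
        sigma = 0.3
        noisy = PointSet(
            labels=ps.labels, coords=ps.coords + sigma * rng.standard_normal((200, 3))
        )
        raw = rmsd(ps.coords, noisy.coords)
        sup = lm.kabsch_superpose(ps, noisy, ps.labels)
        fitted = rmsd(sup.apply(ps.coords), noisy.coords)
        assert fitted <= raw
        assert fitted == pytest.approx(sigma * np.sqrt(3), rel=0.15)

    def test_degenerate_selection_rejected(self):
        line = PointSet(
            labels=["a/X", "b/X", "c/X"],
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),
        )
        with pytest.raises(ValueError, match="degenerate|collinear"):
            lm.kabsch_superpose(line, line, line.labels)
        with pytest.raises(ValueError, match="3 atoms"):
            lm.kabsch_superpose(line, line, ["a/X", "b/X"])


def _marker_trajectory_setup(rng, n_frames=3, n_ligands=2):
    receptor = [(f"REC{i}/CA", rng.uniform(-5, 5, 3)) for i in range(6)]
    markers = {
        f"lig{k}": rng.uniform(-15, 15, (n_frames, 3)) for k in range(n_ligands)
    }
    labels = [lab for lab, _ in receptor] + [f"lig{k}/P" for k in range(n_ligands)]
    coords = np.empty((n_frames, len(labels), 3))
    for f in range(n_frames):
        coords[f, : len(receptor)] = [xyz for _, xyz in receptor]
        for k in range(n_ligands):
            coords[f, len(receptor) + k] = markers[f"lig{k}"][f]
    traj = Trajectory(labels=labels, coords=coords, times=np.arange(n_frames) * 10.0)
    reference = traj.frame(0)
    return traj, reference, markers, [lab for lab, _ in receptor]


class TestMarkerExtraction:
    def test_static_receptor_markers_unchanged(self):
        rng = np.random.default_rng(3)
        traj, ref, markers, align = _marker_trajectory_setup(rng)
        out = lm.extract_marker_trajectories(traj, "P", ["lig0", "lig1"], align, ref)
        assert [t.ligand_id for t in out] == ["lig0", "lig1"]
        for t in out:
            assert np.allclose(t.positions, markers[t.ligand_id], atol=1e-10)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(4)
        traj, ref, markers, align = _marker_trajectory_setup(rng)
        moved = traj.coords.copy()
        for f in range(traj.n_frames):
            R = rotation_matrix(rng.uniform(-1, 1, 3), rng.uniform(0, np.pi))
            moved[f] = traj.coords[f] @ R.T + rng.uniform(-20, 20, 3)
        shaken = Trajectory(labels=traj.labels, coords=moved, times=traj.times)
        out = lm.extract_marker_trajectories(shaken, "P", ["lig0", "lig1"], align, ref)
        for t in out:
            assert np.allclose(t.positions, markers[t.ligand_id], atol=1e-6)

    def test_permutation_stability(self):
        rng = np.random.default_rng(5)
        traj, ref, _, align = _marker_trajectory_setup(rng, n_ligands=3)
        fwd = lm.extract_marker_trajectories(
            traj, "P", ["lig0", "lig1", "lig2"], align, ref
        )
        rev = lm.extract_marker_trajectories(
            traj, "P", ["lig2", "lig1", "lig0"], align, ref
        )
        for a, b in zip(fwd, reversed(rev)):
            assert a.ligand_id == b.ligand_id
            assert np.array_equal(a.positions, b.positions)

    def test_nineteen_ligands_give_nineteen_trajectories(self):
        rng = np.random.default_rng(6)
        traj, ref, _, align = _marker_trajectory_setup(rng, n_ligands=19)
        ids = [f"lig{k}" for k in range(19)]
        out = lm.extract_marker_trajectories(traj, "P", ids, align, ref)
        assert len(out) == 19

    def test_missing_marker_names_ligand(self):
        rng = np.random.default_rng(7)
        traj, ref, _, align = _marker_trajectory_setup(rng)
        with pytest.raises(KeyError, match="lig9"):
            lm.extract_marker_trajectories(traj, "P", ["lig9"], align, ref)


class TestLigandRmsd:
    def _complex(self, rng, n_frames=4):
        labels = [f"REC{i}/CA" for i in range(5)] + ["lig/C1", "lig/C2", "lig/P"]
        base = rng.uniform(-8, 8, (len(labels), 3))
        coords = np.tile(base, (n_frames, 1, 1))
        return labels, coords

    def test_zero_on_reference_frame(self):
        rng = np.random.default_rng(8)
        labels, coords = self._complex(rng)
        traj = Trajectory(labels=labels, coords=coords, times=np.arange(4.0) + 1)
        ref = traj.frame(0)
        series = lm.ligand_rmsd_to_reference(
            traj, ["lig/C1", "lig/C2", "lig/P"], ref, [l for l in labels if "REC" in l]
        )
        assert np.allclose(series.values, 0, atol=1e-10)

    def test_rigid_offset_gives_offset(self):
        rng = np.random.default_rng(9)
        labels, coords = self._complex(rng, n_frames=2)
        lig_idx = [i for i, l in enumerate(labels) if l.startswith("lig/")]
        coords[1, lig_idx, 0] += 5.0
        traj = Trajectory(labels=labels, coords=coords, times=np.array([0.0, 1.0]))
        series = lm.ligand_rmsd_to_reference(
            traj,
            [labels[i] for i in lig_idx],
            traj.frame(0),
            [l for l in labels if "REC" in l],
        )
        assert series.values[0] == pytest.approx(0, abs=1e-10)
        assert series.values[1] == pytest.approx(5.0, abs=1e-8)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(10)
        labels, coords = self._complex(rng, n_frames=3)
        coords += 0.1 * rng.standard_normal(coords.shape)
        traj = Trajectory(labels=labels, coords=coords, times=np.arange(3.0) + 1)
        ref = traj.frame(0)
        lig = [l for l in labels if l.startswith("lig/")]
        rec = [l for l in labels if "REC" in l]
        series = lm.ligand_rmsd_to_reference(traj, lig, ref, rec)
        for f in range(3):
            sup = lm.kabsch_superpose(traj.frame(f), ref, rec)
            moved = sup.apply(traj.coords[f])
            idx = traj.indices(lig)
            expected = np.sqrt(
                np.sum((moved[idx] - ref.coords[ref.indices(lig)]) ** 2) / len(lig)
            )
            assert series.values[f] == pytest.approx(expected, abs=1e-10)


class TestResidueRmsf:
    def _protein_traj(self, displacement, n_frames=8):
        """Three one-atom residues; residue B oscillates +-d along x."""
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [10, 10, 0.0]])
        labels = ["A1/CA", "B2/CA", "C3/CA", "D4/CA"]
        coords = np.tile(base, (n_frames, 1, 1))
        signs = np.resize([1.0, -1.0], n_frames)
        coords[:, 1, 0] += displacement * signs
        return Trajectory(labels=labels, coords=coords, times=np.arange(n_frames, dtype=float))

    def test_static_trajectory_zero(self):
        traj = self._protein_traj(0.0)
        out = lm.residue_rmsf([traj], align_selection=["A1/CA", "C3/CA", "D4/CA"])
        assert np.allclose(out.to_numpy(), 0, atol=1e-12)

    def test_two_point_oscillation_closed_form(self):
        d = 0.7
        traj = self._protein_traj(d)
        out = lm.residue_rmsf([traj], align_selection=["A1/CA", "C3/CA", "D4/CA"])
        assert out["B2"] == pytest.approx(d, rel=1e-9)
        assert out["A1"] == pytest.approx(0, abs=1e-9)

    def test_group_difference_localizes_inflated_jitter(self):
        rng = np.random.default_rng(11)
        n_res, n_frames = 20, 60
        helix = set(range(8, 15))  # inflated residues
        base = rng.uniform(-10, 10, (n_res, 3))
        labels = [f"R{i}/CA" for i in range(n_res)]

        def make(traj_seed, inflate):
            r = np.random.default_rng(traj_seed)
            coords = np.tile(base, (n_frames, 1, 1))
            for i in range(n_res):
                sig = 0.6 if (inflate and i in helix) else 0.2
                coords[:, i] += sig * r.standard_normal((n_frames, 3))
            return Trajectory(labels=labels, coords=coords, times=np.arange(n_frames, dtype=float))

        bound = [make([1, k], True) for k in range(4)]
        quiet = [make([2, k], False) for k in range(4)]
        ref = PointSet(labels=labels, coords=base)
        diff = lm.rmsf_difference(bound, quiet, reference=ref, align_selection=labels)
        inflated = [f"R{i}" for i in sorted(helix)]
        others = [f"R{i}" for i in range(n_res) if i not in helix]
        assert diff[inflated].min() > 0.15
        assert np.abs(diff[others]).max() < 0.12

    def test_too_few_frames_rejected(self):
        traj = self._protein_traj(0.0, n_frames=1)
        with pytest.raises(ValueError, match="2 frames"):
            lm.residue_rmsf([traj])


class TestHydrationCount:
    def test_strict_boundary(self):
        fixture = lm.make_snapshot_fixture(
            {
                "solute": {"lig/P": (0.0, 0.0, 0.0)},
                "waters": {
                    "w1": [(3.0, 0, 0)],
                    "w2": [(0, 4.9, 0)],
                    "w3": [(0, 0, 5.1)],
                },
            }
        )
        assert lm.hydration_count(fixture, ["lig/P"], cutoff=5.0) == 2

    def test_molecule_counted_once(self):
        fixture = lm.make_snapshot_fixture(
            {
                "solute": {"lig/P": (0.0, 0.0, 0.0)},
                "waters": {"w1": [(4.0, 0, 0), (8.0, 0, 0), (0, 8.0, 0)]},
            }
        )
        assert lm.hydration_count(fixture, ["lig/P"], cutoff=5.0) == 1

    def test_matches_all_pairs_scan(self):
        spec = {
            "solute": {f"s{i}/X": xyz for i, xyz in enumerate(
                np.random.default_rng(12).uniform(-3, 3, (4, 3))
            )},
            "random_waters": {"n": 60, "box": ((-8, -8, -8), (8, 8, 8)), "seed": 13},
        }
        fixture = lm.make_snapshot_fixture(spec)
        solute = np.array(list(fixture.solute_atoms.values()))
        expected = sum(
            1
            for xyz in fixture.water_atoms.values()
            if cdist(np.atleast_2d(xyz), solute).min() < 5.0
        )
        got = lm.hydration_count(fixture, list(fixture.solute_atoms), cutoff=5.0)
        assert got == expected

    def test_monotone_in_cutoff(self):
        fixture = lm.make_snapshot_fixture(
            {
                "solute": {"a/X": (0, 0, 0)},
                "random_waters": {"n": 40, "box": ((-6, -6, -6), (6, 6, 6)), "seed": 14},
            }
        )
        counts = [
            lm.hydration_count(fixture, ["a/X"], cutoff=c)
            for c in (1.0, 2.0, 3.5, 5.0, 8.0)
        ]
        assert counts == sorted(counts)

    def test_empty_selection_rejected(self):
        fixture = lm.make_snapshot_fixture({"solute": {"a/X": (0, 0, 0)}})
        with pytest.raises(ValueError, match="non-empty"):
            lm.hydration_count(fixture, [])


class TestRespawnSelection:
    def _series(self, values):
        return lm.ObservableSeries(
            "ligand_rmsd", "angstrom", np.arange(len(values), dtype=float), values
        )

    def test_never_below_threshold_empty(self):
        out = lm.select_respawn_frames([self._series([8.0, 9.0, 12.0])], 5.0, 3)
        assert out == []

    def test_minimum_selected(self):
        out = lm.select_respawn_frames([self._series([12.0, 4.9, 3.0, 6.0])], 5.0, 1)
        assert len(out) == 1
        assert out[0].frame == 2
        assert out[0].value == pytest.approx(3.0)

    def test_matches_enumeration_and_cap(self):
        rng = np.random.default_rng(15)
        series = [self._series(rng.uniform(0, 10, 30)) for _ in range(5)]
        out = lm.select_respawn_frames(series, 5.0, 3)
        for k, s in enumerate(series):
            mine = [(f.frame, f.value) for f in out if f.trajectory == k]
            qualifying = sorted(
                ((v, t) for t, v in zip(s.times, s.values) if v < 5.0)
            )[:3]
            assert [v for v, _ in qualifying] == pytest.approx(
                [v for _, v in mine]
            )
        # ties broken by earliest time
        tied = self._series([2.0, 1.0, 1.0, 9.0])
        best = lm.select_respawn_frames([tied], 5.0, 1)[0]
        assert best.frame == 1


class TestHelixVsLigand:
    def _system(self, rng, n_frames):
        labels = (
            [f"REC{i}/CA" for i in range(5)]
            + [f"H{i}/CA" for i in range(34, 40)]
            + ["lig/P", "lig/C1", "lig/C2"]
        )
        base = rng.uniform(-8, 8, (len(labels), 3))
        coords = np.tile(base, (n_frames, 1, 1))
        return labels, base, coords

    def test_crystal_frame_is_origin_pair(self):
        rng = np.random.default_rng(16)
        labels, base, coords = self._system(rng, 1)
        traj = Trajectory(labels=labels, coords=coords, times=np.array([0.0]))
        ref = PointSet(labels=labels, coords=base)
        helix = [l for l in labels if l.startswith("H")]
        lig = [l for l in labels if l.startswith("lig")]
        rec = [l for l in labels if l.startswith("REC")]
        h, l = lm.helix_vs_ligand_rmsd(traj, helix, ref, lig, rec)
        assert h.values[0] == pytest.approx(0, abs=1e-10)
        assert l.values[0] == pytest.approx(0, abs=1e-10)

    def test_displaced_helix_only(self):
        rng = np.random.default_rng(17)
        labels, base, coords = self._system(rng, 2)
        h_idx = [i for i, l in enumerate(labels) if l.startswith("H")]
        coords[1, h_idx, 2] += 3.0
        traj = Trajectory(labels=labels, coords=coords, times=np.array([0.0, 1.0]))
        ref = PointSet(labels=labels, coords=base)
        helix = [l for l in labels if l.startswith("H")]
        lig = [l for l in labels if l.startswith("lig")]
        rec = [l for l in labels if l.startswith("REC")]
        h, l = lm.helix_vs_ligand_rmsd(traj, helix, ref, lig, rec)
        assert h.values[1] == pytest.approx(3.0, abs=1e-8)
        assert l.values[1] == pytest.approx(0.0, abs=1e-8)

    def test_anticorrelated_construction(self):
        rng = np.random.default_rng(18)
        labels, base, coords = self._system(rng, 20)
        h_idx = [i for i, l in enumerate(labels) if l.startswith("H")]
        l_idx = [i for i, l in enumerate(labels) if l.startswith("lig")]
        # ligand approaches its reference pose while the helix unfolds
        lig_off = np.linspace(6.0, 0.0, 20)
        helix_off = np.linspace(0.0, 4.0, 20)
        for f in range(20):
            coords[f, l_idx, 0] += lig_off[f]
            coords[f, h_idx, 1] += helix_off[f]
        traj = Trajectory(labels=labels, coords=coords, times=np.arange(20, dtype=float))
        ref = PointSet(labels=labels, coords=base)
        h, l = lm.helix_vs_ligand_rmsd(
            traj,
            [lab for lab in labels if lab.startswith("H")],
            ref,
            [lab for lab in labels if lab.startswith("lig")],
            [lab for lab in labels if lab.startswith("REC")],
        )
        rho = spearmanr(h.values, l.values).statistic
        assert rho < -0.9


class TestObservableExport:
    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        series = lm.ObservableSeries(
            "ligand_rmsd", "angstrom", np.array([0.0, 10.0]), np.array([1.5, 2.5])
        )
        path = tmp_path / "obs.tsv"
        series.write_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["name", "units", "frame", "time_ns", "value"]
        assert np.allclose(back["value"], series.values)


class TestReimaging:
    def test_wrapped_atom_restored(self):
        labels = ["REC1/CA", "REC2/CA", "REC3/CA", "lig/P"]
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [48.0, 0.0, 0.0]])
        frame = PointSet(labels=labels, coords=coords)
        out = reimage_frame(frame, box=(50.0, 50.0, 50.0), anchor_selection=labels[:3])
        assert np.allclose(out.coords[3], [-2.0, 0, 0])
        assert np.allclose(out.coords[:3], coords[:3])
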