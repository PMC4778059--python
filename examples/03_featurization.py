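"""Featurize a toy receptor-ligand trajectory: RMSD, RMSF, hydration, respawns.

Builds a miniature labelled system in memory (no files needed) and runs each
observable the analysis uses: receptor-aligned ligand RMSD to a reference
pose, per-residue RMSF, water counting around a solute, and selection of
low-RMSD frames as respawn seeds for adaptive sampling.
"""

import numpy as np

import lipidmsm as lm
from lipidmsm.featurize import PointSet, Trajectory

rng = np.random.default_rng(0)

# a 6-atom receptor and a 3-atom ligand; the ligand drifts toward its pose
labels = [f"REC{i}/CA" for i in range(6)] + ["lig/P", "lig/C1", "lig/C2"]
base = rng.uniform(-8.0, 8.0, (len(labels), 3))
n_frames = 12
coords = np.tile(base, (n_frames, 1, 1))
for f in range(n_frames):
    coords[f, 6:, 0] += 6.0 * (1 - f / (n_frames - 1))  # ligand approach
traj = Trajectory(labels=labels, coords=coords, times=np.arange(n_frames) * 10.0)
reference = PointSet(labels=labels, coords=base)

receptor = [l for l in labels if l.startswith("REC")]
ligand = [l for l in labels if l.startswith("lig")]

sup = lm.kabsch_superpose(traj.frame(0), reference, receptor)
print(f"Kabsch fit of frame 0: rmsd_after = {sup.rmsd_after:.3f} Å")

rmsd_series = lm.ligand_rmsd_to_reference(traj, ligand, reference, receptor)
print("ligand RMSD to reference pose (Å):", np.round(rmsd_series.values, 2))
# the series decays from 6 Å to 0 as the ligand reaches the pose

seeds = lm.select_respawn_frames([rmsd_series], threshold=5.0, max_per_traj=3)
print("respawn seeds (frame, RMSD):", [(s.frame, round(s.value, 2)) for s in seeds])

# RMSF: inflate the thermal motion of residues REC2-REC4 ("flexible helix")
wob = np.tile(base, (40, 1, 1))
for i in range(len(labels)):
    sigma = 0.8 if labels[i] in ("REC2/CA", "REC3/CA", "REC4/CA") else 0.2
    wob[:, i] += sigma * rng.standard_normal((40, 3))
wobbly = Trajectory(labels=labels, coords=wob, times=np.arange(40.0))
rmsf = lm.residue_rmsf([wobbly], align_selection=receptor, reference=reference)
print("per-residue RMSF (Å):")
print(rmsf.round(2).to_string())

# hydration: waters with any atom strictly within 5 Å of the solute
fixture = lm.make_snapshot_fixture(
    {
        "solute": {"lig/P": (0.0, 0.0, 0.0)},
        "random_waters": {"n": 80, "box": ((-8, -8, -8), (8, 8, 8)), "seed": 1},
    }
)
n_waters = lm.hydration_count(fixture, ["lig/P"], cutoff=5.0)
print(f"waters within 5 Å of the solute: {n_waters} of 80 in the box")
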