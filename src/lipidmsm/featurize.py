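"""Structure/trajectory featurization: alignment, RMSD, RMSF, hydration.

Atoms are identified by string labels of the form ``"<group>/<name>"`` where
the group is a residue (``ALA120``) or a ligand (``lig3``); ligand identity is
tracked by atom label/index across frames, never re-assigned by proximity —
chemically indistinguishable ligands remain topologically distinct.

All observables are computed after rigid (Kabsch) superposition of each frame
onto a reference structure over a receptor selection, so they are invariant
under global rigid motion of the system.  RMSD is mass-unweighted over the
named selection, ``sqrt(sum ||dr||^2 / N)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .synthetic import MarkerTrajectory, SnapshotFixture

__all__ = [
    "PointSet",
    "Trajectory",
    "Superposition",
    "ObservableSeries",
    "FrameRef",
    "kabsch_superpose",
    "extract_marker_trajectories",
    "ligand_rmsd_to_reference",
    "residue_rmsf",
    "rmsf_difference",
    "hydration_count",
    "select_respawn_frames",
    "helix_vs_ligand_rmsd",
    "WATER_RESNAMES",
]

#: Residue names recognized as water across common force-field dialects.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})


@dataclass(frozen=True)
class PointSet:
    """Labelled 3D points (a structure or a single frame)."""

    labels: tuple
    coords: np.ndarray   # (n, 3) Å

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atom labels must be unique")

    def indices(self, selection) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.asarray([index[lab] for lab in selection], int)
        except KeyError as err:
            raise KeyError(f"label {err.args[0]!r} not present") from None

    def subset(self, selection) -> "PointSet":
        idx = self.indices(selection)
        return PointSet(labels=[self.labels[i] for i in idx], coords=self.coords[idx])


@dataclass(frozen=True)
class Trajectory:
    """Frames sharing one atom labelling; optional orthorhombic box lengths."""

    labels: tuple
    coords: np.ndarray          # (n_frames, n_atoms, 3) Å
    times: np.ndarray           # (n_frames,) ns
    box: np.ndarray | None = None   # (3,) or (n_frames, 3) box edge lengths, Å

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        object.__setattr__(self, "times", np.asarray(self.times, float))
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.labels):
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.times.shape != (len(self.coords),):
            raise ValueError("times must have one entry per frame")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            object.__setattr__(self, "box", np.asarray(self.box, float))

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> PointSet:
        return PointSet(labels=self.labels, coords=self.coords[i])

    def indices(self, selection) -> np.ndarray:
        return self.frame(0).indices(selection)


@dataclass(frozen=True)
class Superposition:
    """Rigid transform (rotation then translation) minimizing selection RMSD."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,) Å
    rmsd_after: float        # Å

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8 or abs(np.linalg.det(R) - 1) > 1e-8:
            raise ValueError("rotation must be orthonormal with determinant +1")
        if self.rmsd_after < 0:
            raise ValueError("rmsd_after must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class ObservableSeries:
    """A named per-frame scalar observable with units."""

    name: str
    units: str
    times: np.ndarray    # ns
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.name,
                "units": self.units,
                "frame": np.arange(len(self.times)),
                "time_ns": self.times,
                "value": self.values,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FrameRef:
    """Reference to one frame of one trajectory (respawn seed candidate)."""

    trajectory: int
    frame: int
    time_ns: float
    value: float


# --- alignment --------------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain mass-unweighted RMSD between matched coordinate arrays."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: PointSet, reference: PointSet, selection) -> Superposition:
    """Least-squares rigid superposition (Kabsch, SVD form) over a selection.

    Returns the proper rotation + translation minimizing the RMSD of the
    selected atoms of ``mobile`` onto the matching atoms of ``reference``.
    Degenerate selections (fewer than 3 points, or collinear/coincident
    points, which leave a rotation degree of freedom undetermined) raise.
    """
    selection = list(selection)
    if len(selection) < 3:
        raise ValueError("selection must contain at least 3 atoms")
    X = mobile.coords[mobile.indices(selection)]
    Y = reference.coords[reference.indices(selection)]
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # collinear/coincident points leave the rotation underdetermined
    if np.linalg.matrix_rank(X0, tol=1e-8 * max(1.0, np.abs(X0).max())) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    return Superposition(rotation=R, translation=t, rmsd_after=rmsd(X @ R.T + t, Y))


def _aligned_frames(traj: Trajectory, reference: PointSet, align_selection):
    """Yield each frame's coordinates after superposition onto the reference."""
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        sup = kabsch_superpose(frame, reference, align_selection)
        yield i, sup.apply(frame.coords)


# --- marker extraction ------------------------------------------------------

def extract_marker_trajectories(
    traj: Trajectory,
    marker_label: str,
    ligand_ids,
    align_selection,
    reference: PointSet,
) -> list:
    """Receptor-aligned marker trajectory for each ligand, tracked by index.

    The marker atom of ligand ``lig`` is the atom labelled
    ``"<lig>/<marker_label>"``; each ligand's marker coordinates are treated
    as an independent trajectory (the ligands are chemically identical but
    topologically distinct).  Every frame is superposed onto ``reference``
    over ``align_selection`` first, so marker positions live in the receptor
    frame.
    """
    ligand_ids = list(ligand_ids)
    marker_idx = {}
    for lig in ligand_ids:
        label = f"{lig}/{marker_label}"
        try:
            marker_idx[lig] = traj.indices([label])[0]
        except KeyError:
            raise KeyError(
                f"marker atom {label!r} missing for ligand {lig!r} (frame 0)"
            ) from None

    if len(traj.times) > 1:
        interval = float(traj.times[1] - traj.times[0])
    else:
        interval = float(traj.times[0]) if traj.times[0] > 0 else 1.0

    aligned = np.empty((traj.n_frames, len(ligand_ids), 3))
    cols = np.asarray([marker_idx[lig] for lig in ligand_ids])
    for i, coords in _aligned_frames(traj, reference, align_selection):
        aligned[i] = coords[cols]
    return [
        MarkerTrajectory(
            ligand_id=str(lig), frame_interval=interval, positions=aligned[:, k]
        )
        for k, lig in enumerate(ligand_ids)
    ]


# --- RMSD / RMSF observables ------------------------------------------------

def ligand_rmsd_to_reference(
    traj: Trajectory,
    ligand_atoms,
    reference_pose: PointSet,
    align_selection,
    name: str = "ligand_rmsd",
) -> ObservableSeries:
    """Per-frame ligand RMSD to a reference pose after receptor alignment.

    The fit uses only ``align_selection`` (receptor atoms); the ligand itself
    is never fitted, so the value reports genuine displacement from the
    reference pose in the receptor frame.
    """
    ligand_atoms = list(ligand_atoms)
    idx_traj = traj.indices(ligand_atoms)
    ref = reference_pose.coords[reference_pose.indices(ligand_atoms)]
    values = np.empty(traj.n_frames)
    for i, coords in _aligned_frames(traj, reference_pose, align_selection):
        values[i] = rmsd(coords[idx_traj], ref)
    return ObservableSeries(name=name, units="angstrom", times=traj.times, values=values)


def _residue_of(label: str) -> str:
    return label.split("/", 1)[0]


def residue_rmsf(
    trajectory_set,
    selection=None,
    align_selection=None,
    reference: PointSet | None = None,
) -> pd.Series:
    """Per-residue RMSF about the mean aligned position, averaged over trajectories.

    For each trajectory, frames are superposed onto the reference (default:
    the first frame of the first trajectory) over ``align_selection`` (default:
    all atoms of the selected residues); the atomic RMSF is
    ``sqrt(mean_t ||r(t) - <r>||^2)``, a residue's value is the mean over its
    atoms, and trajectories are averaged with equal weight.
    """
    trajectory_set = list(trajectory_set)
    if not trajectory_set:
        raise ValueError("need at least one trajectory")
    if sum(t.n_frames for t in trajectory_set) < 2:
        raise ValueError("need at least 2 frames in total")
    labels = trajectory_set[0].labels
    residues = sorted({_residue_of(l) for l in labels}) if selection is None else list(selection)
    atom_idx = {
        res: [i for i, l in enumerate(labels) if _residue_of(l) == res]
        for res in residues
    }
    for res, idx in atom_idx.items():
        if not idx:
            raise KeyError(f"residue {res!r} not present in trajectory labels")
    if reference is None:
        reference = trajectory_set[0].frame(0)
    if align_selection is None:
        align_selection = [labels[i] for res in residues for i in atom_idx[res]]

    per_traj = []
    for traj in trajectory_set:
        if traj.labels != labels:
            raise ValueError("trajectories must share one atom labelling")
        coords = np.empty_like(traj.coords)
        for i, aligned in _aligned_frames(traj, reference, align_selection):
            coords[i] = aligned
        mean = coords.mean(axis=0)
        atom_rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
        per_traj.append(
            pd.Series({res: atom_rmsf[atom_idx[res]].mean() for res in residues})
        )
    out = pd.concat(per_traj, axis=1).mean(axis=1)
    out.name = "rmsf_angstrom"
    return out


def rmsf_difference(group_a, group_b, **kwargs) -> pd.Series:
    """Per-residue RMSF of group A minus group B (e.g. binding vs non-binding)."""
    a = residue_rmsf(group_a, **kwargs)
    b = residue_rmsf(group_b, **kwargs)
    out = a - b
    out.name = "rmsf_difference_angstrom"
    return out


# --- hydration --------------------------------------------------------------

def hydration_count(snapshot, solute_selection, cutoff: float = 5.0) -> int:
    """Number of water molecules with any atom strictly within ``cutoff``.

    ``snapshot`` is a :class:`SnapshotFixture` or a :class:`PointSet` whose
    water atoms are labelled ``"<resname><id>/<atom>"`` with the residue name
    in :data:`WATER_RESNAMES`.  A molecule is counted once however many of
    its atoms qualify; the boundary is a strict ``<`` comparison.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    solute_selection = list(solute_selection)
    if not solute_selection:
        raise ValueError("solute selection must be non-empty")

    if isinstance(snapshot, SnapshotFixture):
        pool = dict(snapshot.solute_atoms)
        for res, (names, coords) in snapshot.protein_atoms.items():
            for nm, xyz in zip(names, coords):
                pool[f"{res}/{nm}"] = xyz
        try:
            solute = np.asarray([pool[lab] for lab in solute_selection], float)
        except KeyError as err:
            raise KeyError(f"solute label {err.args[0]!r} not present") from None
        waters = list(snapshot.water_atoms.values())
    else:  # PointSet frame
        idx = snapshot.indices(solute_selection)
        solute = snapshot.coords[idx]
        groups = {}
        for i, lab in enumerate(snapshot.labels):
            res = _residue_of(lab)
            resname = "".join(ch for ch in res if not ch.isdigit())
            if resname.upper() in WATER_RESNAMES:
                groups.setdefault(res, []).append(i)
        waters = [snapshot.coords[np.asarray(ix)] for ix in groups.values()]

    count = 0
    for wat in waters:
        if cdist(np.atleast_2d(wat), solute).min() < cutoff:
            count += 1
    return count


# --- respawn selection ------------------------------------------------------

def select_respawn_frames(series, threshold: float, max_per_traj: int) -> list:
    """Frames below an RMSD threshold, best-first, capped per trajectory.

    ``series`` is a sequence of :class:`ObservableSeries` (one per
    trajectory).  Within each trajectory qualifying frames are ordered by
    ascending value, ties broken by earliest time; at most ``max_per_traj``
    are kept.  Deterministic; an empty result is allowed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = []
    for k, s in enumerate(series):
        hits = np.flatnonzero(s.values < threshold)
        order = hits[np.lexsort((s.times[hits], s.values[hits]))]
        for j in order[: max(0, int(max_per_traj))]:
            out.append(
                FrameRef(
                    trajectory=k,
                    frame=int(j),
                    time_ns=float(s.times[j]),
                    value=float(s.values[j]),
                )
            )
    return out


# --- helix flexibility ------------------------------------------------------

def helix_vs_ligand_rmsd(
    traj: Trajectory,
    helix_selection,
    reference: PointSet,
    ligand_atoms,
    align_selection,
) -> tuple:
    """Paired per-frame series: helix RMSD and ligand RMSD after alignment.

    Used to relate partial unfolding of the N-terminal helix (residues 34-48
    in the receptor numbering) to ligand progress toward the bound pose; the
    pair of series is suitable for a scatter export.
    """
    helix_selection = list(helix_selection)
    ligand_atoms = list(ligand_atoms)
    h_idx = traj.indices(helix_selection)
    l_idx = traj.indices(ligand_atoms)
    h_ref = reference.coords[reference.indices(helix_selection)]
    l_ref = reference.coords[reference.indices(ligand_atoms)]
    h_vals = np.empty(traj.n_frames)
    l_vals = np.empty(traj.n_frames)
    for i, coords in _aligned_frames(traj, reference, align_selection):
        h_vals[i] = rmsd(coords[h_idx], h_ref)
        l_vals[i] = rmsd(coords[l_idx], l_ref)
    return (
        ObservableSeries("helix_rmsd", "angstrom", traj.times, h_vals),
        ObservableSeries("ligand_rmsd", "angstrom", traj.times, l_vals),
    )


# --- periodic re-imaging ----------------------------------------------------

def reimage_frame(frame: PointSet, box, anchor_selection) -> PointSet:
    """Minimum-image re-imaging relative to the anchor-selection centroid.

    For orthorhombic boxes only: every atom is shifted by whole box lengths
    so it lies within half a box of the anchor centroid.  Without box
    information coordinates are used as-is elsewhere in the package.
    """
    box = np.asarray(box, float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive edge lengths")
    center = frame.coords[frame.indices(list(anchor_selection))].mean(axis=0)
    shifted = frame.coords - np.round((frame.coords - center) / box) * box
    return PointSet(labels=frame.labels, coords=shifted)
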