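"""Readers and writers for structures, models and trajectory adapters.

Plain-text formats are first-class: marker trajectories travel as delimited
tables (see :mod:`lipidmsm.synthetic`), cluster/transition models as JSON
documents with dense matrices as nested lists, grids as OpenDX text.  PDB
reference structures are read through Biotite; binary MD trajectory formats
(DCD/XTC) are available behind the same frame-iterator contract when mdtraj
is installed (``pip install lipidmsm[traj]``).
"""

from __future__ import annotations

import json

import numpy as np

from .featurize import PointSet, Trajectory
from .msm import ClusterModel, CountMatrix, TransitionModel

__all__ = [
    "read_structure",
    "read_binary_trajectory",
    "save_cluster_model",
    "load_cluster_model",
    "save_count_matrix",
    "load_count_matrix",
    "save_transition_model",
    "load_transition_model",
]


def read_structure(path, heavy_only: bool = True) -> PointSet:
    """Read a PDB file into a labelled point set.

    Labels follow the package convention ``"<resname><resid>/<atomname>"``.
    Hydrogens are dropped by default (the RMSD convention here is
    heavy-atom).
    """
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    if heavy_only:
        structure = structure[structure.element != "H"]
    labels = [
        f"{rn}{ri}/{an}"
        for rn, ri, an in zip(structure.res_name, structure.res_id, structure.atom_name)
    ]
    # disambiguate duplicates (altlocs etc.) deterministically
    seen: dict = {}
    unique = []
    for lab in labels:
        k = seen.get(lab, 0)
        seen[lab] = k + 1
        unique.append(lab if k == 0 else f"{lab}.{k}")
    return PointSet(labels=unique, coords=np.asarray(structure.coord, float))


def read_binary_trajectory(path, topology) -> Trajectory:
    """Read a DCD/XTC trajectory through mdtraj behind the Trajectory contract.

    ``topology`` is a PDB path providing atom naming.  Coordinates are
    converted from nm to Å and times from ps to ns.  Requires the optional
    ``traj`` extra.
    """
    try:
        import mdtraj
    except ImportError as err:  # pragma: no cover - depends on extras
        raise ImportError(
            "binary trajectory support requires mdtraj (pip install lipidmsm[traj])"
        ) from err

    t = mdtraj.load(str(path), top=str(topology))
    labels = [
        f"{a.residue.name}{a.residue.resSeq}/{a.name}" for a in t.topology.atoms
    ]
    times = np.asarray(t.time, float) / 1000.0
    if len(times) > 1 and times[1] <= times[0]:
        times = np.arange(t.n_frames, dtype=float)
    box = None
    if t.unitcell_lengths is not None:
        box = np.asarray(t.unitcell_lengths, float) * 10.0
    return Trajectory(
        labels=labels,
        coords=np.asarray(t.xyz, float) * 10.0,
        times=times,
        box=box,
    )


# --- JSON model containers --------------------------------------------------

def _dump(path, doc) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load(path):
    with open(path) as fh:
        return json.load(fh)


def save_cluster_model(model: ClusterModel, path) -> None:
    _dump(path, {
        "format": "lipidmsm.cluster_model/1",
        "cutoff_angstrom": float(model.cutoff),
        "centers_angstrom": model.centers.tolist(),
    })


def load_cluster_model(path) -> ClusterModel:
    doc = _load(path)
    return ClusterModel(
        centers=np.asarray(doc["centers_angstrom"], float),
        cutoff=float(doc["cutoff_angstrom"]),
    )


def save_count_matrix(cm: CountMatrix, path) -> None:
    _dump(path, {
        "format": "lipidmsm.count_matrix/1",
        "lag_ns": float(cm.lag),
        "counting_mode": cm.counting_mode,
        "counts": cm.counts.tolist(),
    })


def load_count_matrix(path) -> CountMatrix:
    doc = _load(path)
    return CountMatrix(
        counts=np.asarray(doc["counts"], float),
        lag=float(doc["lag_ns"]),
        counting_mode=doc["counting_mode"],
    )


def save_transition_model(model: TransitionModel, path) -> None:
    _dump(path, {
        "format": "lipidmsm.transition_model/1",
        "lag_ns": float(model.lag),
        "transition": model.transition.tolist(),
        "stationary": model.stationary.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "timescales_ns": [
            None if not np.isfinite(t) and np.isnan(t) else
            ("inf" if np.isinf(t) else float(t))
            for t in model.timescales
        ],
        "active_set": model.active_set.tolist(),
        "n_iterations": int(model.n_iterations),
        "final_change": float(model.final_change),
    })


def load_transition_model(path) -> TransitionModel:
    doc = _load(path)
    ts = np.asarray(
        [np.nan if t is None else (np.inf if t == "inf" else float(t))
         for t in doc["timescales_ns"]],
        float,
    )
    return TransitionModel(
        transition=np.asarray(doc["transition"], float),
        lag=float(doc["lag_ns"]),
        stationary=np.asarray(doc["stationary"], float),
        eigenvalues=np.asarray(doc["eigenvalues"], float),
        timescales=ts,
        active_set=np.asarray(doc["active_set"], int),
        n_iterations=int(doc["n_iterations"]),
        final_change=float(doc["final_change"]),
    )
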