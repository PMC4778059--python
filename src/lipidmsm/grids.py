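"""Equilibrium occupancy and free-energy voxel grids of the ligand marker.

A raw occupancy grid deposits per-frame weights into the voxel containing
each marker position (half-open voxels, lower edge inclusive); reweighting
frames by the Markov-model stationary distribution (``pi_i / n_i`` for a
frame in cluster ``i``) turns the histogram into an estimate of the
equilibrium spatial density even when the raw sampling is biased by how
trajectories were spawned.  Free energies follow as
``G_v = -kT ln(w_v / w_max)``, anchored at 0 in the most occupied voxel;
never-visited voxels carry ``+inf``.

Grids round-trip through the OpenDX scalar-field format (z-fastest data
order, documented in the file header) readable by common molecular viewers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .msm import ClusterModel, ProcessAssignment, TransitionModel

__all__ = [
    "FreeEnergyGrid",
    "auto_grid_geometry",
    "occupancy_grid",
    "equilibrium_weights",
    "free_energy_grid",
    "isosurface_mask",
    "basin_delta_g",
    "basin_delta_g_detail",
    "blob_grids",
    "sphere_region",
    "box_region",
    "region_mask",
    "write_volumetric",
    "read_volumetric",
]

#: Encoding of +inf (never-occupied voxel) in OpenDX output.
DX_INF_SENTINEL = 9.999e30


@dataclass(frozen=True)
class FreeEnergyGrid:
    """Regular 3D voxel grid (occupancy weights or free energies).

    Voxels are half-open boxes ``[origin + i*spacing, origin + (i+1)*spacing)``
    with 0-based indices; voxel centers sit at ``origin + (i + 0.5)*spacing``.
    ``kind`` is ``"occupancy"`` (raw weights) or ``"free_energy"``
    (kcal/mol, minimum 0, unoccupied voxels ``+inf``).
    """

    origin: np.ndarray        # (3,) Å, lower corner of voxel (0,0,0)
    spacing: float            # Å
    shape: tuple              # (nx, ny, nz)
    values: np.ndarray        # (nx, ny, nz)
    kT: float
    kind: str = "occupancy"
    out_of_grid_weight: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape entries must be positive")
        if self.values.shape != self.shape:
            raise ValueError("values must match shape")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.kind not in ("occupancy", "free_energy"):
            raise ValueError("kind must be 'occupancy' or 'free_energy'")
        if np.any(np.isnan(self.values)):
            raise ValueError("grid values must not be NaN")
        if self.kind == "occupancy" and not np.all(np.isfinite(self.values)):
            raise ValueError("occupancy grids must be finite")

    @property
    def voxel_centers_1d(self):
        return tuple(
            self.origin[k] + (np.arange(self.shape[k]) + 0.5) * self.spacing
            for k in range(3)
        )

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Voxel indices of points (may lie outside the grid)."""
        return np.floor(
            (np.atleast_2d(points) - self.origin) / self.spacing
        ).astype(int)


def auto_grid_geometry(trajectories, spacing: float = 1.0, margin: float = 3.0):
    """Grid origin/shape fitted to the data with a margin on all sides."""
    pts = np.concatenate([t.positions for t in trajectories])
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    return lo, shape


def occupancy_grid(
    trajectories,
    weights=None,
    origin=None,
    spacing: float = 1.0,
    shape=None,
    kT: float = 0.596,
) -> FreeEnergyGrid:
    """Deposit per-frame weights into voxels (lower-inclusive binning).

    ``weights`` is one value per frame over the concatenation of all
    trajectories (unit weights if absent).  Frames falling outside the grid
    are not deposited but their total weight is recorded in
    ``out_of_grid_weight`` so weight is conserved and the loss visible.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    trajectories = list(trajectories)
    if origin is None or shape is None:
        origin, shape = auto_grid_geometry(trajectories, spacing)
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("zero-size grid")
    pts = np.concatenate([t.positions for t in trajectories])
    if weights is None:
        weights = np.ones(len(pts))
    weights = np.asarray(weights, float)
    if weights.shape != (len(pts),):
        raise ValueError("weights must have one entry per frame")

    origin = np.asarray(origin, float)
    idx = np.floor((pts - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    values = np.zeros(shape)
    np.add.at(
        values, (idx[inside, 0], idx[inside, 1], idx[inside, 2]), weights[inside]
    )
    return FreeEnergyGrid(
        origin=origin,
        spacing=spacing,
        shape=shape,
        values=values,
        kT=kT,
        kind="occupancy",
        out_of_grid_weight=float(weights[~inside].sum()),
    )


@dataclass(frozen=True)
class ReweightResult:
    """Per-frame equilibrium weights plus the trimming loss report."""

    weights: np.ndarray
    n_unassigned: int          # frames in states outside the active set
    unassigned_fraction: float


def equilibrium_weights(labels, model: TransitionModel) -> ReweightResult:
    """Stationary reweighting: a frame in cluster ``i`` gets ``pi_i / n_i``.

    ``labels`` are cluster labels per frame (original cluster indexing);
    frames in clusters outside the model's active set get zero weight and are
    reported, not silently dropped.  Weights of the retained frames sum to 1.
    """
    labels = np.asarray(labels, int)
    weights = np.zeros(len(labels))
    active_pos = {int(s): k for k, s in enumerate(model.active_set)}
    for state, k in active_pos.items():
        mask = labels == state
        n_i = int(mask.sum())
        if n_i:
            weights[mask] = model.stationary[k] / n_i
    n_unassigned = int(np.sum(weights == 0))
    total = weights.sum()
    if total > 0:
        weights /= total
    return ReweightResult(
        weights=weights,
        n_unassigned=n_unassigned,
        unassigned_fraction=n_unassigned / max(len(labels), 1),
    )


def free_energy_grid(occupancy: FreeEnergyGrid, kT: float) -> FreeEnergyGrid:
    """Convert occupancy weights to relative free energy.

    ``G_v = -kT ln(w_v / w_max)``: 0 at the most occupied voxel, ``+inf``
    where the weight is zero.  Invariant under rescaling all weights.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    if occupancy.kind != "occupancy":
        raise ValueError("input must be an occupancy grid")
    w = occupancy.values
    w_max = w.max()
    if w_max <= 0:
        raise ValueError("occupancy grid is empty (all-zero weights)")
    with np.errstate(divide="ignore"):
        G = -kT * np.log(w / w_max)
    return replace(occupancy, values=G, kT=kT, kind="free_energy")


def isosurface_mask(grid: FreeEnergyGrid, level: float = 1.0) -> np.ndarray:
    """Boolean mask of voxels within ``level`` kT of the free-energy minimum."""
    if grid.kind != "free_energy":
        raise ValueError("isosurface mask is defined on free-energy grids")
    # never-occupied voxels (+inf) stay outside the surface even at level inf
    return (grid.values <= level * grid.kT) & np.isfinite(grid.values)


# --- regions ----------------------------------------------------------------

def sphere_region(center, radius: float):
    """Voxel predicate: voxel centers within ``radius`` of ``center``."""
    center = np.asarray(center, float)
    if radius <= 0:
        raise ValueError("radius must be positive")

    def predicate(xyz):
        return np.sum((xyz - center) ** 2, axis=-1) <= radius**2

    return predicate


def box_region(lower, upper):
    """Voxel predicate: voxel centers inside an axis-aligned box."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)

    def predicate(xyz):
        return np.all((xyz >= lower) & (xyz <= upper), axis=-1)

    return predicate


def region_mask(grid: FreeEnergyGrid, region) -> np.ndarray:
    """Evaluate a voxel predicate on the grid's voxel centers."""
    cx, cy, cz = grid.voxel_centers_1d
    xyz = np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)
    return region(xyz)


def basin_delta_g_detail(grid: FreeEnergyGrid, region_a, region_b, kT: float | None = None):
    """Free-energy difference b minus a, population and voxel-minimum readings.

    The population definition is ``dG = -kT ln(W_b / W_a)`` from region-summed
    occupancy weights; the voxel-minimum definition compares the deepest
    free-energy voxel of each region.  Returns ``(population_dg, min_voxel_dg)``.
    """
    if grid.kind != "occupancy":
        raise ValueError("basin free energies need an occupancy grid")
    kT = grid.kT if kT is None else kT
    mask_a = region_mask(grid, region_a)
    mask_b = region_mask(grid, region_b)
    W_a = grid.values[mask_a].sum()
    W_b = grid.values[mask_b].sum()
    if W_a <= 0 or W_b <= 0:
        raise ValueError("both regions must contain occupied voxels")
    population = -kT * np.log(W_b / W_a)
    G = free_energy_grid(grid, kT).values
    min_voxel = float(G[mask_b].min() - G[mask_a].min())
    return float(population), min_voxel


def basin_delta_g(grid: FreeEnergyGrid, region_a, region_b, kT: float | None = None) -> float:
    """Population free-energy difference of region b relative to region a."""
    return basin_delta_g_detail(grid, region_a, region_b, kT)[0]


# --- process blobs ----------------------------------------------------------

def blob_grids(
    assignment: ProcessAssignment,
    clusters: ClusterModel,
    labels,
    trajectories,
    weights=None,
    origin=None,
    spacing: float = 1.0,
    shape=None,
    active_set=None,
    kT: float = 0.596,
):
    """Source/sink occupancy grids of one relaxation process, for rendering.

    Frames belonging to the source (resp. sink) clusters of the eigenvector
    split are binned separately, yielding the two "blobs" between which the
    relaxation exchanges probability.  ``labels`` are per-frame cluster labels
    in the original cluster indexing; ``active_set`` maps the assignment's
    state indices back to it (defaults to identity).
    """
    labels = np.asarray(labels, int)
    if active_set is None:
        active_set = np.arange(clusters.n_clusters)
    active_set = np.asarray(active_set, int)
    pts = np.concatenate([t.positions for t in trajectories])
    if len(labels) != len(pts):
        raise ValueError("labels must have one entry per frame")
    if weights is None:
        weights = np.ones(len(pts))
    weights = np.asarray(weights, float)
    if origin is None or shape is None:
        origin, shape = auto_grid_geometry(trajectories, spacing)

    out = []
    for side in (assignment.source_states, assignment.sink_states):
        member = np.isin(labels, active_set[side])
        side_weights = np.where(member, weights, 0.0)
        out.append(
            occupancy_grid(
                trajectories,
                weights=side_weights,
                origin=origin,
                spacing=spacing,
                shape=shape,
                kT=kT,
            )
        )
    return tuple(out)


# --- OpenDX I/O -------------------------------------------------------------

def write_volumetric(grid: FreeEnergyGrid, path) -> None:
    """Write a grid as an OpenDX scalar field.

    Data order is z-fastest (the OpenDX convention), stated in the header
    comment; ``+inf`` is encoded as ``9.999e+30``.  The voxel *centers* are
    exported as the grid positions, matching how viewers place isosurfaces.
    """
    nx, ny, nz = grid.shape
    vals = grid.values.astype(float).copy()
    vals[np.isinf(vals)] = DX_INF_SENTINEL
    flat = vals.reshape(-1)  # C order = z fastest for (x, y, z) axes
    center0 = grid.origin + 0.5 * grid.spacing
    lines = [
        "# OpenDX scalar field written by lipidmsm",
        f"# kind={grid.kind} kT={grid.kT!r} out_of_grid_weight={grid.out_of_grid_weight!r}",
        "# data order: x slowest, z fastest; +inf encoded as 9.999e+30",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {center0[0]:.10g} {center0[1]:.10g} {center0[2]:.10g}",
        f"delta {grid.spacing:.10g} 0 0",
        f"delta 0 {grid.spacing:.10g} 0",
        f"delta 0 0 {grid.spacing:.10g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {flat.size} data follows",
    ]
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.17g}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_volumetric(path) -> FreeEnergyGrid:
    """Read an OpenDX scalar field written by :func:`write_volumetric`.

    Tolerates comments and blank lines; rejects non-uniform or non-axis-
    aligned deltas with an error naming the offending line.
    """
    shape = None
    center0 = None
    deltas = []
    data = []
    n_items = None
    kind, kT, oog = "occupancy", 0.596, 0.0
    with open(path) as fh:
        in_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "kind=" in line:
                    for tok in line.lstrip("# ").split():
                        key, _, val = tok.partition("=")
                        if key == "kind":
                            kind = val
                        elif key == "kT":
                            kT = float(val)
                        elif key == "out_of_grid_weight":
                            oog = float(val)
                continue
            if in_data:
                if line.startswith(("attribute", "object")):
                    in_data = False
                    continue
                try:
                    data.extend(float(tok) for tok in line.split())
                except ValueError:
                    raise ValueError(f"{path}: bad data value on line {lineno}") from None
                continue
            if line.startswith("object 1"):
                try:
                    shape = tuple(int(tok) for tok in line.split()[-3:])
                except ValueError:
                    raise ValueError(f"{path}: bad counts on line {lineno}") from None
            elif line.startswith("origin"):
                center0 = np.asarray([float(t) for t in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append(np.asarray([float(t) for t in line.split()[1:4]]))
            elif "data follows" in line:
                n_items = int(line.split()[-3])
                in_data = True
    if shape is None or center0 is None or len(deltas) != 3:
        raise ValueError(f"{path}: missing grid header (counts/origin/deltas)")
    D = np.asarray(deltas)
    spacing = float(D[0, 0])
    if not np.allclose(D, np.eye(3) * spacing) or spacing <= 0:
        raise ValueError(f"{path}: only uniform axis-aligned deltas are supported")
    if n_items is None or len(data) != n_items:
        raise ValueError(
            f"{path}: expected {n_items} data values, found {len(data)}"
        )
    values = np.asarray(data).reshape(shape)
    if kind == "free_energy":
        values = np.where(values >= 1e30, np.inf, values)
    return FreeEnergyGrid(
        origin=center0 - 0.5 * spacing,
        spacing=spacing,
        shape=shape,
        values=values,
        kT=kT,
        kind=kind,
        out_of_grid_weight=oog,
    )
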