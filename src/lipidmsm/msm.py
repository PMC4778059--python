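"""Markov state model estimation from discretized marker trajectories.

The chain of operations mirrors standard MSM practice for ligand-binding
kinetics: discretize 3D marker positions with single-pass regular-space
clustering, count lagged transitions between clusters, restrict to the
largest strongly connected set, estimate a transition matrix by maximum
likelihood under a detailed-balance constraint, and read kinetics off the
spectrum (implied timescales ``t_s = -lag / ln(lambda_s)``) and mechanisms
off the eigenvector sign structure.

Convention note: the transition matrix is stored *row*-stochastically,
``T[i, j] = P(state j at t + lag | state i at t)``, matching the counting
direction.  The master-equation literature often writes the column
convention ``P(t) = T_col(t) P(0)``; the two are transposes of each other
and :func:`propagate` accepts probability vectors in the natural (row)
orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterModel",
    "CountMatrix",
    "TransitionModel",
    "ProcessAssignment",
    "regular_space_cluster",
    "assign",
    "count_matrix",
    "largest_connected_set",
    "reversible_mle",
    "transition_model_from_matrix",
    "stationary_distribution",
    "implied_timescales",
    "timescales_vs_lag",
    "lag_flatness",
    "eigenvector_processes",
    "propagate",
]

#: Implied timescale reported when an eigenvalue is indistinguishable from 1
#: at float precision (relaxation beyond the observable horizon).
BEYOND_HORIZON = np.inf


@dataclass(frozen=True)
class ClusterModel:
    """Regular-space cluster centers with their admission distance."""

    centers: np.ndarray   # (m, 3) Å
    cutoff: float         # Å

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, float))
        if self.centers.ndim != 2 or len(self.centers) < 1:
            raise ValueError("need at least one center")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if len(self.centers) > 1:
            d = cdist(self.centers, self.centers)
            np.fill_diagonal(d, np.inf)
            # strict regular-space invariant, with float slack
            if d.min() < self.cutoff * (1 - 1e-12):
                raise ValueError("cluster centers closer than the cutoff")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class CountMatrix:
    """Lagged transition counts pooled over trajectories."""

    counts: np.ndarray        # (m, m)
    lag: float                # ns
    counting_mode: str        # "sliding" | "strided"

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lag <= 0:
            raise ValueError("lag must be positive")
        if self.counting_mode not in ("sliding", "strided"):
            raise ValueError("counting_mode must be 'sliding' or 'strided'")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class TransitionModel:
    """Reversible transition matrix with its spectral summary.

    ``active_set`` maps the rows/columns of ``transition`` back to the
    original cluster indices (states dropped by connectivity trimming are
    absent).  ``eigenvalues`` are real (reversibility) and descending;
    ``timescales`` carries ``-lag / ln(lambda_s)`` for the eigenvalues in
    (0, 1), aligned with ``eigenvalues[1:]`` (NaN where undefined).
    """

    transition: np.ndarray       # (m, m) row-stochastic
    lag: float                   # ns
    stationary: np.ndarray       # (m,)
    eigenvalues: np.ndarray      # (m,) descending
    timescales: np.ndarray       # (m - 1,) ns, NaN where eigenvalue <= 0
    active_set: np.ndarray       # (m,) original state indices
    n_iterations: int = 0
    final_change: float = 0.0

    def __post_init__(self):
        for name in ("transition", "stationary", "eigenvalues", "timescales", "active_set"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        T, pi = self.transition, self.stationary
        if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
            raise ValueError("transition entries must lie in [0, 1]")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition rows must sum to 1")
        flux = pi[:, None] * T
        scale = np.maximum(np.abs(flux), np.abs(flux.T))
        bad = np.abs(flux - flux.T) > 1e-8 * np.maximum(scale, 1e-300)
        if np.any(bad & (scale > 0)):
            raise ValueError("transition model violates detailed balance")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


@dataclass(frozen=True)
class ProcessAssignment:
    """Sign split of one relaxation eigenvector into source and sink states."""

    index: int                   # which relaxation process (2 = slowest)
    source_states: np.ndarray    # indices into the active set
    sink_states: np.ndarray
    source_centroid: np.ndarray  # (3,) Å, stationary-weighted
    sink_centroid: np.ndarray
    timescale: float             # ns


# --- discretization ---------------------------------------------------------

def regular_space_cluster(points, cutoff: float, chunk: int = 65536) -> ClusterModel:
    """Single-pass regular-space clustering in input order.

    A point becomes a new center iff its distance to every existing center is
    at least ``cutoff``.  The result is deterministic given the input order.
    Vectorized in chunks; cost is O(n * m) with m the number of centers.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(points) == 0:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite coordinates")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    centers = [points[0]]
    i = 1
    n = len(points)
    while i < n:
        block = points[i : i + chunk]
        d = cdist(block, np.asarray(centers)).min(axis=1)
        far = d >= cutoff
        if not far.any():
            i += len(block)
            continue
        j = int(np.argmax(far))  # first admissible point in this block
        centers.append(block[j])
        i += j + 1
    return ClusterModel(centers=np.asarray(centers), cutoff=cutoff)


def assign(points, model: ClusterModel, chunk: int = 262144) -> np.ndarray:
    """Label each point with its nearest center (ties -> lowest center index)."""
    points = np.atleast_2d(np.asarray(points, float))
    labels = np.empty(len(points), dtype=np.int64)
    for i in range(0, len(points), chunk):
        block = points[i : i + chunk]
        labels[i : i + len(block)] = cdist(block, model.centers).argmin(axis=1)
    return labels


# --- counting ---------------------------------------------------------------

def _lag_steps(lag: float, frame_interval: float) -> int:
    steps = lag / frame_interval
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError(
            f"lag ({lag} ns) must be a positive integer multiple of the frame "
            f"interval ({frame_interval} ns)"
        )
    return int(round(steps))


def count_matrix(
    label_seqs,
    frame_interval: float,
    lag: float,
    mode: str = "sliding",
    n_states: int | None = None,
) -> CountMatrix:
    """Pool lagged transition counts over discrete trajectories.

    ``sliding`` counts every ordered pair ``(s(t), s(t + lag))``; ``strided``
    counts only non-overlapping pairs.  Counting never crosses trajectory
    boundaries.  Sequences no longer than the lag contribute nothing.
    """
    steps = _lag_steps(lag, frame_interval)
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    seqs = [np.asarray(s, dtype=np.int64) for s in label_seqs]
    if n_states is None:
        n_states = 1 + max((int(s.max()) for s in seqs if len(s)), default=0)
    C = np.zeros((n_states, n_states))
    for s in seqs:
        if len(s) <= steps:
            continue
        if mode == "sliding":
            a, b = s[:-steps], s[steps:]
        else:
            sub = s[::steps]
            a, b = sub[:-1], sub[1:]
        np.add.at(C, (a, b), 1.0)
    return CountMatrix(counts=C, lag=lag, counting_mode=mode)


def largest_connected_set(counts: CountMatrix) -> np.ndarray:
    """Largest strongly connected component of the transition-count graph.

    Edges are ``i -> j`` wherever ``counts[i, j] > 0``.  Ties in component
    size are broken by total counts, then by lowest state index.
    """
    C = counts.counts
    if not np.any(C > 0):
        raise ValueError("count matrix has no transitions")
    n_comp, labels = connected_components(
        csr_matrix((C > 0).astype(np.int8)), directed=True, connection="strong"
    )
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        key = (len(members), C[np.ix_(members, members)].sum(), -members[0])
        if best_key is None or key > best_key:
            best, best_key = members, key
    return best


# --- estimation -------------------------------------------------------------

def reversible_mle(
    counts: CountMatrix,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
) -> TransitionModel:
    """Maximum-likelihood reversible transition matrix.

    Maximizes ``sum_ij c_ij ln T_ij`` over row-stochastic matrices satisfying
    detailed balance via the self-consistent fixed-point iteration on
    unnormalized symmetric flows::

        x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)

    with ``x_i = sum_j x_ij`` (row sums) and ``c_i = sum_j c_ij``, initialized
    from symmetrized counts.  The iteration is likelihood-ascending; the
    result has ``T_ij = x_ij / x_i`` and stationary vector ``pi_i = x_i / X``.
    Estimation is restricted to the largest strongly connected set; dropped
    states are reflected in ``active_set``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    active = largest_connected_set(counts)
    C = counts.counts[np.ix_(active, active)]
    c_row = C.sum(axis=1)
    if np.any(c_row <= 0):  # cannot happen on a strongly connected set
        raise ValueError("state with no outgoing counts in the connected set")

    sym = C + C.T
    mask = sym > 0
    x = sym / sym.sum()
    delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        x_row = x.sum(axis=1)
        q = c_row / x_row
        denom = q[:, None] + q[None, :]
        x_new = np.where(mask, sym / np.where(mask, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mask, np.abs(x_new - x) / np.where(mask, x, 1.0), 0.0)
        delta = rel.max()
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last relative change {delta:.3e})"
        )

    x_row = x.sum(axis=1)
    T = x / x_row[:, None]
    pi = x_row / x_row.sum()
    eigenvalues, _ = _reversible_spectrum(T, pi)
    ts = _timescales_from_eigenvalues(eigenvalues, counts.lag)
    return TransitionModel(
        transition=T,
        lag=counts.lag,
        stationary=pi,
        eigenvalues=eigenvalues,
        timescales=ts,
        active_set=active,
        n_iterations=n_iter,
        final_change=float(delta),
    )


def reversible_log_likelihood(counts: np.ndarray, T: np.ndarray) -> float:
    """``sum_ij c_ij ln T_ij`` over entries with positive counts."""
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(T[mask])))


def _reversible_spectrum(T: np.ndarray, pi: np.ndarray):
    """Real spectrum and right eigenvectors of a reversible transition matrix.

    Uses the symmetrized matrix ``S = D^{1/2} T D^{-1/2}`` (D = diag(pi)),
    which shares eigenvalues with T; right eigenvectors are recovered as
    ``D^{-1/2} psi`` and are orthonormal in the pi-weighted inner product.
    """
    d = np.sqrt(pi)
    S = (d[:, None] * T) / d[None, :]
    S = 0.5 * (S + S.T)  # symmetrize float noise
    vals, psi = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    R = psi[:, order] / d[:, None]
    return vals, R


def _timescales_from_eigenvalues(eigenvalues, lag, one_tol: float = 1e-12):
    """-lag/ln(lambda) for eigenvalues after the stationary one; NaN if <= 0."""
    lams = np.asarray(eigenvalues, float)[1:]
    ts = np.full(lams.shape, np.nan)
    near_one = lams >= 1.0 - one_tol
    ok = (lams > 0) & ~near_one
    ts[ok] = -lag / np.log(lams[ok])
    ts[near_one] = BEYOND_HORIZON
    return ts


def transition_model_from_matrix(
    T: np.ndarray,
    lag: float,
    active_set=None,
) -> TransitionModel:
    """Wrap an explicit reversible row-stochastic matrix as a TransitionModel.

    Useful for analyzing exact transition matrices (e.g. ``expm(K * lag)`` of
    a ground-truth rate model) with the same spectral machinery as estimated
    ones.  The stationary vector is computed from the matrix.
    """
    T = np.asarray(T, float)
    if active_set is None:
        active_set = np.arange(T.shape[0])
    n_comp, _ = connected_components(
        csr_matrix((T > 0).astype(np.int8)), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ValueError("transition matrix is reducible")
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(vecs[:, k].real)
    pi /= pi.sum()
    eigenvalues, _ = _reversible_spectrum(T, pi)
    return TransitionModel(
        transition=T,
        lag=lag,
        stationary=pi,
        eigenvalues=eigenvalues,
        timescales=_timescales_from_eigenvalues(eigenvalues, lag),
        active_set=np.asarray(active_set, int),
    )


def stationary_distribution(model: TransitionModel) -> np.ndarray:
    """Stationary probability vector of ``T`` (eigenvalue-1 left eigenvector).

    Recomputed from the matrix (independently of the estimator's internal
    flow normalization) by solving ``pi T = pi``; raises for a reducible
    matrix, where the stationary vector is not unique.
    """
    T = model.transition
    n_comp, _ = connected_components(
        csr_matrix((T > 0).astype(np.int8)), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ValueError("transition matrix is reducible; stationary vector not unique")
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(vecs[:, k].real)
    return pi / pi.sum()


def implied_timescales(model: TransitionModel, n_processes: int) -> np.ndarray:
    """The ``n_processes`` slowest implied timescales ``-lag / ln(lambda_s)``.

    Only eigenvalues strictly inside (0, 1) define a relaxation time;
    eigenvalues numerically at 1 are reported as ``inf`` (beyond the
    observable horizon) and non-positive eigenvalues are excluded with a
    warning.
    """
    if n_processes >= model.n_states:
        raise ValueError("n_processes must be smaller than the number of states")
    ts = model.timescales[:n_processes]
    n_bad = int(np.sum(np.isnan(ts)))
    if n_bad:
        warnings.warn(
            f"{n_bad} requested process(es) have non-positive eigenvalues; "
            "their timescales are undefined and excluded",
            stacklevel=2,
        )
    return ts[~np.isnan(ts)]


def timescales_vs_lag(
    label_seqs,
    frame_interval: float,
    lags,
    n_processes: int,
    mode: str = "sliding",
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Run the full estimation pipeline at each lag (convergence diagnostic).

    Returns a tidy table (lag_ns, process, timescale_ns); ``process`` is the
    eigenvalue index with 2 = slowest.  Implied timescales that are flat in
    the lag indicate Markovian behavior at that discretization.
    """
    rows = []
    for lag in lags:
        model = reversible_mle(
            count_matrix(label_seqs, frame_interval, lag, mode=mode), tol=tol
        )
        ts = implied_timescales(model, min(n_processes, model.n_states - 1))
        for k, t in enumerate(ts):
            rows.append({"lag_ns": lag, "process": k + 2, "timescale_ns": t})
    return pd.DataFrame(rows, columns=["lag_ns", "process", "timescale_ns"])


def lag_flatness(table: pd.DataFrame) -> pd.Series:
    """Max relative timescale change per process over the upper half of lags."""
    lags = np.sort(table["lag_ns"].unique())
    upper = lags[len(lags) // 2 :]
    out = {}
    for proc, sub in table[table["lag_ns"].isin(upper)].groupby("process"):
        ts = sub.sort_values("lag_ns")["timescale_ns"].to_numpy()
        finite = ts[np.isfinite(ts)]
        if len(finite) >= 2:
            out[proc] = float(finite.max() / finite.min() - 1.0)
    return pd.Series(out, name="max_rel_change")


# --- mechanism --------------------------------------------------------------

def eigenvector_processes(
    model: TransitionModel,
    clusters: ClusterModel,
    process_index: int,
    mass_threshold: float = 0.90,
) -> ProcessAssignment:
    """Assign one relaxation process to a source/sink split of the clusters.

    The right eigenvector of the requested eigenvalue is thresholded: states
    are ranked by ``|v_i| * pi_i`` and only the top ``mass_threshold`` of that
    cumulative mass participates in the split (the rest are spectators of the
    relaxation).  The sign orientation is fixed so the source side carries
    the lower stationary mass, matching the reading of a relaxation as decay
    of excess population from the minor into the major basin.
    """
    if process_index < 2:
        raise ValueError("process_index counts from 2 (the slowest relaxation)")
    if process_index > model.n_states:
        raise ValueError("process_index exceeds the number of states")
    vals, R = _reversible_spectrum(model.transition, model.stationary)
    v = R[:, process_index - 1]
    pi = model.stationary

    mass = np.abs(v) * pi
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order]) / mass.sum()
    n_keep = int(np.searchsorted(cum, mass_threshold) + 1)
    keep = np.zeros(model.n_states, bool)
    keep[order[:n_keep]] = True

    pos = keep & (v > 0)
    neg = keep & (v < 0)
    if not pos.any() or not neg.any():
        raise ValueError(
            f"eigenvector {process_index} has a one-sided sign structure; "
            "no genuine relaxation to assign"
        )
    if pi[pos].sum() <= pi[neg].sum():
        source, sink = pos, neg
    else:
        source, sink = neg, pos

    centers = clusters.centers[model.active_set]

    def _centroid(side):
        w = pi[side]
        return (centers[side] * w[:, None]).sum(axis=0) / w.sum()

    return ProcessAssignment(
        index=process_index,
        source_states=np.flatnonzero(source),
        sink_states=np.flatnonzero(sink),
        source_centroid=_centroid(source),
        sink_centroid=_centroid(sink),
        timescale=float(model.timescales[process_index - 2]),
    )


# --- propagation ------------------------------------------------------------

def propagate(model, p0, t: float) -> np.ndarray:
    """Evolve a probability vector for time ``t``.

    For a :class:`TransitionModel` this is the matrix power ``p0 T^(t/lag)``
    (``t`` must be a multiple of the lag); for a rate model it is the matrix
    exponential solution of the master equation.
    """
    p0 = np.asarray(p0, float)
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-10:
        raise ValueError("p0 must be a probability vector")
    if t < 0:
        raise ValueError("t must be non-negative")
    if isinstance(model, TransitionModel):
        steps = t / model.lag
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("t must be a multiple of the model lag")
        out = p0 @ np.linalg.matrix_power(model.transition, int(round(steps)))
    else:  # rate model: dP/dt = K P with K in column convention
        from scipy.linalg import expm

        K = np.asarray(model.rate_matrix, float)
        out = expm(K * t) @ p0
    out = np.clip(out, 0.0, None)
    return out / out.sum()
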