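"""Ant-colony clustering with pheromone dynamics and a mutation refinement.

Data points (here: lncRNA association profiles) are treated as foraging
ants and cluster centers as food sources.  Each point carries a pheromone
trail ``T[i, j]`` toward every center ``j``; the probability that point
``i`` joins center ``j`` combines accumulated pheromone (weighted by the
exponent ``alpha``) with *visibility*, the reciprocal Euclidean distance
(weighted by ``beta``)::

    p[i, j] = T[i, j]**alpha * eta[i, j]**beta / sum_j'(...)

A point joins the most probable center when that probability exceeds the
threshold ``p0``; otherwise it founds a new cluster at its own position,
so the number of clusters is discovered rather than fixed in advance.
Pheromone is initialized by thresholding distance at the cluster radius
``r`` (trail 1 within radius, 0 beyond) and thereafter evaporates at rate
``rho_evap`` while receiving a deposit ``Q / d(x_i, c_j)`` each cycle, so
trails concentrate on short paths.

The refinement loop adds a *mutation* step: occasionally one point is
reassigned to a random other cluster, and the move is kept only if it
strictly lowers the best objective ``F_min`` seen so far, where the
objective ``F`` is the mean squared Euclidean distance of points to their
own cluster center.  This lets the colony escape premature convergence
without ever worsening the best solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "AntParams",
    "PheromoneMatrix",
    "ClusterState",
    "euclidean_distance",
    "visibility",
    "init_pheromone",
    "transition_probabilities",
    "assign_points",
    "update_centers",
    "update_pheromone",
    "objective_F",
    "mutate",
    "run_clustering",
]

#: guard against division by zero when a point coincides with a center
EPS = 1e-12

# customary parameter ranges; values outside draw a warning, not an error
_SOFT_RANGES = {
    "alpha": (0.0, 5.0),
    "beta": (0.0, 5.0),
    "rho_evap": (0.1, 0.99),
    "Q": (1.0, 10000.0),
}


@dataclass
class AntParams:
    """Tunable parameters of the ant-colony clustering.

    Attributes
    ----------
    r : float or None
        Cluster radius used to initialize pheromone (trail 1 iff distance
        <= r).  ``None`` means "median pairwise distance of the data".
    p0 : float
        Transition-probability threshold; a point joins an existing
        cluster only if its best transition probability exceeds ``p0``.
    alpha, beta : float
        Pheromone and visibility importance exponents.
    rho_evap : float
        Pheromone evaporation rate in (0, 1].
    Q : float
        Pheromone deposit constant (> 0); larger Q accumulates trail
        faster and speeds convergence.
    max_iter : int
        Cap on outer iterations.
    mutation_rate : float
        Per-iteration probability of attempting a single-point mutation.
    seed : int or None
        Seed for the single RNG that drives every stochastic choice.
    """

    r: float | None = None
    p0: float = 0.7
    alpha: float = 1.0
    beta: float = 2.0
    rho_evap: float = 0.5
    Q: float = 100.0
    max_iter: int = 100
    mutation_rate: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.r is not None and not self.r > 0:
            raise ValueError("cluster radius r must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not 0 < self.rho_evap <= 1:
            raise ValueError("rho_evap must lie in (0, 1]")
        if not self.Q > 0:
            raise ValueError("Q must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        for name, (lo, hi) in _SOFT_RANGES.items():
            v = getattr(self, name)
            if not lo < v < hi:
                warnings.warn(
                    f"{name}={v} is outside the customary range ({lo}, {hi})"
                )


@dataclass
class PheromoneMatrix:
    """Nonnegative, finite trail intensities, points x clusters."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("pheromone matrix must be 2-d")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("pheromone entries must be nonnegative and finite")
        self.values = v


@dataclass
class ClusterState:
    """Snapshot of a clustering run.

    ``objective`` is the current F (mean squared distance to own center);
    ``best_objective`` is F_min, the smallest objective seen so far, and
    is nonincreasing across iterations by construction.
    """

    assignments: np.ndarray
    centers: np.ndarray
    pheromone: PheromoneMatrix
    objective: float
    best_objective: float
    n_iter: int = 0
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        k = self.centers.shape[0]
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= k
        ):
            raise ValueError("every assignment must index an existing center")
        if self.objective < 0:
            raise ValueError("objective must be nonnegative")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def euclidean_distance(x, y) -> float:
    """Euclidean distance ``(sum_k |x_k - y_k|^2)^(1/2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(((x - y) ** 2).sum()))


def visibility(d: float, eps: float = EPS) -> float:
    """Heuristic desirability of a transition: ``1 / max(d, eps)``."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return 1.0 / max(d, eps)


def init_pheromone(points, centers, r: float) -> PheromoneMatrix:
    """Initial binary trails: 1 iff a point lies within radius r of a center."""
    if not r > 0:
        raise ValueError("radius r must be positive")
    d = cdist(np.atleast_2d(points), np.atleast_2d(centers))
    return PheromoneMatrix((d <= r).astype(float))


def transition_probabilities(T_row, eta_row, alpha: float, beta: float) -> np.ndarray:
    """Normalized transition probabilities ``T^alpha * eta^beta / sum``.

    Raises
    ------
    ValueError
        If every product term is zero ("no admissible transition"); the
        caller then seeds a new cluster at the point.
    """
    T_row = np.asarray(T_row, dtype=float)
    eta_row = np.asarray(eta_row, dtype=float)
    if T_row.shape != eta_row.shape:
        raise ValueError("pheromone and visibility rows must align")
    if (T_row < 0).any() or (eta_row < 0).any():
        raise ValueError("pheromone and visibility must be nonnegative")
    w = T_row**alpha * eta_row**beta
    total = w.sum()
    if not total > 0:
        raise ValueError("no admissible transition: all product terms are zero")
    return w / total


def _compact(points: np.ndarray, assignments: np.ndarray, pheromone: np.ndarray):
    """Mean-update centers, drop empty clusters, compact indices.

    Returns (centers, assignments, pheromone) with cluster indices
    renumbered 0..k-1 over the nonempty clusters only.
    """
    k = int(assignments.max()) + 1 if assignments.size else 0
    occupied = [j for j in range(k) if (assignments == j).any()]
    remap = {old: new for new, old in enumerate(occupied)}
    new_assign = np.array([remap[a] for a in assignments], dtype=int)
    centers = np.vstack(
        [points[assignments == j].mean(axis=0) for j in occupied]
    )
    pher = pheromone[:, occupied]
    return centers, new_assign, pher


def update_centers(points, assignments):
    """Recompute centers as member means; drop empty clusters.

    Returns ``(centers, assignments)`` with compacted cluster indices.
    """
    points = np.asarray(points, dtype=float)
    assignments = np.asarray(assignments, dtype=int)
    dummy = np.zeros((points.shape[0], int(assignments.max()) + 1))
    centers, new_assign, _ = _compact(points, assignments, dummy)
    return centers, new_assign


def update_pheromone(T: PheromoneMatrix, distances, params: AntParams) -> PheromoneMatrix:
    """Evaporate and deposit: ``T' = (1 - rho_evap) T + Q / max(d, eps)``."""
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    delta = params.Q / np.maximum(d, EPS)
    return PheromoneMatrix((1.0 - params.rho_evap) * T.values + delta)


def objective_F(points, state: ClusterState) -> float:
    """Mean squared Euclidean distance of each point to its own center."""
    points = np.asarray(points, dtype=float)
    diffs = points - state.centers[state.assignments]
    return float((diffs**2).sum(axis=1).mean())


def _mean_sq(points: np.ndarray, assignments: np.ndarray, centers: np.ndarray) -> float:
    diffs = points - centers[assignments]
    return float((diffs**2).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# clustering passes
# ---------------------------------------------------------------------------

def assign_points(points, state: ClusterState, params: AntParams, rng) -> ClusterState:
    """One colony pass: every point picks a center or founds a new cluster.

    For point ``i`` the transition probabilities over the current centers
    are computed from its pheromone row and visibilities; if the best
    probability exceeds ``p0`` the point joins that center, otherwise (or
    when no transition is admissible) it seeds a new cluster at its own
    position, whose pheromone column is distance-thresholded at radius r.
    Centers are recomputed (member means) and empty clusters dropped.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    r = params.r
    if r is None:
        raise ValueError("assign_points needs a concrete radius; resolve r first")
    centers = state.centers.copy()
    pher = state.pheromone.values.copy()
    assignments = np.empty(n, dtype=int)

    for i in range(n):
        d = np.sqrt(((points[i] - centers) ** 2).sum(axis=1))
        eta = 1.0 / np.maximum(d, EPS)
        try:
            probs = transition_probabilities(pher[i], eta, params.alpha, params.beta)
            j = int(np.argmax(probs))
            admissible = probs[j] > params.p0
        except ValueError:
            admissible = False
        if admissible:
            assignments[i] = j
        else:
            # found a new cluster at this point; binary trails at radius r
            centers = np.vstack([centers, points[i]])
            new_col = (
                np.sqrt(((points - points[i]) ** 2).sum(axis=1)) <= r
            ).astype(float)
            pher = np.hstack([pher, new_col[:, None]])
            assignments[i] = centers.shape[0] - 1

    centers, assignments, pher = _compact(points, assignments, pher)
    F = _mean_sq(points, assignments, centers)
    return ClusterState(
        assignments=assignments,
        centers=centers,
        pheromone=PheromoneMatrix(pher),
        objective=F,
        best_objective=min(state.best_objective, F),
        n_iter=state.n_iter,
        history=state.history,
    )


def mutate(points, state: ClusterState, params: AntParams, rng) -> ClusterState:
    """Single-point random reassignment, accepted only if it beats F_min.

    With probability ``mutation_rate`` one uniformly chosen point is moved
    to a uniformly chosen *different* cluster; centers are recomputed and
    the mutated objective F_temp compared against the best objective seen
    so far.  The move is kept iff ``F_temp < F_min`` (which then becomes
    the new F_min); otherwise the input state is returned unchanged.
    No-op when fewer than two clusters exist.
    """
    points = np.asarray(points, dtype=float)
    k = state.n_clusters
    if k < 2 or params.mutation_rate == 0:
        return state
    if rng.random() >= params.mutation_rate:
        return state
    n = points.shape[0]
    i = int(rng.integers(n))
    cur = int(state.assignments[i])
    j = int(rng.integers(k - 1))
    if j >= cur:
        j += 1
    trial = state.assignments.copy()
    trial[i] = j
    centers, trial, pher = _compact(points, trial, state.pheromone.values)
    F_temp = _mean_sq(points, trial, centers)
    if F_temp < state.best_objective:
        return ClusterState(
            assignments=trial,
            centers=centers,
            pheromone=PheromoneMatrix(pher),
            objective=F_temp,
            best_objective=F_temp,
            n_iter=state.n_iter,
            history=state.history,
        )
    return state


def resolve_radius(points, params: AntParams) -> float:
    """Concrete cluster radius: params.r, else median pairwise distance."""
    if params.r is not None:
        return params.r
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(points)))
    return med if med > 0 else 1.0


def run_clustering(points, params: AntParams | None = None) -> ClusterState:
    """Full clustering loop: assign, deposit pheromone, mutate, repeat.

    The colony starts from a single cluster seeded at a uniformly drawn
    point; new clusters appear through the ``p0`` rule.  Iteration stops
    when the assignment vector is identical on two consecutive passes or
    after ``max_iter`` passes.  Deterministic given ``params.seed``, and
    invariant to permutations of the input rows (up to cluster
    relabeling): points are processed in a canonical lexicographic order
    internally and the result mapped back to input order.
    """
    if params is None:
        params = AntParams()
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValueError("points must be a nonempty n x d matrix")
    n = points.shape[0]

    order = np.lexsort(points.T[::-1])  # canonical: sort by col 0, then 1, ...
    pts = points[order]
    rng = np.random.default_rng(params.seed)
    r = resolve_radius(pts, params)
    params = replace(params, r=r)

    centers = pts[[int(rng.integers(n))]]
    pher = init_pheromone(pts, centers, r)
    assignments = np.zeros(n, dtype=int)
    F0 = _mean_sq(pts, assignments, centers)
    state = ClusterState(
        assignments=assignments,
        centers=centers,
        pheromone=pher,
        objective=F0,
        best_objective=F0,
    )

    prev = state.assignments.copy()
    for it in range(1, params.max_iter + 1):
        state = assign_points(pts, state, params, rng)
        d = cdist(pts, state.centers)
        state.pheromone = update_pheromone(state.pheromone, d, params)
        state = mutate(pts, state, params, rng)
        state.n_iter = it
        state.history.append(state.best_objective)
        if state.assignments.shape == prev.shape and np.array_equal(
            state.assignments, prev
        ):
            break
        prev = state.assignments.copy()

    # map canonical-order assignments back to the caller's row order
    out = np.empty(n, dtype=int)
    out[order] = state.assignments
    pher_out = np.empty_like(state.pheromone.values)
    pher_out[order] = state.pheromone.values
    state.assignments = out
    state.pheromone = PheromoneMatrix(pher_out)
    return state
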