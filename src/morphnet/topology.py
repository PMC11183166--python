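"""Graph-theoretic topology of thresholded similarity networks.

Weighted similarity matrices are binarized over a grid of *sparsity*
thresholds (the fraction of strongest edges retained), and standard global
and nodal metrics are computed at every threshold:

* global: clustering coefficient ``Cp``, characteristic path length
  ``Lp``, normalized ``gamma = Cp / <Cp_rand>`` and
  ``lambda = Lp / <Lp_rand>`` against degree-preserving rewired null
  graphs, small-worldness ``sigma = gamma / lambda``, global efficiency
  ``Eg`` and local efficiency ``Eloc``;
* nodal: degree, nodal efficiency and shortest-path betweenness.

Because sparse binarized graphs can disconnect, path length follows the
harmonic-mean convention ``Lp = 1 / Eg`` (unreachable pairs contribute
zero efficiency), which keeps ``Lp`` and ``lambda`` finite everywhere.
Each metric curve over the grid is summarized by its trapezoidal area
under the curve (AUC).

Shortest-path distances are computed with a dense breadth-first search
expressed as boolean matrix products, which is exact for unweighted graphs
and fast at parcellation scale; betweenness uses igraph's Brandes
implementation (unnormalized, each unordered pair counted once, fractional
credit across equal-length paths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numba
import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "SparsityGrid",
    "BinaryGraph",
    "GlobalMetrics",
    "threshold_by_sparsity",
    "shortest_path_lengths",
    "clustering_and_paths",
    "betweenness",
    "rewired_null",
    "small_world",
    "metric_curves",
    "auc",
]

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eg", "Eloc")
NODAL_METRICS = ("degree", "efficiency", "betweenness")


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered grid of sparsity thresholds (defaults: 0.05-0.40 step 0.01)."""

    start: float = 0.05
    stop: float = 0.40
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.start < self.stop <= 1):
            raise ValueError("need 0 < start < stop <= 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def thresholds(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return np.linspace(self.start, self.stop, n)

    def __len__(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph as a dense 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        a = np.ascontiguousarray(np.asarray(self.adjacency), dtype=np.uint8)
        object.__setattr__(self, "adjacency", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(a > 1):
            raise ValueError("adjacency must be 0/1")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric (undirected)")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, 1)
        mask = self.adjacency[iu] > 0
        return np.column_stack([iu[0][mask], iu[1][mask]]).astype(np.int64)


@dataclass(frozen=True)
class GlobalMetrics:
    """Global metrics of one binarized network at one threshold."""

    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    nodal_efficiency: np.ndarray = field(repr=False)


def threshold_by_sparsity(w: SimilarityMatrix | np.ndarray, s: float) -> BinaryGraph:
    """Binarize by keeping the ``floor(S * N(N-1)/2)`` strongest edges.

    Off-diagonal entries only; ties are broken deterministically by
    ascending (row, column) pair so equal-similarity matrices threshold
    identically across runs.
    """
    values = w.values if isinstance(w, SimilarityMatrix) else np.asarray(w, dtype=float)
    n = values.shape[0]
    if not (0 < s <= 1):
        raise ValueError("sparsity must lie in (0, 1]")
    max_edges = n * (n - 1) // 2
    k = int(np.floor(s * max_edges))
    if k == 0:
        raise ValueError(f"sparsity {s} retains 0 of {max_edges} edges")
    iu, ju = np.triu_indices(n, 1)
    vals = values[iu, ju]
    # sort by descending value, then ascending (i, j) for deterministic ties
    order = np.lexsort((ju, iu, -vals))[:k]
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[order], ju[order]] = 1
    a |= a.T
    return BinaryGraph(adjacency=a, sparsity=k / max_edges)


def shortest_path_lengths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf if unreachable)."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a > 0] = 1.0
    reach = a.astype(np.float32)
    a32 = a.astype(np.float32)
    level = 1
    while level <= n:
        reach = (reach @ a32) > 0
        new = reach & np.isinf(dist)
        np.fill_diagonal(new, False)
        level += 1
        if not new.any():
            break
        dist[new] = level
        reach = reach.astype(np.float32)
    return dist


def _efficiency_from_dist(dist: np.ndarray) -> tuple[float, np.ndarray]:
    """(global efficiency, per-node efficiency) from a distance matrix."""
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    nodal = inv.sum(axis=1) / (n - 1)
    return float(nodal.mean()), nodal


def _clustering(adjacency: np.ndarray) -> float:
    a = adjacency.astype(np.float32)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    k = adjacency.sum(axis=0).astype(np.float64)
    denom = k * (k - 1) / 2.0
    ci = np.zeros_like(k, dtype=np.float64)
    good = denom > 0
    ci[good] = triangles[good] / denom[good]  # Ci = 0 when degree < 2
    return float(ci.mean())


def _cp_lp(adjacency: np.ndarray) -> tuple[float, float]:
    """Clustering and harmonic path length only (fast path for null graphs)."""
    eg, _ = _efficiency_from_dist(shortest_path_lengths(adjacency))
    lp = np.inf if eg == 0 else 1.0 / eg
    return _clustering(adjacency), lp


def clustering_and_paths(g: BinaryGraph) -> GlobalMetrics:
    """Cp, Lp, Eg, Eloc and nodal efficiency of one binary graph.

    ``Lp = 1/Eg`` (harmonic mean of pairwise distances); ``Eloc`` is the
    mean over nodes of the global efficiency of each node's neighbor-induced
    subgraph (zero for nodes with fewer than two neighbors).
    """
    n = g.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes")
    a = g.adjacency
    dist = shortest_path_lengths(a)
    eg, nodal_eff = _efficiency_from_dist(dist)
    lp = np.inf if eg == 0 else 1.0 / eg
    cp = _clustering(a)

    eloc_sum = 0.0
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        eg_sub, _ = _efficiency_from_dist(shortest_path_lengths(sub))
        eloc_sum += eg_sub
    eloc = eloc_sum / n
    return GlobalMetrics(Cp=cp, Lp=lp, Eg=eg, Eloc=eloc, nodal_efficiency=nodal_eff)


def betweenness(g: BinaryGraph) -> np.ndarray:
    """Unnormalized shortest-path betweenness per node.

    Each unordered pair contributes once, with fractional credit split
    across equal-length shortest paths (Brandes' algorithm via igraph).
    """
    graph = ig.Graph(n=g.n_nodes, edges=[tuple(e) for e in g.edge_list()])
    return np.asarray(graph.betweenness(directed=False), dtype=float)


@numba.njit(cache=False)
def _swap_kernel(a, edges, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m = edges.shape[0]
    performed = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        x1, y1 = edges[e1, 0], edges[e1, 1]
        x2, y2 = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            x2, y2 = y2, x2
        # proposed rewiring: (x1,y1),(x2,y2) -> (x1,y2),(x2,y1)
        if x1 == x2 or x1 == y2 or y1 == x2 or y1 == y2:
            continue
        if a[x1, y2] or a[x2, y1]:
            continue
        a[x1, y1] = 0
        a[y1, x1] = 0
        a[x2, y2] = 0
        a[y2, x2] = 0
        a[x1, y2] = 1
        a[y2, x1] = 1
        a[x2, y1] = 1
        a[y1, x2] = 1
        edges[e1, 0] = x1
        edges[e1, 1] = y2
        edges[e2, 0] = x2
        edges[e2, 1] = y1
        performed += 1
    return performed


def rewired_null(g: BinaryGraph, n_swap_multiple: int = 10, seed: int = 0) -> BinaryGraph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``n_swap_multiple * n_edges`` swaps; each accepted swap
    replaces edges (a,b),(c,d) with (a,d),(c,b) when that creates no
    multi-edge or self-loop, leaving every node's degree unchanged. Graphs
    with fewer than 2 edges, or complete graphs (no legal swap exists), are
    returned as copies with a logged warning.
    """
    n, m = g.n_nodes, g.n_edges
    if m < 2 or m == n * (n - 1) // 2:
        logger.warning("graph not rewireable (|E|=%d, N=%d); returning copy", m, n)
        return BinaryGraph(adjacency=g.adjacency.copy(), sparsity=g.sparsity)
    a = g.adjacency.copy()
    edges = g.edge_list()
    _swap_kernel(a, edges, int(n_swap_multiple) * m, int(seed) % (2**31))
    return BinaryGraph(adjacency=a, sparsity=g.sparsity)


def small_world(
    g: BinaryGraph, n_null: int = 100, seed: int = 0, n_swap_multiple: int = 10
) -> tuple[float, float, float]:
    """Normalized clustering/path length and small-worldness.

    ``gamma = Cp / mean(Cp_null)``, ``lambda = Lp / mean(Lp_null)``,
    ``sigma = gamma / lambda`` over ``n_null`` degree-preserving rewired
    graphs. ``sigma > 1`` indicates small-world organization.
    """
    cp, lp = _cp_lp(g.adjacency)
    rng = np.random.default_rng(seed)
    cps = np.empty(n_null)
    lps = np.empty(n_null)
    for i in range(n_null):
        null = rewired_null(g, n_swap_multiple, seed=int(rng.integers(2**31)))
        cps[i], lps[i] = _cp_lp(null.adjacency)
    mean_cp, mean_lp = cps.mean(), lps.mean()
    if mean_cp == 0 or mean_lp == 0 or not np.isfinite(mean_lp):
        raise ValueError("degenerate null means; cannot normalize")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return float(gamma), float(lam), float(gamma / lam)


def metric_curves(
    w: SimilarityMatrix | np.ndarray,
    grid: SparsityGrid = SparsityGrid(),
    n_null: int = 100,
    seed: int = 0,
    subject_id: str | None = None,
    compute_betweenness: bool = True,
    compute_eloc: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All global and nodal metrics across the sparsity grid.

    Returns ``(global_df, nodal_df)`` tidy frames: one row per threshold
    (global) and one per node per threshold (nodal). Thresholds where the
    small-world index is not greater than one are logged. ``n_null``
    controls the number of rewired null graphs behind gamma/lambda.
    """
    values = w.values if isinstance(w, SimilarityMatrix) else np.asarray(w, dtype=float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    grows, nrows = [], []
    for s in grid.thresholds:
        g = threshold_by_sparsity(values, s)
        gm = clustering_and_paths(g) if compute_eloc else None
        if gm is None:
            dist = shortest_path_lengths(g.adjacency)
            eg, nodal_eff = _efficiency_from_dist(dist)
            lp = np.inf if eg == 0 else 1.0 / eg
            cp = _clustering(g.adjacency)
            eloc = np.nan
        else:
            cp, lp, eg, eloc, nodal_eff = gm.Cp, gm.Lp, gm.Eg, gm.Eloc, gm.nodal_efficiency
        gamma, lam, sigma = small_world(g, n_null=n_null, seed=int(rng.integers(2**31)))
        if sigma <= 1:
            logger.info(
                "subject %s: sigma=%.3f <= 1 at sparsity %.2f", subject_id, sigma, s
            )
        grows.append(
            {
                "subject_id": subject_id,
                "threshold": float(s),
                "Cp": cp,
                "Lp": lp,
                "gamma": gamma,
                "lambda": lam,
                "sigma": sigma,
                "Eg": eg,
                "Eloc": eloc,
            }
        )
        deg = g.degrees
        btw = betweenness(g) if compute_betweenness else np.full(n, np.nan)
        for node in range(n):
            nrows.append(
                {
                    "subject_id": subject_id,
                    "threshold": float(s),
                    "node": node,
                    "degree": float(deg[node]),
                    "efficiency": float(nodal_eff[node]),
                    "betweenness": float(btw[node]),
                }
            )
    return pd.DataFrame(grows), pd.DataFrame(nrows)


def auc(curve: np.ndarray, grid: SparsityGrid = SparsityGrid()) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid."""
    curve = np.asarray(curve, dtype=float)
    thresholds = grid.thresholds
    if curve.shape != thresholds.shape:
        raise ValueError(
            f"curve length {curve.size} does not match grid length {thresholds.size}"
        )
    return float(np.trapezoid(curve, thresholds))
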