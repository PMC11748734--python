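"""Graph topology of thresholded morphological networks.

Weighted similarity matrices are binarized by proportional (sparsity)
thresholding: the strongest ``s * N(N-1)/2`` edges are kept.  Small-world
parameters — clustering coefficient Cp and characteristic path length Lp —
are normalized against degree-preserving rewired null networks, and
summarized across a sparsity range by the area under each curve.

The lower end of the usable sparsity range is set by an estimability
criterion on the average degree: a sparsity s is estimable when
``s * (N - 1) >= ln(N)``, which for the 58-node gyral and 62-node sulcal
networks gives minima of 0.071 and 0.068.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BinaryGraph",
    "SmallWorldResult",
    "DEFAULT_SPARSITIES",
    "max_edges",
    "min_estimable_sparsity",
    "proportional_threshold",
    "clustering_coefficient",
    "characteristic_path_length",
    "rewire_preserving_degree",
    "normalized_small_world",
    "sparsity_sweep",
    "curve_auc",
]

DEFAULT_SPARSITIES = np.round(np.arange(8, 41, 2) / 100.0, 2)


@dataclass
class BinaryGraph:
    """Undirected binary graph: symmetric 0/1 adjacency, no self-loops."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def sparsity(self) -> float:
        return self.n_edges / max_edges(self.n_nodes)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)


def max_edges(n: int) -> int:
    """Maximum possible edge count of an undirected graph: N(N-1)/2."""
    if n < 1:
        raise ValueError("need at least one node")
    return n * (n - 1) // 2


def min_estimable_sparsity(n: int) -> float:
    """Smallest sparsity at which small-world metrics are estimable.

    Requires the average degree ``s * (N - 1)`` to reach ``ln(N)``; the
    bound ``ln(N) / (N - 1)`` is returned rounded to 3 decimals.
    """
    if n < 3:
        raise ValueError("criterion needs at least 3 nodes")
    return round(math.log(n) / (n - 1), 3)


def proportional_threshold(w: np.ndarray, s: float) -> BinaryGraph:
    """Keep the ``round(s * N(N-1)/2)`` strongest unique edges of ``w``.

    Ties at the cutoff are broken by ascending (i, j) node index, making
    the edge sets at nested sparsities themselves nested and the output
    deterministic.  Edge-count rounding is half-away-from-zero.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.all(np.isfinite(w)):
        raise ValueError("weight matrix must be finite")
    if not np.allclose(w, w.T, rtol=0, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if not 0 < s <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n = w.shape[0]
    m_target = int(math.floor(s * max_edges(n) + 0.5))
    if m_target < 1:
        raise ValueError(f"sparsity {s} retains zero edges on {n} nodes")
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    # lexsort: last key is primary -> sort by descending weight, then i, then j
    order = np.lexsort((ju, iu, -weights))[:m_target]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[order], ju[order]] = 1
    a |= a.T
    return BinaryGraph(adjacency=a)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean nodal clustering: closed triangles over possible triangles.

    Nodes with degree < 2 contribute 0 to the average.
    """
    a = g.adjacency.astype(float)
    if g.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    deg = a.sum(axis=0)
    triangles = np.diag(a @ a @ a)  # 2 * closed triangles through each node
    possible = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return float(c.mean())


def characteristic_path_length(g: BinaryGraph) -> tuple[float, bool]:
    """Mean shortest-path length over reachable unordered node pairs.

    Returns ``(lp, disconnected)``.  When the graph is disconnected the
    mean is taken over reachable pairs only and the flag is set, keeping
    the value finite across a sparsity sweep.
    """
    if g.n_nodes < 2:
        raise ValueError("path length needs at least 2 nodes")
    if g.n_edges == 0:
        raise ValueError("path length undefined on an edgeless graph")
    d = shortest_path(csr_matrix(g.adjacency), method="D", unweighted=True)
    iu = np.triu_indices(g.n_nodes, k=1)
    dist = d[iu]
    finite = np.isfinite(dist)
    disconnected = bool(~finite.all())
    return float(dist[finite].mean()), disconnected


def rewire_preserving_degree(
    g: BinaryGraph, n_swaps: int, seed: int | None = None
) -> BinaryGraph:
    """Degree-preserving null network by repeated double-edge swaps.

    The degree sequence of the output is identical to the input's.  If no
    valid swap can be performed within the attempt budget (e.g. a complete
    graph), the input is returned unchanged with a warning.
    """
    if n_swaps < 1:
        raise ValueError("need at least one swap")
    graph = nx.from_numpy_array(g.adjacency)
    try:
        nx.double_edge_swap(
            graph, nswap=n_swaps, max_tries=max(100 * n_swaps, 1000), seed=seed
        )
    except nx.NetworkXException as exc:
        warnings.warn(
            f"rewiring fell back to the input graph: {exc}",
            UserWarning,
            stacklevel=2,
        )
        return BinaryGraph(adjacency=g.adjacency.copy())
    a = nx.to_numpy_array(graph, nodelist=range(g.n_nodes), dtype=np.int8)
    return BinaryGraph(adjacency=a)


def _null_metrics(
    g: BinaryGraph, n_null: int, seed: int | None, swaps_per_edge: int = 10
) -> tuple[float, float]:
    n_swaps = max(swaps_per_edge * g.n_edges, 1)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_null)
    cps, lps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s in child_seeds:
            null = rewire_preserving_degree(g, n_swaps, seed=int(s))
            cps.append(clustering_coefficient(null))
            lps.append(characteristic_path_length(null)[0])
    return float(np.mean(cps)), float(np.mean(lps))


def normalized_small_world(
    g: BinaryGraph, n_null: int = 100, seed: int | None = None
) -> tuple[float, float]:
    """Normalized small-world parameters (gamma, lambda).

    gamma = Cp / mean(Cp over rewired nulls), lambda = Lp / mean(Lp over
    nulls); each null uses a swap budget of 10 swaps per edge.  A
    small-world network has gamma > 1 with lambda close to 1.
    """
    cp = clustering_coefficient(g)
    lp, _ = characteristic_path_length(g)
    cp_rand, lp_rand = _null_metrics(g, n_null, seed)
    if cp_rand == 0:
        raise ZeroDivisionError("null clustering is zero; gamma undefined")
    return cp / cp_rand, lp / lp_rand


@dataclass
class SmallWorldResult:
    """Per-sparsity small-world curves and their AUC summaries."""

    sparsities: np.ndarray
    cp: np.ndarray
    lp: np.ndarray
    cp_rand: np.ndarray
    lp_rand: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    disconnected: np.ndarray
    auc: dict[str, float] = field(default_factory=dict)


def sparsity_sweep(
    w: np.ndarray,
    sparsities: np.ndarray | None = None,
    n_null: int = 100,
    seed: int | None = None,
) -> SmallWorldResult:
    """Threshold ``w`` at each sparsity and compute normalized metrics.

    Defaults to the range 0.08 to 0.40 in steps of 0.02 (17 thresholds).
    Returns raw and normalized curves plus trapezoidal AUCs.
    """
    if sparsities is None:
        sparsities = DEFAULT_SPARSITIES
    sparsities = np.asarray(sparsities, dtype=float)
    seeds = np.random.SeedSequence(seed).generate_state(len(sparsities))
    cp = np.empty(len(sparsities))
    lp = np.empty(len(sparsities))
    cpr = np.empty(len(sparsities))
    lpr = np.empty(len(sparsities))
    flags = np.zeros(len(sparsities), dtype=bool)
    for k, s in enumerate(sparsities):
        g = proportional_threshold(w, s)
        cp[k] = clustering_coefficient(g)
        lp[k], flags[k] = characteristic_path_length(g)
        cpr[k], lpr[k] = _null_metrics(g, n_null, int(seeds[k]))
    if np.any(cpr == 0):
        warnings.warn(
            "null clustering is zero at some sparsities; gamma reported as NaN there",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(cpr > 0, cp / cpr, np.nan)
    lam = lp / lpr
    auc = {
        "cp": curve_auc(cp, sparsities),
        "lp": curve_auc(lp, sparsities),
        "gamma": curve_auc(gamma, sparsities),
        "lambda": curve_auc(lam, sparsities),
    }
    return SmallWorldResult(
        sparsities=sparsities,
        cp=cp,
        lp=lp,
        cp_rand=cpr,
        lp_rand=lpr,
        gamma=gamma,
        lam=lam,
        disconnected=flags,
        auc=auc,
    )


def curve_auc(values: np.ndarray, sparsities: np.ndarray) -> float:
    """Trapezoidal area under a metric-vs-sparsity curve."""
    values = np.asarray(values, dtype=float)
    sparsities = np.asarray(sparsities, dtype=float)
    if values.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(sparsities) <= 0):
        raise ValueError("sparsities must be strictly increasing")
    return float(np.trapezoid(values, sparsities))
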