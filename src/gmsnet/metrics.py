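"""Graph-theoretic characterization across a sparsity grid.

Each subject's weighted region network is binarized at every sparsity level
S of a grid (default 0.10 to 0.34 in steps of 0.01: 25 levels) by keeping the
S * n(n-1)/2 strongest positive weights.  At each level the small-world
parameters (clustering coefficient Cp, characteristic path length Lp), the
efficiency parameters (global Eglob, local Eloc), and the nodal centralities
(degree kappa, nodal efficiency e) are computed on the binary graph.  Cp and
Lp are normalized by the means of an ensemble of degree-preserving rewired
random networks (default 100), giving gamma = Cp/C_random,
lambda = Lp/L_random, and the small-world scalar sigma = gamma/lambda.
Curves over the grid are summarized by their trapezoidal area under the
curve (AUC), avoiding an arbitrary single-threshold choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .atlas import RegionNetwork

__all__ = [
    "SparsityGrid",
    "BinaryGraph",
    "GlobalMetrics",
    "NodalMetrics",
    "RandomEnsembleConfig",
    "threshold_at_sparsity",
    "compute_global_metrics",
    "compute_nodal_metrics",
    "rewire_random",
    "normalize_small_world",
    "auc_over_grid",
    "metric_curves",
    "auc_summary",
]


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity levels for network thresholding."""

    values: tuple[float, ...] = tuple(round(0.10 + 0.01 * i, 2) for i in range(25))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 1 or np.any(np.diff(v) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError("sparsity levels must lie in (0, 1)")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class BinaryGraph:
    """Binarized instance of a region network at one sparsity level."""

    adjacency: np.ndarray      # symmetric 0/1, zero diagonal
    sparsity_target: float
    sparsity_actual: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    connected: bool = True
    C_random: float | None = None
    L_random: float | None = None
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None


@dataclass
class NodalMetrics:
    degree: np.ndarray       # kappa, per-node edge count
    efficiency: np.ndarray   # e, per-node mean inverse shortest path


@dataclass(frozen=True)
class RandomEnsembleConfig:
    n_random: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")


def threshold_at_sparsity(
    network: RegionNetwork | np.ndarray, sparsity: float
) -> BinaryGraph:
    """Keep the round-half-up(S * n(n-1)/2) strongest positive weights.

    Ties are broken by weight descending, then (row, col) ascending, so the
    selection is fully deterministic and the edge set at sparsity S is a
    subset of the edge set at any larger S.  If fewer positive weights exist
    than requested, all of them are kept and the achieved sparsity recorded.
    """
    if not 0.0 < sparsity < 1.0:
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    w = network.weights if isinstance(network, RegionNetwork) else np.asarray(network)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    n_pairs = vals.size
    m_target = int(np.floor(sparsity * n_pairs + 0.5))  # round half up
    pos = vals > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        warnings.warn("all-zero network: empty binary graph", stacklevel=2)
        return BinaryGraph(
            adjacency=np.zeros((n, n), dtype=np.int8),
            sparsity_target=float(sparsity),
            sparsity_actual=0.0,
        )
    order = np.lexsort((ju, iu, -vals))
    m_keep = min(m_target, n_pos)
    sel = order[:m_keep]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[sel], ju[sel]] = 1
    adj[ju[sel], iu[sel]] = 1
    return BinaryGraph(
        adjacency=adj,
        sparsity_target=float(sparsity),
        sparsity_actual=m_keep / n_pairs,
    )


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(adj.astype(np.float64)), unweighted=True)


def _clustering_mean(adj: np.ndarray) -> float:
    a = adj.astype(np.float64)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2x triangles per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return float(c.mean()) if c.size else 0.0


def _efficiency_from_distances(d: np.ndarray) -> float:
    """Mean of 1/d over all ordered off-diagonal pairs (1/inf = 0)."""
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def compute_global_metrics(graph: BinaryGraph) -> GlobalMetrics:
    """Cp, Lp, Eglob, Eloc of a binary graph.

    Lp averages over connected ordered pairs only; a disconnection is flagged
    rather than propagated as an infinity.  An edgeless graph yields zeros
    with Lp marked undefined (NaN).
    """
    adj = graph.adjacency
    n = graph.n_nodes
    if graph.n_edges == 0:
        return GlobalMetrics(Cp=0.0, Lp=float("nan"), Eglob=0.0, Eloc=0.0,
                             connected=False)
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    connected = bool(finite.sum() == n * (n - 1))
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    eglob = _efficiency_from_distances(d)
    cp = _clustering_mean(adj)
    eloc_terms = np.zeros(n)
    for i in range(n):
        nbr = np.flatnonzero(adj[i])
        if nbr.size < 2:
            continue
        sub = adj[np.ix_(nbr, nbr)]
        eloc_terms[i] = _efficiency_from_distances(_distances(sub))
    return GlobalMetrics(Cp=cp, Lp=lp, Eglob=eglob, Eloc=float(eloc_terms.mean()),
                         connected=connected)


def compute_nodal_metrics(graph: BinaryGraph) -> NodalMetrics:
    """Nodal degree kappa and nodal efficiency e per region."""
    adj = graph.adjacency
    n = graph.n_nodes
    deg = adj.sum(axis=1).astype(np.int64)
    if graph.n_edges == 0:
        return NodalMetrics(degree=deg, efficiency=np.zeros(n))
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / max(n - 1, 1)
    return NodalMetrics(degree=deg, efficiency=eff)


def _double_edge_swap(
    edges: np.ndarray, nswap: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Maslov-Sneppen rewiring on an edge array.

    Repeatedly picks two edges (a, b), (c, d) and proposes (a, d), (c, b),
    rejecting self-loops and multi-edges; degrees are invariant.  Returns the
    rewired edge array and the number of accepted swaps.
    """
    m = edges.shape[0]
    elist = [tuple(e) for e in edges]
    eset = {frozenset(e) for e in elist}
    accepted = 0
    tries_budget = nswap * 20
    # draw candidate indices in bulk; refill if the budget allows
    while accepted < nswap and tries_budget > 0:
        chunk = min(tries_budget, 4 * nswap)
        picks = rng.integers(0, m, size=(chunk, 2))
        sides = rng.integers(0, 2, size=chunk)
        for (e1, e2), flip in zip(picks, sides):
            tries_budget -= 1
            if e1 == e2:
                continue
            a, b = elist[e1]
            c, d = elist[e2]
            if flip:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            new1, new2 = frozenset((a, d)), frozenset((c, b))
            if new1 in eset or new2 in eset:
                continue
            eset.discard(frozenset((a, b)))
            eset.discard(frozenset((c, d)))
            eset.add(new1)
            eset.add(new2)
            elist[e1] = (a, d)
            elist[e2] = (c, b)
            accepted += 1
            if accepted >= nswap:
                break
        if accepted >= nswap:
            break
    return np.asarray(elist, dtype=np.intp), accepted


def rewire_random(
    graph: BinaryGraph, config: RandomEnsembleConfig
) -> list[BinaryGraph]:
    """Degree-preserving random ensemble via repeated double-edge swaps.

    Every member has exactly the input's degree sequence (swaps that would
    create self-loops or multi-edges are rejected by construction).  Graphs
    too small to swap are returned as unmodified copies with a warning.
    """
    m = graph.n_edges
    if m < 2:
        warnings.warn("graph has < 2 edges; ensemble is copies", stacklevel=2)
        return [
            BinaryGraph(graph.adjacency.copy(), graph.sparsity_target,
                        graph.sparsity_actual)
            for _ in range(config.n_random)
        ]
    iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
    edges0 = np.stack([iu, ju], axis=1)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_random)
    out: list[BinaryGraph] = []
    nswap = config.rewires_per_edge * m
    for s in seeds:
        rng = np.random.default_rng(int(s))
        edges, accepted = _double_edge_swap(edges0, nswap, rng)
        if accepted == 0:
            warnings.warn("no swap possible; ensemble member is a copy",
                          stacklevel=2)
        adj = np.zeros_like(graph.adjacency)
        adj[edges[:, 0], edges[:, 1]] = 1
        adj[edges[:, 1], edges[:, 0]] = 1
        out.append(BinaryGraph(adj, graph.sparsity_target, graph.sparsity_actual))
    return out


def normalize_small_world(
    graph_metrics: GlobalMetrics, ensemble: list[BinaryGraph]
) -> GlobalMetrics:
    """Fill C_random, L_random, gamma, lambda, and sigma = gamma/lambda."""
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    cs, ls = [], []
    for g in ensemble:
        if g.n_edges == 0:
            continue
        d = _distances(g.adjacency)
        off = ~np.eye(g.n_nodes, dtype=bool)
        finite = np.isfinite(d) & off
        ls.append(float(d[finite].mean()) if finite.any() else np.nan)
        cs.append(_clustering_mean(g.adjacency))
    c_rand = float(np.nanmean(cs)) if cs else 0.0
    l_rand = float(np.nanmean(ls)) if ls else 0.0
    gm = graph_metrics
    if c_rand == 0.0 or l_rand == 0.0 or not np.isfinite(l_rand):
        warnings.warn("degenerate random ensemble; normalized metrics undefined",
                      stacklevel=2)
        return GlobalMetrics(gm.Cp, gm.Lp, gm.Eglob, gm.Eloc, gm.connected,
                             c_rand, l_rand, float("nan"), float("nan"),
                             float("nan"))
    gamma = gm.Cp / c_rand
    lam = gm.Lp / l_rand
    sigma = gamma / lam if lam != 0 else float("nan")
    return GlobalMetrics(gm.Cp, gm.Lp, gm.Eglob, gm.Eloc, gm.connected,
                         c_rand, l_rand, gamma, lam, sigma)


def auc_over_grid(curve: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid."""
    c = np.asarray(curve, dtype=float)
    if c.size != len(grid):
        raise ValueError(f"curve length {c.size} != grid length {len(grid)}")
    return float(np.trapezoid(c, grid.array))


GLOBAL_METRIC_NAMES = ("Eglob", "Eloc", "Cp", "Lp", "gamma", "lambda", "sigma")


def metric_curves(
    network: RegionNetwork | np.ndarray,
    grid: SparsityGrid | None = None,
    ensemble_config: RandomEnsembleConfig | None = None,
) -> dict[str, np.ndarray]:
    """Global and nodal metric curves for one subject across the grid.

    Returns a dict with the seven global curves (length = grid) and nodal
    ``degree`` / ``nodal_efficiency`` arrays of shape (n_regions, len(grid)).
    Normalized metrics are NaN when no ensemble_config is given.
    """
    if grid is None:
        grid = SparsityGrid()
    if ensemble_config is None:
        ensemble_config = RandomEnsembleConfig()
    w = network.weights if isinstance(network, RegionNetwork) else np.asarray(network)
    n = w.shape[0]
    nlev = len(grid)
    out: dict[str, np.ndarray] = {k: np.full(nlev, np.nan) for k in GLOBAL_METRIC_NAMES}
    out["degree"] = np.zeros((n, nlev))
    out["nodal_efficiency"] = np.zeros((n, nlev))
    seeds = np.random.SeedSequence(ensemble_config.seed).generate_state(nlev)
    for li, s in enumerate(grid.values):
        bg = threshold_at_sparsity(w, s)
        gm = compute_global_metrics(bg)
        ens = rewire_random(
            bg,
            RandomEnsembleConfig(
                n_random=ensemble_config.n_random,
                rewires_per_edge=ensemble_config.rewires_per_edge,
                seed=int(seeds[li]),
            ),
        )
        gm = normalize_small_world(gm, ens)
        nm = compute_nodal_metrics(bg)
        out["Eglob"][li] = gm.Eglob
        out["Eloc"][li] = gm.Eloc
        out["Cp"][li] = gm.Cp
        out["Lp"][li] = gm.Lp
        out["gamma"][li] = gm.gamma
        out["lambda"][li] = gm.lam
        out["sigma"][li] = gm.sigma
        out["degree"][:, li] = nm.degree
        out["nodal_efficiency"][:, li] = nm.efficiency
    return out


def auc_summary(
    curves: dict[str, np.ndarray], grid: SparsityGrid | None = None
) -> dict[str, float | np.ndarray]:
    """AUC scalars for the global curves and per-node AUC vectors."""
    if grid is None:
        grid = SparsityGrid()
    out: dict[str, float | np.ndarray] = {}
    for name in GLOBAL_METRIC_NAMES:
        out[name] = auc_over_grid(curves[name], grid)
    x = grid.array
    out["degree"] = np.trapezoid(curves["degree"], x, axis=1)
    out["nodal_efficiency"] = np.trapezoid(curves["nodal_efficiency"], x, axis=1)
    return out
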