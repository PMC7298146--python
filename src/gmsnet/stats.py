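"""Three-group statistics on network metrics.

AUC-summarized metrics are compared with a one-way ANOVA followed by pooled
two-sample post hoc t tests; nodal families are Bonferroni-corrected.  Edge
weights among nodes with aberrant centralities are Fisher z-transformed and
compared pairwise between groups with the network-based statistic (NBS):
edges whose |t| exceeds a primary threshold form a suprathreshold graph whose
connected components are assigned family-wise-error-corrected p-values by
permuting group labels and recording the maximal null component extent.
Metric-symptom associations are assessed with partial correlations adjusting
for age, sex, and education.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_array
from scipy.sparse.csgraph import connected_components

from .errors import CollinearityError

__all__ = [
    "NBSConfig",
    "NBSResult",
    "PartialCorrelationResult",
    "anova_oneway",
    "posthoc_t",
    "bonferroni_flags",
    "select_aberrant_nodes",
    "fisher_z",
    "nbs",
    "partial_correlation",
]


@dataclass(frozen=True)
class NBSConfig:
    t_threshold: float = 3.1
    n_permutations: int = 5_000
    alpha: float = 0.05
    component_measure: str = "extent"

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.component_measure != "extent":
            raise ValueError("only extent-based components are supported")


@dataclass
class NBSResult:
    components: list[np.ndarray]      # each (m, 2) array of node-index pairs
    extents: list[int]
    fwe_p: list[float]
    null_max_extents: np.ndarray
    edge_t: np.ndarray                # per-edge t statistics (input order)
    component_t: list[np.ndarray] = field(default_factory=list)


@dataclass
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    covariate_names: tuple[str, ...]


def anova_oneway(*groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way F test across k groups, df = (k-1, N-k)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(a) == 0 for a in arrs) and len({a[0] for a in arrs}) == 1:
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrs)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(f), float(p)


def posthoc_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t with a two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):  # zero pooled variance
        return (0.0, 1.0) if a.mean() == b.mean() else (float(np.sign(a.mean() - b.mean()) * np.inf), 0.0)
    return float(t), float(p)


def bonferroni_flags(
    p_values: np.ndarray, alpha: float = 0.05, family_size: int | None = None
) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected level alpha/family."""
    p = np.asarray(p_values, dtype=float)
    if family_size is None:
        family_size = p.size
    if family_size < p.size:
        raise ValueError("family_size must cover all tests")
    return p < alpha / family_size


def select_aberrant_nodes(
    p_degree: np.ndarray,
    p_efficiency: np.ndarray,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> np.ndarray:
    """Nodes whose corrected ANOVA is significant in at least one centrality.

    Each nodal metric (degree, nodal efficiency) is corrected as its own
    family; the union of significant nodes is returned as sorted indices.
    """
    fd = bonferroni_flags(p_degree, alpha, family_size)
    fe = bonferroni_flags(p_efficiency, alpha, family_size)
    return np.flatnonzero(fd | fe)


def fisher_z(weight: np.ndarray | float) -> np.ndarray | float:
    """atanh variance-stabilization; weights at 1 are clipped to 1 - 1e-6."""
    w = np.clip(np.asarray(weight, dtype=float), None, 1.0 - 1e-6)
    out = np.arctanh(w)
    return float(out) if np.isscalar(weight) else out


def _tstats(x: np.ndarray, in_a: np.ndarray, in_b: np.ndarray) -> np.ndarray:
    """Pooled two-sample t per column of x (subjects x features)."""
    na, nb = int(in_a.sum()), int(in_b.sum())
    xa, xb = x[in_a], x[in_b]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    diff = ma - mb
    t[(denom == 0) & (diff == 0)] = 0.0
    t[(denom == 0) & (diff != 0)] = np.sign(diff[(denom == 0) & (diff != 0)]) * np.inf
    return t


def _max_component_extent(
    supra: np.ndarray, edges: np.ndarray, n_nodes: int
) -> int:
    if not supra.any():
        return 0
    e = edges[supra]
    adj = coo_array(
        (np.ones(e.shape[0]), (e[:, 0], e[:, 1])), shape=(n_nodes, n_nodes)
    )
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[e[:, 0]]
    return int(np.bincount(comp_of_edge).max())


def nbs(
    edge_values: np.ndarray,
    labels: np.ndarray,
    edges: np.ndarray,
    n_nodes: int,
    config: NBSConfig | None = None,
    seed: int = 0,
) -> NBSResult:
    """Network-based statistic for a two-group edge-wise comparison.

    Parameters
    ----------
    edge_values
        (n_subjects, n_edges) matrix of Fisher-z edge weights.
    labels
        Group label per subject; exactly two distinct labels.
    edges
        (n_edges, 2) node-index pairs aligned with edge_values columns.
    n_nodes
        Number of nodes the edge indices refer to.

    Per-edge pooled t statistics are computed; edges with |t| above the
    primary threshold form the suprathreshold graph, whose connected
    components are candidate effects.  The FWE p of a component of extent m
    is (1 + #{permutations with max null extent >= m}) / (n_permutations+1).
    """
    if config is None:
        config = NBSConfig()
    x = np.asarray(edge_values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"nbs requires exactly two groups, got {uniq.size}")
    in_a = labels == uniq[0]
    in_b = labels == uniq[1]
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs n >= 2")
    edges = np.asarray(edges, dtype=np.intp)
    if x.shape[1] != edges.shape[0]:
        raise ValueError("edge_values columns must align with edges")
    if x.shape[1] == 0:
        raise ValueError("edge set is empty")

    t_obs = _tstats(x, in_a, in_b)
    supra = np.abs(t_obs) > config.t_threshold

    components: list[np.ndarray] = []
    extents: list[int] = []
    comp_t: list[np.ndarray] = []
    if supra.any():
        e = edges[supra]
        te = t_obs[supra]
        adj = coo_array(
            (np.ones(e.shape[0]), (e[:, 0], e[:, 1])), shape=(n_nodes, n_nodes)
        )
        _, node_labels = connected_components(adj, directed=False)
        comp_ids = node_labels[e[:, 0]]
        for cid in np.unique(comp_ids):
            sel = comp_ids == cid
            components.append(e[sel])
            extents.append(int(sel.sum()))
            comp_t.append(te[sel])

    rng = np.random.default_rng(seed)
    null_max = np.zeros(config.n_permutations, dtype=np.int64)
    for b in range(config.n_permutations):
        perm = rng.permutation(labels.size)
        tp = _tstats(x, in_a[perm], in_b[perm])
        null_max[b] = _max_component_extent(
            np.abs(tp) > config.t_threshold, edges, n_nodes
        )

    fwe = [
        float((1 + int((null_max >= m).sum())) / (config.n_permutations + 1))
        for m in extents
    ]
    return NBSResult(
        components=components,
        extents=extents,
        fwe_p=fwe,
        null_max_extents=null_max,
        edge_t=t_obs,
        component_t=comp_t,
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    covariate_names: tuple[str, ...] = ("age", "sex", "education"),
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after linear covariate adjustment.

    Both variables are residualized against the covariates (with intercept);
    the p-value uses a t reference with n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.size:
        cov = cov.T
    n, k = cov.shape
    if x.size != n or y.size != n:
        raise ValueError("x, y, covariates must share the subject dimension")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 subjects (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate design matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return PartialCorrelationResult(0.0, 1.0, n, covariate_names)
    r = float(np.clip(np.dot(rx, ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return PartialCorrelationResult(r, 0.0, n, covariate_names)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(r, p, n, covariate_names)
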