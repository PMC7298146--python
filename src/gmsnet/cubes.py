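"""Single-subject cube-correlation similarity graphs.

The subject's gray-matter volume is tiled into non-overlapping, axis-aligned
3x3x3-voxel cubes (keeping the 3D structure of the cortex intact).  Structural
similarity between two cubes is the Pearson correlation of their 27-voxel
value vectors, optionally maximized over the 24 proper rotations of one cube.
The similarity matrix is binarized at a subject-specific threshold chosen with
a permutation null (within-cube value shuffling destroys spatial structure) so
that the expected fraction of chance edges among retained edges stays below a
target rate (default 5%).  Only positive correlations survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .errors import DegenerateCubesError, EmptyCubeSetError, NoValidThresholdError
from .synthetic import GMVolume

__all__ = [
    "CubeSet",
    "NullDistribution",
    "CubeGraph",
    "extract_cubes",
    "cube_correlation",
    "estimate_null_distribution",
    "determine_threshold",
    "build_cube_graph",
    "estimate_spurious_rate",
]

CUBE_SIDE = 3
CUBE_VOXELS = CUBE_SIDE**3
MIN_NULL_PAIRS = 10_000
# z-score for the upper confidence bound on the Monte-Carlo null tail used
# during threshold selection; guards the <target_rate guarantee against
# sampling error in the permutation null
NULL_TAIL_Z = 3.0


def _rotation_permutations() -> np.ndarray:
    """Index permutations of a flattened 3x3x3 block under the 24 proper
    rotations of the cube (signed permutation matrices with det +1)."""
    coords = np.array(list(product([-1, 0, 1], repeat=3)))  # C-order ravel
    perms = []
    for p in permutations(range(3)):
        for signs in product([1, -1], repeat=3):
            mat = np.zeros((3, 3), dtype=int)
            for row, (col, s) in enumerate(zip(p, signs)):
                mat[row, col] = s
            if round(np.linalg.det(mat)) != 1:
                continue
            src = coords @ mat  # source coord for each output position
            idx = (src[:, 0] + 1) * 9 + (src[:, 1] + 1) * 3 + (src[:, 2] + 1)
            perms.append(idx)
    out = np.array(perms, dtype=np.intp)
    assert out.shape == (24, 27)
    return out

ROTATION_PERMS = _rotation_permutations()


@dataclass
class CubeSet:
    """Non-overlapping 3x3x3 cubes retained from one subject's volume."""

    values: np.ndarray          # (n_cubes, 27) gray-matter probabilities
    origins: np.ndarray         # (n_cubes, 3) voxel coordinates of each cube
    gm_fraction: np.ndarray     # (n_cubes,) fraction of the 27 voxels in-mask
    grid_shape: tuple[int, int, int]
    subject_id: str | None = None

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def cube_ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.intp)

    @property
    def zero_variance(self) -> np.ndarray:
        # constant cubes: ptp is exact where fp round-off makes std() tiny
        return np.ptp(self.values, axis=1) == 0.0


@dataclass
class NullDistribution:
    samples: np.ndarray
    n_samples: int
    seed: int


@dataclass
class CubeGraph:
    """Binarized similarity graph with its subject-specific threshold."""

    n_cubes: int
    edges: np.ndarray               # (n_edges, 2) cube-id pairs, i < j
    threshold: float
    spurious_rate_estimate: float
    n_valid_cubes: int = 0
    edge_correlations: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cubes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


def _block_view(arr: np.ndarray) -> np.ndarray:
    """(n_cubes, 27) view of complete 3x3x3 blocks, lexicographic by origin."""
    a, b, c = (s // CUBE_SIDE for s in arr.shape)
    crop = arr[: a * CUBE_SIDE, : b * CUBE_SIDE, : c * CUBE_SIDE]
    blocks = crop.reshape(a, CUBE_SIDE, b, CUBE_SIDE, c, CUBE_SIDE)
    return blocks.transpose(0, 2, 4, 1, 3, 5).reshape(a * b * c, CUBE_VOXELS)


def extract_cubes(volume: GMVolume, min_gm_fraction: float = 0.5) -> CubeSet:
    """Tile the volume into cubes and keep those sufficiently inside the mask.

    Tiling starts at voxel (0, 0, 0) in steps of 3; trailing partial slabs are
    dropped.  Cube order is lexicographic by grid origin.
    """
    shape = volume.values.shape
    if any(s < CUBE_SIDE for s in shape):
        raise EmptyCubeSetError(f"volume shape {shape} smaller than one cube")
    vals = _block_view(volume.values)
    frac = _block_view(volume.brain_mask.astype(np.float64)).mean(axis=1)
    a, b, c = (s // CUBE_SIDE for s in shape)
    ii, jj, kk = np.unravel_index(np.arange(a * b * c), (a, b, c))
    origins = np.stack([ii, jj, kk], axis=1) * CUBE_SIDE
    keep = frac >= min_gm_fraction
    if not keep.any():
        raise EmptyCubeSetError(
            f"no cube reaches gm_fraction >= {min_gm_fraction}"
        )
    return CubeSet(
        values=np.ascontiguousarray(vals[keep]),
        origins=origins[keep].astype(np.intp),
        gm_fraction=frac[keep],
        grid_shape=tuple(shape),
    )


def cube_correlation(
    values_a: np.ndarray, values_b: np.ndarray, rotation_mode: str = "none"
) -> float:
    """Pearson similarity of two cubes; NaN marks a zero-variance cube.

    With ``rotation_mode="max_over_rotations"`` the maximum correlation over
    the 24 proper rotations of cube B's 3x3x3 value block is returned.
    """
    a = np.asarray(values_a, dtype=np.float64).ravel()
    b = np.asarray(values_b, dtype=np.float64).ravel()
    if a.size != CUBE_VOXELS or b.size != CUBE_VOXELS:
        raise ValueError("cube value vectors must have length 27")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    sa, sb = a.std(), b.std()
    az = (a - a.mean()) / sa
    bz = (b - b.mean()) / sb
    if rotation_mode == "none":
        return float(np.dot(az, bz) / CUBE_VOXELS)
    if rotation_mode == "max_over_rotations":
        return float((bz[ROTATION_PERMS] @ az).max() / CUBE_VOXELS)
    raise ValueError(f"unknown rotation_mode {rotation_mode!r}")


def _standardized_valid(cubeset: CubeSet) -> tuple[np.ndarray, np.ndarray]:
    valid = ~cubeset.zero_variance
    v = cubeset.values[valid]
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
    return z, np.flatnonzero(valid)


def estimate_null_distribution(
    cubeset: CubeSet, n_pairs: int = 100_000, seed: int = 0
) -> NullDistribution:
    """Null similarity of spatially structureless cubes.

    Samples random cube pairs and randomly permutes the 27 values of one
    member before correlating, which preserves the value histogram but
    destroys the spatial arrangement the similarity measure relies on.
    """
    if len(cubeset) < 2:
        raise DegenerateCubesError("need at least 2 cubes for a null")
    if n_pairs < MIN_NULL_PAIRS:
        warnings.warn(
            f"n_pairs={n_pairs} < {MIN_NULL_PAIRS}: null tail may be unstable",
            stacklevel=2,
        )
    z, valid_idx = _standardized_valid(cubeset)
    if z.shape[0] < 2:
        raise DegenerateCubesError(
            "all cubes have zero variance; empty null distribution"
        )
    rng = np.random.default_rng(seed)
    n = z.shape[0]
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    clash = i == j
    while clash.any():
        j[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = i == j
    b = z[j]
    perm = np.argsort(rng.random((n_pairs, CUBE_VOXELS)), axis=1)
    b = np.take_along_axis(b, perm, axis=1)
    samples = np.einsum("ij,ij->i", z[i], b) / CUBE_VOXELS
    return NullDistribution(samples=samples, n_samples=n_pairs, seed=int(seed))


def _correlation_matrix(z: np.ndarray, rotation_mode: str) -> np.ndarray:
    if rotation_mode == "none":
        return (z @ z.T) / CUBE_VOXELS
    if rotation_mode == "max_over_rotations":
        r = np.full((z.shape[0], z.shape[0]), -np.inf)
        for perm in ROTATION_PERMS:
            np.maximum(r, z @ z[:, perm].T / CUBE_VOXELS, out=r)
        return r
    raise ValueError(f"unknown rotation_mode {rotation_mode!r}")


def pairwise_correlations(
    cubeset: CubeSet, rotation_mode: str = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """Full correlation matrix over non-degenerate cubes.

    Returns ``(R, valid_idx)`` where ``R`` is the correlation matrix among
    valid cubes and ``valid_idx`` maps its rows back to cube ids.
    """
    z, valid_idx = _standardized_valid(cubeset)
    return _correlation_matrix(z, rotation_mode), valid_idx


def determine_threshold(
    cubeset: CubeSet,
    null: NullDistribution,
    target_rate: float = 0.05,
    rotation_mode: str = "none",
    keep_correlations: bool = False,
) -> CubeGraph:
    """Binarize the similarity matrix at the subject-specific threshold.

    The threshold r* is the smallest observed correlation value such that

        E[chance edges at r*] / observed edges at r*  <  target_rate,

    with E[chance edges at r*] = P(null > r*) x (number of cube pairs).
    Because P(null > r*) is itself a Monte-Carlo estimate, selection uses an
    upper confidence bound on the null tail (NULL_TAIL_Z standard errors plus
    one resolution unit), so the spurious-rate guarantee holds under
    independent re-estimation rather than only in expectation.  Only strictly
    positive thresholds are admissible, so every retained edge has a positive
    correlation.  The reported ``spurious_rate_estimate`` is the point
    estimate at r*.
    """
    rmat, valid_idx = pairwise_correlations(cubeset, rotation_mode)
    n = rmat.shape[0]
    if n < 2:
        raise NoValidThresholdError("fewer than 2 non-degenerate cubes")
    iu, ju = np.triu_indices(n, k=1)
    robs = rmat[iu, ju]
    n_total_pairs = robs.size

    null_sorted = np.sort(null.samples)
    order = np.argsort(robs)           # ascending
    obs_sorted = robs[order]
    # candidate thresholds = observed values; with >= edge semantics,
    # observed edge count at obs_sorted[k] is n_total_pairs - k
    observed_counts = n_total_pairs - np.arange(n_total_pairs)
    n_null = null_sorted.size
    tail = n_null - np.searchsorted(null_sorted, obs_sorted, side="right")
    p_tail = tail / n_null
    p_upper = (
        p_tail
        + NULL_TAIL_Z * np.sqrt(p_tail * (1.0 - p_tail) / n_null)
        + 1.0 / n_null
    )
    ratio_ub = (p_upper * n_total_pairs) / observed_counts
    ok = (ratio_ub < target_rate) & (obs_sorted > 0.0)
    if not ok.any():
        raise NoValidThresholdError(
            f"no threshold achieves a spurious-edge rate < {target_rate}"
        )
    k = int(np.argmax(ok))  # smallest admissible observed value
    ratio = (p_tail * n_total_pairs) / observed_counts
    r_star = float(obs_sorted[k])
    keep = robs >= r_star
    edges = np.stack([valid_idx[iu[keep]], valid_idx[ju[keep]]], axis=1)
    return CubeGraph(
        n_cubes=len(cubeset),
        edges=edges.astype(np.int32),
        threshold=r_star,
        spurious_rate_estimate=float(ratio[k]),
        n_valid_cubes=n,
        edge_correlations=robs[keep] if keep_correlations else None,
    )


def build_cube_graph(
    volume: GMVolume,
    min_gm_fraction: float = 0.5,
    n_null_pairs: int = 100_000,
    target_rate: float = 0.05,
    rotation_mode: str = "none",
    seed: int = 0,
) -> tuple[CubeSet, CubeGraph]:
    """Convenience wrapper: extract cubes, estimate the null, threshold."""
    cubeset = extract_cubes(volume, min_gm_fraction)
    null = estimate_null_distribution(cubeset, n_null_pairs, seed)
    graph = determine_threshold(cubeset, null, target_rate, rotation_mode)
    return cubeset, graph


def estimate_spurious_rate(
    cubeset: CubeSet,
    graph: CubeGraph,
    n_pairs: int = 100_000,
    seed: int = 1,
    rotation_mode: str = "none",
) -> float:
    """Re-estimate the chance-edge fraction at the graph's threshold with a
    freshly seeded, independent null (a verification, not a refit)."""
    null = estimate_null_distribution(cubeset, n_pairs, seed)
    tail = float(np.mean(null.samples > graph.threshold))
    n = graph.n_valid_cubes
    n_total_pairs = n * (n - 1) // 2
    if graph.n_edges == 0:
        return 0.0
    return tail * n_total_pairs / graph.n_edges
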