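"""Atlas normalization: collapse cube graphs onto a fixed parcellation.

Subjects' cube graphs differ in size, and graph-theoretic properties vary
with network size, so each cube graph is collapsed onto the parcellation to
yield the same-size weighted network for every subject.  Each cube is
assigned to the region holding the plurality of its 27 voxels; the weight
between two regions is the number of observed cube edges between them divided
by the number of possible cube pairs between them, which is bounded in
[0, 1].  Self-connections (within-region edges) are excluded, giving a
zero-diagonal symmetric n_regions x n_regions matrix per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cubes import CubeGraph, CubeSet, CUBE_SIDE
from .errors import GmsnetError, GridMismatchError
from .synthetic import Parcellation

__all__ = ["RegionNetwork", "assign_cubes_to_regions", "normalize_network"]

logger = logging.getLogger(__name__)


@dataclass
class RegionNetwork:
    """Symmetric weighted network on the parcellation's regions."""

    weights: np.ndarray                 # (n_regions, n_regions), zero diagonal
    region_names: list[str]
    cubes_per_region: np.ndarray        # (n_regions,) mapped cube counts
    subject_id: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def assign_cubes_to_regions(
    cubeset: CubeSet, parcellation: Parcellation
) -> dict[int, int]:
    """Map each cube id to the region holding the plurality of its voxels.

    Plurality is taken among labeled (non-background) voxels; ties break to
    the lowest region id.  Cubes containing no labeled voxel are dropped from
    the mapping.
    """
    if tuple(parcellation.labels.shape) != tuple(cubeset.grid_shape):
        raise GridMismatchError(
            f"parcellation grid {parcellation.labels.shape} != "
            f"cube grid {cubeset.grid_shape}"
        )
    labels = parcellation.labels
    n_regions = parcellation.n_regions
    mapping: dict[int, int] = {}
    for cid, (i, j, k) in enumerate(cubeset.origins):
        block = labels[i : i + CUBE_SIDE, j : j + CUBE_SIDE, k : k + CUBE_SIDE]
        counts = np.bincount(block.ravel(), minlength=n_regions + 1)[1:]
        if counts.sum() == 0:
            continue  # entirely background
        mapping[cid] = int(np.argmax(counts)) + 1  # argmax -> lowest id on ties
    return mapping


def normalize_network(
    cubegraph: CubeGraph,
    mapping: dict[int, int],
    n_regions: int,
    region_names: list[str] | None = None,
    subject_id: str | None = None,
) -> RegionNetwork:
    """Collapse a cube graph to region weights by the connection-ratio rule.

    weight(i, j) = (# cube edges between regions i and j) / (n_i * n_j) for
    i != j, where n_i counts the cubes mapped to region i (zero-variance
    cubes included: they occupy gray matter even though they carry no edges).
    Within-region edges are discarded (the diagonal is excluded by
    construction) but counted in the diagnostics as a cohesion signal.
    """
    if mapping and max(mapping.values()) > n_regions:
        raise GmsnetError(
            f"mapping contains region id {max(mapping.values())} > n_regions={n_regions}"
        )
    if region_names is None:
        region_names = [f"R{k:03d}" for k in range(1, n_regions + 1)]
    if len(region_names) != n_regions:
        raise GmsnetError("region_names length inconsistent with n_regions")

    counts_per_region = np.zeros(n_regions, dtype=np.int64)
    for reg in mapping.values():
        counts_per_region[reg - 1] += 1

    # -1 marks unmapped cubes
    lut = np.full(cubegraph.n_cubes, -1, dtype=np.int64)
    for cid, reg in mapping.items():
        lut[cid] = reg - 1

    cross = np.zeros((n_regions, n_regions), dtype=np.int64)
    within = np.zeros(n_regions, dtype=np.int64)
    dropped_unmapped = 0
    if cubegraph.n_edges:
        ra = lut[cubegraph.edges[:, 0]]
        rb = lut[cubegraph.edges[:, 1]]
        ok = (ra >= 0) & (rb >= 0)
        dropped_unmapped = int((~ok).sum())
        ra, rb = ra[ok], rb[ok]
        same = ra == rb
        np.add.at(within, ra[same], 1)
        ra_c, rb_c = ra[~same], rb[~same]
        np.add.at(cross, (ra_c, rb_c), 1)
        np.add.at(cross, (rb_c, ra_c), 1)

    if dropped_unmapped:
        logger.info("dropped %d edges with unmapped endpoints", dropped_unmapped)

    possible = np.outer(counts_per_region, counts_per_region).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(possible > 0, cross / possible, 0.0)
    np.fill_diagonal(weights, 0.0)

    empty = np.flatnonzero(counts_per_region == 0)
    if empty.size:
        warnings.warn(
            f"{empty.size} regions received no cubes (zero rows): "
            f"{[region_names[e] for e in empty[:10]]}",
            stacklevel=2,
        )

    return RegionNetwork(
        weights=weights,
        region_names=list(region_names),
        cubes_per_region=counts_per_region,
        subject_id=subject_id,
        diagnostics={
            "dropped_unmapped_edges": dropped_unmapped,
            "within_region_edges": within,
            "empty_regions": empty.tolist(),
        },
    )
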