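"""Shared fixtures: one session-scoped synthetic cohort run end-to-end.

The main cohort (21 subjects, 7 per group, 90 regions on a 36x42x36 grid at
2 mm) is extracted and normalized once and reused by the unit and acceptance
tests; a smaller 12-region configuration serves the faster recovery and
pipeline checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gmsnet as g
from gmsnet import metrics as gmm

COHORT_SEED = 7
N_NULL_PAIRS = 30_000


@pytest.fixture(scope="session")
def cohort_config() -> g.CohortConfig:
    return g.CohortConfig(
        n_per_group=(7, 7, 7),
        volume_shape=(36, 42, 36),
        n_regions=90,
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def parcellation(cohort_config) -> g.Parcellation:
    return g.generate_parcellation(
        cohort_config.volume_shape, cohort_config.n_regions, cohort_config.seed
    )


@pytest.fixture(scope="session")
def cohort(cohort_config, parcellation):
    """List of (SubjectRecord, GMVolume) for all 21 subjects."""
    return list(g.iter_subject_volumes(cohort_config, parcellation))


@pytest.fixture(scope="session")
def cohort_extraction(cohort):
    """Per subject: (record, CubeSet, CubeGraph)."""
    out = []
    for i, (rec, vol) in enumerate(cohort):
        cubeset, graph = g.build_cube_graph(
            vol, n_null_pairs=N_NULL_PAIRS, seed=1000 + i
        )
        out.append((rec, cubeset, graph))
    return out


@pytest.fixture(scope="session")
def cohort_networks(cohort_extraction, parcellation):
    """Per subject: (record, RegionNetwork) on the 90-region parcellation."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec, cubeset, graph in cohort_extraction:
            mapping = g.assign_cubes_to_regions(cubeset, parcellation)
            net = g.normalize_network(
                graph, mapping, parcellation.n_regions,
                parcellation.region_names, rec.subject_id,
            )
            out.append((rec, net))
    return out


@pytest.fixture(scope="session")
def cohort_nodal_aucs(cohort_networks):
    """Ensemble-free AUC summaries (Eglob/Cp/Lp/Eloc + nodal) per subject."""
    grid = gmm.SparsityGrid()
    rows = []
    for rec, net in cohort_networks:
        nlev = len(grid)
        n = net.n_regions
        eg, cp, lp, el = (np.zeros(nlev) for _ in range(4))
        deg = np.zeros((n, nlev))
        eff = np.zeros((n, nlev))
        for li, s in enumerate(grid.values):
            bg = gmm.threshold_at_sparsity(net.weights, s)
            gmet = gmm.compute_global_metrics(bg)
            nmet = gmm.compute_nodal_metrics(bg)
            eg[li], cp[li], lp[li], el[li] = gmet.Eglob, gmet.Cp, gmet.Lp, gmet.Eloc
            deg[:, li] = nmet.degree
            eff[:, li] = nmet.efficiency
        x = grid.array
        rows.append({
            "record": rec,
            "Eglob": float(np.trapezoid(eg, x)),
            "Cp": float(np.trapezoid(cp, x)),
            "Lp": float(np.trapezoid(lp, x)),
            "Eloc": float(np.trapezoid(el, x)),
            "degree": np.trapezoid(deg, x, axis=1),
            "nodal_efficiency": np.trapezoid(eff, x, axis=1),
        })
    return rows


def small_config(**overrides) -> g.CohortConfig:
    """12-region micro-cohort configuration used by fast integration tests."""
    kw = dict(
        n_per_group=(5, 5, 5),
        volume_shape=(24, 30, 24),
        n_regions=12,
        seed=3,
    )
    kw.update(overrides)
    return g.CohortConfig(**kw)
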