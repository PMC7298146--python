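"""Cohort generator: parcellation construction, volume invariants, effects."""

import warnings

import numpy as np
import pandas as pd
import pytest

import gmsnet as g
from gmsnet import metrics as gmm, stats as gs
from gmsnet.errors import GmsnetError, SizingError
from gmsnet.synthetic import _template

from conftest import small_config


class TestParcellation:
    def test_postconditions(self, parcellation):
        labels = parcellation.labels
        found = np.unique(labels[labels > 0])
        assert list(found) == list(range(1, 91))
        counts = np.bincount(labels.ravel())[1:]
        assert counts.min() >= 27

    def test_deterministic(self):
        a = g.generate_parcellation((24, 30, 24), 12, seed=5)
        b = g.generate_parcellation((24, 30, 24), 12, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_small_raises_sizing_error(self):
        with pytest.raises(SizingError, match="[Mm]inimum feasible"):
            g.generate_parcellation((6, 6, 6), 90, seed=1)

    def test_labels_confined_to_ellipsoid_mask(self, parcellation):
        # corners of the grid lie outside the inscribed ellipsoid
        assert parcellation.labels[0, 0, 0] == 0
        assert parcellation.labels[-1, -1, -1] == 0


class TestSubjectVolumes:
    def test_gm_volume_invariants(self, cohort):
        for _, vol in cohort:
            assert vol.values.min() >= 0.0 and vol.values.max() <= 1.0
            assert np.all(vol.values[~vol.brain_mask] == 0.0)

    def test_zero_noise_limit_reproduces_template(self):
        cfg = small_config(noise_sigma=0.0)
        parc = g.generate_parcellation(cfg.volume_shape, cfg.n_regions, cfg.seed)
        tmpl = _template(cfg, parc)
        vols = [v.values for _, v in g.iter_subject_volumes(cfg, parc)]
        for v in vols:
            np.testing.assert_allclose(v, np.clip(tmpl, 0, 1), atol=1e-12)

    def test_determinism(self):
        cfg = small_config()
        a = [v.values for _, v in g.iter_subject_volumes(cfg)]
        b = [v.values for _, v in g.iter_subject_volumes(cfg)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_smoothing_raises_adjacent_cube_similarity(self):
        """Neighboring cubes correlate more strongly in smoothed volumes."""
        def mean_adjacent_corr(fwhm):
            cfg = small_config(smoothing_fwhm_mm=fwhm, n_per_group=(2, 2, 2))
            vals = []
            for _, vol in g.iter_subject_volumes(cfg):
                cs = g.extract_cubes(vol)
                # pairs of cubes 3 voxels apart along the first axis
                key = {tuple(o): i for i, o in enumerate(cs.origins)}
                for o, i in key.items():
                    j = key.get((o[0] + 3, o[1], o[2]))
                    if j is None:
                        continue
                    r = g.cube_correlation(cs.values[i], cs.values[j])
                    if np.isfinite(r):
                        vals.append(r)
            return np.mean(vals)

        assert mean_adjacent_corr(6.0) > mean_adjacent_corr(0.0)

    def test_unknown_group_rejected(self):
        cfg = small_config()
        parc = g.generate_parcellation(cfg.volume_shape, cfg.n_regions, cfg.seed)
        rec = g.SubjectRecord("sub-x", "nogroup", 25.0, 1, 12.0, {})
        with pytest.raises(GmsnetError, match="nogroup"):
            g.generate_subject_volume(cfg, rec, parc)

    def test_effect_region_validation(self):
        with pytest.raises(GmsnetError, match="region ids"):
            small_config(
                effects=[g.EffectSpec("group1", (99,), "decorrelate", 1.0)]
            )


class TestEffects:
    def test_decorrelate_lowers_parcel_cube_degree(self):
        """Full-strength decorrelation in one parcel collapses the cube-graph
        degree of that parcel's cubes in the affected group."""
        eff = [g.EffectSpec("group1", (5,), "decorrelate", 1.0)]
        cfg = small_config(effects=eff, seed=21)
        parc = g.generate_parcellation(cfg.volume_shape, cfg.n_regions, cfg.seed)
        mean_deg = {"group1": [], "control": []}
        for i, (rec, vol) in enumerate(g.iter_subject_volumes(cfg, parc)):
            if rec.group == "group2":
                continue
            cs, cg = g.build_cube_graph(vol, n_null_pairs=15_000, seed=i)
            mapping = g.assign_cubes_to_regions(cs, parc)
            deg = cg.degrees()
            in5 = [cid for cid, r in mapping.items() if r == 5]
            mean_deg[rec.group].append(deg[in5].mean())
        assert np.mean(mean_deg["group1"]) < np.mean(mean_deg["control"])

    def test_attenuate_lowers_mean_gm(self):
        eff = [g.EffectSpec("group1", (3,), "attenuate", 0.8)]
        cfg = small_config(effects=eff, seed=9)
        parc = g.generate_parcellation(cfg.volume_shape, cfg.n_regions, cfg.seed)
        sel = parc.labels == 3
        means = {"group1": [], "control": []}
        for rec, vol in g.iter_subject_volumes(cfg, parc):
            if rec.group in means:
                means[rec.group].append(vol.values[sel].mean())
        assert np.mean(means["group1"]) < 0.5 * np.mean(means["control"])


class TestCohortIO:
    def test_counts_and_determinism(self, tmp_path):
        cfg = small_config()
        records, parc, table = g.generate_cohort(cfg, tmp_path / "a")
        assert len(records) == 15
        assert len(table) == 15
        assert len(list((tmp_path / "a" / "volumes").glob("*.nii.gz"))) == 15
        assert (tmp_path / "a" / "parcellation.nii.gz").exists()
        g.generate_cohort(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "subjects.tsv").read_bytes() == (
            tmp_path / "b" / "subjects.tsv"
        ).read_bytes()

    def test_roundtrip_via_loaders(self, tmp_path):
        cfg = small_config(n_per_group=(2, 2, 2))
        records, parc, table = g.generate_cohort(cfg, tmp_path)
        from gmsnet.synthetic import load_parcellation, load_volume

        parc2 = load_parcellation(tmp_path / "parcellation.nii.gz")
        np.testing.assert_array_equal(parc.labels, parc2.labels)
        vol = load_volume(tmp_path / records[0].volume_ref)
        assert vol.values.shape == tuple(cfg.volume_shape)
        assert vol.voxel_size_mm == pytest.approx(2.0)


class TestExchangeability:
    def test_type_i_error_at_nominal_level_without_effects(self):
        """With no planted effects the three groups are exchangeable: the
        ANOVA on global-efficiency AUC rejects at ~5% across 200 replicate
        micro-cohorts (binomial 95% bounds)."""
        grid = gmm.SparsityGrid((0.15, 0.25, 0.34))
        n_rep = 200
        rejections = 0
        for rep in range(n_rep):
            cfg = g.CohortConfig(
                n_per_group=(3, 3, 3), volume_shape=(15, 18, 15),
                n_regions=5, seed=40_000 + rep,
            )
            parc = g.generate_parcellation(cfg.volume_shape, 5, cfg.seed)
            aucs, groups = [], []
            for i, (rec, vol) in enumerate(g.iter_subject_volumes(cfg, parc)):
                _, cg = g.build_cube_graph(vol, n_null_pairs=10_000, seed=i)
                mapping = g.assign_cubes_to_regions(
                    g.extract_cubes(vol), parc
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net = g.normalize_network(cg, mapping, 5)
                curve = [
                    gmm.compute_global_metrics(
                        gmm.threshold_at_sparsity(net.weights, s)
                    ).Eglob
                    for s in grid.values
                ]
                aucs.append(gmm.auc_over_grid(curve, grid))
                groups.append(rec.group)
            aucs, groups = np.array(aucs), np.array(groups)
            _, p = gs.anova_oneway(
                aucs[groups == "group1"], aucs[groups == "group2"],
                aucs[groups == "control"],
            )
            rejections += p < 0.05
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) <= half_width


class TestLinkedSymptoms:
    def test_linked_model_recovered_by_partial_correlation(self):
        """A latent severity linked to global efficiency (r=0.8) is
        recovered as a positive covariate-adjusted correlation at n=40."""
        cfg = g.CohortConfig(
            n_per_group=(14, 13, 13), volume_shape=(24, 30, 24), n_regions=12,
            symptom_model=g.SymptomModel(
                score_names=("severity",), linked_metric="global_efficiency",
                r=0.8,
            ),
            seed=11,
        )
        parc = g.generate_parcellation(cfg.volume_shape, cfg.n_regions, cfg.seed)
        grid = gmm.SparsityGrid(tuple(round(0.10 + 0.04 * i, 2) for i in range(7)))
        eglob, score, cov = [], [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, (rec, vol) in enumerate(g.iter_subject_volumes(cfg, parc)):
                _, cg = (cs_cg := g.build_cube_graph(vol, n_null_pairs=15_000, seed=i))
                mapping = g.assign_cubes_to_regions(cs_cg[0], parc)
                net = g.normalize_network(cg, mapping, cfg.n_regions)
                curve = [
                    gmm.compute_global_metrics(
                        gmm.threshold_at_sparsity(net.weights, s)
                    ).Eglob
                    for s in grid.values
                ]
                eglob.append(gmm.auc_over_grid(curve, grid))
                score.append(rec.symptom_scores["severity"])
                cov.append([rec.age, rec.sex, rec.education])
        res = gs.partial_correlation(np.array(eglob), np.array(score), np.array(cov))
        assert res.r > 0
        assert res.p < 0.05
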