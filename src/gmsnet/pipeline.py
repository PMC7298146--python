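"""Resumable pipeline: simulate -> extract -> normalize -> metrics -> stats -> report.

Each stage reads the previous stage's on-disk outputs, writes flat files
under the run directory, and records a manifest (parameters, seed, content
hashes of inputs and outputs).  Re-running a stage with unchanged config and
inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import atlas, cubes, metrics as gm, stats as gs, synthetic as syn
from .errors import MissingStageError

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "normalize", "metrics", "stats", "report")


@dataclass
class PipelineConfig:
    """All stage parameters, with defaults at the study's stated values."""

    out_dir: Path = Path("gmsnet_run")
    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    # optional external inputs (skip the simulate stage)
    volumes_dir: Path | None = None
    parcellation_path: Path | None = None
    subject_table: Path | None = None
    # extraction
    min_gm_fraction: float = 0.5
    rotation_mode: str = "none"
    n_null_pairs: int = 100_000
    target_rate: float = 0.05
    # metrics
    grid: gm.SparsityGrid = field(default_factory=gm.SparsityGrid)
    ensemble: gm.RandomEnsembleConfig = field(default_factory=gm.RandomEnsembleConfig)
    # stats
    nbs: gs.NBSConfig = field(default_factory=gs.NBSConfig)
    alpha: float = 0.05
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "out_dir" in raw:
            kw["out_dir"] = Path(raw["out_dir"])
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "effects" in c:
                c["effects"] = [syn.EffectSpec(**e) for e in c["effects"]]
            if "symptom_model" in c:
                c["symptom_model"] = syn.SymptomModel(**c["symptom_model"])
            if "covariate_model" in c:
                c["covariate_model"] = syn.CovariateModel(**c["covariate_model"])
            for t in ("n_per_group", "group_names", "volume_shape"):
                if t in c:
                    c[t] = tuple(c[t])
            kw["cohort"] = syn.CohortConfig(**c)
        if "grid" in raw:
            kw["grid"] = gm.SparsityGrid(tuple(raw["grid"]))
        if "ensemble" in raw:
            kw["ensemble"] = gm.RandomEnsembleConfig(**raw["ensemble"])
        if "nbs" in raw:
            kw["nbs"] = gs.NBSConfig(**raw["nbs"])
        for name in (
            "volumes_dir", "parcellation_path", "subject_table",
            "min_gm_fraction", "rotation_mode", "n_null_pairs", "target_rate",
            "alpha", "seed", "threads",
        ):
            if name in raw:
                val = raw[name]
                if name.endswith(("_dir", "_path", "_table")) and val is not None:
                    val = Path(val)
                kw[name] = val
        return cls(**kw)

    def params_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(d["out_dir"])
        for k in ("volumes_dir", "parcellation_path", "subject_table"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    config: PipelineConfig, stage: str, inputs: list[Path], outputs: list[Path]
) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "params": config.params_dict(),
        "inputs": {str(p.relative_to(config.out_dir)): _sha256(p) for p in inputs},
        "outputs": {str(p.relative_to(config.out_dir)): _sha256(p) for p in outputs},
        "warnings": [],
    }
    out = config.out_dir / f"manifest_{stage}.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"missing {path}; run the '{producing_stage}' stage first"
        )
    return path


def _subject_seed(master: int, subject_id: str) -> int:
    return int(
        np.random.SeedSequence(
            [int(master), zlib.crc32(subject_id.encode())]
        ).generate_state(1)[0] % (2**31)
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig) -> list[Path]:
    out = config.out_dir / "simulate"
    cohort = config.cohort
    if cohort.seed != config.seed:
        cohort = syn.CohortConfig(**{**asdict_cohort(cohort), "seed": config.seed})
    _, _, table = syn.generate_cohort(cohort, out)
    outputs = [out / "subjects.tsv", out / "parcellation.nii.gz"]
    outputs += sorted((out / "volumes").glob("*.nii.gz"))
    _write_manifest(config, "simulate", [], outputs)
    return outputs


def asdict_cohort(cohort: syn.CohortConfig) -> dict:
    d = {
        "n_per_group": cohort.n_per_group,
        "group_names": cohort.group_names,
        "volume_shape": cohort.volume_shape,
        "voxel_size_mm": cohort.voxel_size_mm,
        "smoothing_fwhm_mm": cohort.smoothing_fwhm_mm,
        "n_regions": cohort.n_regions,
        "effects": list(cohort.effects),
        "noise_sigma": cohort.noise_sigma,
        "covariate_model": cohort.covariate_model,
        "symptom_model": cohort.symptom_model,
        "seed": cohort.seed,
    }
    return d


def _input_locations(config: PipelineConfig) -> tuple[Path, Path, Path]:
    """(subject table, parcellation, volume base dir) for extraction."""
    if config.subject_table is not None:
        return (
            Path(config.subject_table),
            Path(config.parcellation_path),
            Path(config.volumes_dir) if config.volumes_dir else Path(config.subject_table).parent,
        )
    sim = config.out_dir / "simulate"
    return (
        _require(sim / "subjects.tsv", "simulate"),
        _require(sim / "parcellation.nii.gz", "simulate"),
        sim,
    )


def _extract_one(
    vol_path: Path, sid: str, config: PipelineConfig, out: Path
) -> dict:
    volume = syn.load_volume(vol_path)
    cubeset, graph = cubes.build_cube_graph(
        volume,
        min_gm_fraction=config.min_gm_fraction,
        n_null_pairs=config.n_null_pairs,
        target_rate=config.target_rate,
        rotation_mode=config.rotation_mode,
        seed=_subject_seed(config.seed, sid),
    )
    np.savez_compressed(
        out / f"{sid}_cubegraph.npz",
        origins=cubeset.origins,
        gm_fraction=cubeset.gm_fraction,
        grid_shape=np.asarray(cubeset.grid_shape),
        edges=graph.edges,
        threshold=graph.threshold,
        spurious_rate=graph.spurious_rate_estimate,
        n_cubes=len(cubeset),
        n_valid_cubes=graph.n_valid_cubes,
    )
    return {
        "subject_id": sid,
        "n_cubes": len(cubeset),
        "n_valid_cubes": graph.n_valid_cubes,
        "n_edges": graph.n_edges,
        "threshold": graph.threshold,
        "spurious_rate": graph.spurious_rate_estimate,
    }


def stage_extract(config: PipelineConfig) -> list[Path]:
    table_path, _, vol_base = _input_locations(config)
    table = pd.read_csv(table_path, sep="\t")
    out = config.out_dir / "extract"
    out.mkdir(parents=True, exist_ok=True)
    jobs = [
        (vol_base / row.volume_path, row.subject_id)
        for row in table.itertuples()
    ]
    for p, _ in jobs:
        _require(p, "simulate")
    if config.threads > 1:
        rows = Parallel(n_jobs=config.threads)(
            delayed(_extract_one)(p, sid, config, out) for p, sid in jobs
        )
    else:
        rows = [_extract_one(p, sid, config, out) for p, sid in jobs]
    summary = pd.DataFrame(rows)
    _write_tsv(summary, out / "extraction_summary.tsv")
    outputs = [out / "extraction_summary.tsv"] + sorted(out.glob("*_cubegraph.npz"))
    _write_manifest(config, "extract", [table_path], outputs)
    return outputs


def stage_normalize(config: PipelineConfig) -> list[Path]:
    table_path, parc_path, _ = _input_locations(config)
    parc = syn.load_parcellation(parc_path)
    table = pd.read_csv(table_path, sep="\t")
    ext = config.out_dir / "extract"
    _require(ext / "extraction_summary.tsv", "extract")
    out = config.out_dir / "normalize"
    out.mkdir(parents=True, exist_ok=True)

    ids, mats, counts, rows = [], [], [], []
    for row in table.itertuples():
        sid = row.subject_id
        data = np.load(_require(ext / f"{sid}_cubegraph.npz", "extract"))
        cubeset = cubes.CubeSet(
            values=np.zeros((int(data["n_cubes"]), cubes.CUBE_VOXELS)),
            origins=data["origins"],
            gm_fraction=data["gm_fraction"],
            grid_shape=tuple(int(x) for x in data["grid_shape"]),
            subject_id=sid,
        )
        graph = cubes.CubeGraph(
            n_cubes=int(data["n_cubes"]),
            edges=data["edges"],
            threshold=float(data["threshold"]),
            spurious_rate_estimate=float(data["spurious_rate"]),
            n_valid_cubes=int(data["n_valid_cubes"]),
        )
        mapping = atlas.assign_cubes_to_regions(cubeset, parc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = atlas.normalize_network(
                graph, mapping, parc.n_regions, parc.region_names, sid
            )
        ids.append(sid)
        mats.append(net.weights)
        counts.append(net.cubes_per_region)
        rows.append({
            "subject_id": sid,
            "mapped_cubes": int(net.cubes_per_region.sum()),
            "empty_regions": len(net.diagnostics["empty_regions"]),
            "dropped_unmapped_edges": net.diagnostics["dropped_unmapped_edges"],
            "within_region_edges": int(net.diagnostics["within_region_edges"].sum()),
        })
    np.savez_compressed(
        out / "networks.npz",
        subject_ids=np.asarray(ids),
        weights=np.asarray(mats),
        cubes_per_region=np.asarray(counts),
        region_names=np.asarray(parc.region_names),
    )
    _write_tsv(pd.DataFrame(rows), out / "normalize_summary.tsv")
    outputs = [out / "networks.npz", out / "normalize_summary.tsv"]
    _write_manifest(config, "normalize", [table_path, parc_path], outputs)
    return outputs


def stage_metrics(config: PipelineConfig) -> list[Path]:
    norm = config.out_dir / "normalize" / "networks.npz"
    _require(norm, "normalize")
    data = np.load(norm, allow_pickle=False)
    ids = [str(s) for s in data["subject_ids"]]
    weights = data["weights"]
    region_names = [str(r) for r in data["region_names"]]
    out = config.out_dir / "metrics"
    out.mkdir(parents=True, exist_ok=True)

    grid = config.grid
    curve_rows, auc_rows = [], []
    deg_rows, eff_rows = [], []
    for sid, w in zip(ids, weights):
        ens = gm.RandomEnsembleConfig(
            n_random=config.ensemble.n_random,
            rewires_per_edge=config.ensemble.rewires_per_edge,
            seed=_subject_seed(config.seed ^ 0x5EED, sid),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = gm.metric_curves(w, grid, ens)
            aucs = gm.auc_summary(curves, grid)
        for li, s in enumerate(grid.values):
            curve_rows.append({
                "subject_id": sid, "sparsity": s,
                **{name: curves[name][li] for name in gm.GLOBAL_METRIC_NAMES},
            })
        auc_rows.append({
            "subject_id": sid,
            **{name: aucs[name] for name in gm.GLOBAL_METRIC_NAMES},
        })
        deg_rows.append({"subject_id": sid, **dict(zip(region_names, aucs["degree"]))})
        eff_rows.append({
            "subject_id": sid, **dict(zip(region_names, aucs["nodal_efficiency"]))
        })
    _write_tsv(pd.DataFrame(curve_rows), out / "global_curves.tsv")
    _write_tsv(pd.DataFrame(auc_rows), out / "global_auc.tsv")
    _write_tsv(pd.DataFrame(deg_rows), out / "nodal_degree_auc.tsv")
    _write_tsv(pd.DataFrame(eff_rows), out / "nodal_efficiency_auc.tsv")
    outputs = [
        out / "global_curves.tsv", out / "global_auc.tsv",
        out / "nodal_degree_auc.tsv", out / "nodal_efficiency_auc.tsv",
    ]
    _write_manifest(config, "metrics", [norm], outputs)
    return outputs


def _group_values(df: pd.DataFrame, table: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
    merged = df.merge(table[["subject_id", "group"]], on="subject_id")
    return {g: sub[col].to_numpy() for g, sub in merged.groupby("group", sort=False)}


def stage_stats(config: PipelineConfig) -> list[Path]:
    table_path, parc_path, _ = _input_locations(config)
    table = pd.read_csv(table_path, sep="\t")
    met = config.out_dir / "metrics"
    auc = pd.read_csv(_require(met / "global_auc.tsv", "metrics"), sep="\t")
    deg = pd.read_csv(_require(met / "nodal_degree_auc.tsv", "metrics"), sep="\t")
    eff = pd.read_csv(_require(met / "nodal_efficiency_auc.tsv", "metrics"), sep="\t")
    ndata = np.load(
        _require(config.out_dir / "normalize" / "networks.npz", "normalize")
    )
    weights = ndata["weights"]
    ids = [str(s) for s in ndata["subject_ids"]]
    region_names = [str(r) for r in ndata["region_names"]]
    n_regions = len(region_names)
    groups = list(config.cohort.group_names)
    if config.subject_table is not None:
        groups = list(dict.fromkeys(table["group"]))
    pairs = [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]
    out = config.out_dir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"groups": groups}

    # --- global AUC metrics: one-way ANOVA + post hoc t per Table-2 layout
    glob = {}
    for metric in gm.GLOBAL_METRIC_NAMES:
        by_group = _group_values(auc, table, metric)
        f, p = gs.anova_oneway(*[by_group[g] for g in groups])
        entry = {"F": f, "p": p}
        for ga, gb in pairs:
            t, tp = gs.posthoc_t(by_group[ga], by_group[gb])
            entry[f"t_{ga}_vs_{gb}"] = t
            entry[f"p_{ga}_vs_{gb}"] = tp
        glob[metric] = entry
    results["global"] = glob

    # --- nodal ANOVA with Bonferroni (family = n_regions per metric)
    nodal = {}
    p_deg = np.ones(n_regions)
    p_eff = np.ones(n_regions)
    for ri, rname in enumerate(region_names):
        fd, pd_ = gs.anova_oneway(*[
            _group_values(deg, table, rname)[g] for g in groups
        ])
        fe, pe_ = gs.anova_oneway(*[
            _group_values(eff, table, rname)[g] for g in groups
        ])
        p_deg[ri], p_eff[ri] = pd_, pe_
        nodal[rname] = {"degree_F": fd, "degree_p": pd_,
                        "efficiency_F": fe, "efficiency_p": pe_}
    sig_deg = gs.bonferroni_flags(p_deg, config.alpha, n_regions)
    sig_eff = gs.bonferroni_flags(p_eff, config.alpha, n_regions)
    for ri, rname in enumerate(region_names):
        nodal[rname]["degree_sig"] = bool(sig_deg[ri])
        nodal[rname]["efficiency_sig"] = bool(sig_eff[ri])
    results["nodal"] = nodal
    aberrant = gs.select_aberrant_nodes(p_deg, p_eff, config.alpha, n_regions)
    results["aberrant_nodes"] = [region_names[i] for i in aberrant]

    # --- post hoc on aberrant nodes only (mirrors the corrected-ANOVA gate)
    posthoc = {}
    for ri in aberrant:
        rname = region_names[ri]
        entry = {}
        for metric_df, mname in ((deg, "degree"), (eff, "efficiency")):
            by_group = _group_values(metric_df, table, rname)
            for ga, gb in pairs:
                t, tp = gs.posthoc_t(by_group[ga], by_group[gb])
                entry[f"{mname}_t_{ga}_vs_{gb}"] = t
                entry[f"{mname}_p_{ga}_vs_{gb}"] = tp
        posthoc[rname] = entry
    results["nodal_posthoc"] = posthoc

    # --- NBS on Fisher-z weights among aberrant nodes, per group pair
    nbs_out: dict = {}
    if aberrant.size >= 2:
        ai, aj = np.triu_indices(aberrant.size, k=1)
        edges = np.stack([aberrant[ai], aberrant[aj]], axis=1)
        z = gs.fisher_z(weights[:, edges[:, 0], edges[:, 1]])
        sid_group = dict(zip(table["subject_id"], table["group"]))
        labels_all = np.asarray([sid_group[s] for s in ids])
        for pi, (ga, gb) in enumerate(pairs):
            sel = np.isin(labels_all, [ga, gb])
            res = gs.nbs(
                z[sel], labels_all[sel], edges, n_regions,
                config.nbs, seed=(config.seed * 7 + pi + 1) % (2**31),
            )
            comps = []
            for c, ext, fwe, tvals in zip(
                res.components, res.extents, res.fwe_p, res.component_t
            ):
                comps.append({
                    "extent": ext,
                    "fwe_p": fwe,
                    "edges": [
                        {"region_1": region_names[int(a)],
                         "region_2": region_names[int(b)],
                         "t": float(t)}
                        for (a, b), t in zip(c, tvals)
                    ],
                })
            nbs_out[f"{ga}_vs_{gb}"] = {"components": comps}
    else:
        nbs_out["skipped"] = "no aberrant nodes passed the corrected ANOVA"
    results["nbs"] = nbs_out

    # --- partial correlations with age/sex/education, per patient group
    score_cols = [c for c in table.columns if c.startswith("score_")]
    pcorr: dict = {}
    metric_cols = {m: auc for m in ("Eglob", "Cp", "Lp", "gamma", "sigma")}
    for ri in aberrant:
        metric_cols[f"degree_{region_names[ri]}"] = deg
        metric_cols[f"efficiency_{region_names[ri]}"] = eff
    for g in groups[:2]:  # the two patient-like groups
        sub = table[table["group"] == g]
        entry = {}
        for mname, df in metric_cols.items():
            col = mname.split("_", 1)[1] if "_R" in mname else mname
            merged = sub.merge(df, on="subject_id")
            cov = merged[["age", "sex", "education"]].to_numpy()
            for sc in score_cols:
                try:
                    res = gs.partial_correlation(
                        merged[col].to_numpy(), merged[sc].to_numpy(), cov
                    )
                    entry[f"{mname}|{sc}"] = {"r": res.r, "p": res.p, "n": res.n}
                except (ValueError, gs.CollinearityError) as exc:
                    entry[f"{mname}|{sc}"] = {"error": str(exc)}
        pcorr[g] = entry
    results["partial_correlations"] = pcorr

    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float)
    )
    outputs = [out / "results.json"]
    _write_manifest(config, "stats", [table_path], outputs)
    return outputs


def _hemisphere(parc: syn.Parcellation) -> dict[str, str]:
    mid = (parc.labels.shape[0] - 1) / 2.0
    out = {}
    for rid, name in enumerate(parc.region_names, start=1):
        xs = np.argwhere(parc.labels == rid)[:, 0]
        out[name] = "L" if xs.mean() < mid else "R"
    return out


def stage_report(config: PipelineConfig) -> list[Path]:
    res_path = _require(config.out_dir / "stats" / "results.json", "stats")
    results = json.loads(res_path.read_text())
    _, parc_path, _ = _input_locations(config)
    hemi = _hemisphere(syn.load_parcellation(parc_path))
    out = config.out_dir / "report"
    out.mkdir(parents=True, exist_ok=True)

    rows = [{"metric": m, **results["global"][m]} for m in gm.GLOBAL_METRIC_NAMES]
    _write_tsv(pd.DataFrame(rows), out / "global_metrics.tsv")

    nodal_rows = [
        {"region": r, **results["nodal"][r]} for r in sorted(results["nodal"])
    ]
    _write_tsv(pd.DataFrame(nodal_rows), out / "nodal_metrics.tsv")

    ph = results["nodal_posthoc"]
    ph_rows = [{"region": r, **ph[r]} for r in sorted(ph)]
    _write_tsv(
        pd.DataFrame(ph_rows) if ph_rows else pd.DataFrame(columns=["region"]),
        out / "nodal_posthoc.tsv",
    )

    nbs_rows = []
    for contrast, block in results["nbs"].items():
        if contrast == "skipped":
            continue
        for ci, comp in enumerate(block["components"]):
            for e in comp["edges"]:
                nbs_rows.append({
                    "contrast": contrast,
                    "component": ci,
                    "region_1": e["region_1"],
                    "region_2": e["region_2"],
                    "t": e["t"],
                    "extent": comp["extent"],
                    "fwe_p": comp["fwe_p"],
                    "interhemispheric": (
                        "yes" if hemi[e["region_1"]] != hemi[e["region_2"]] else "no"
                    ),
                })
    cols = ["contrast", "component", "region_1", "region_2", "t",
            "extent", "fwe_p", "interhemispheric"]
    _write_tsv(
        pd.DataFrame(nbs_rows, columns=cols), out / "nbs_edges.tsv"
    )

    pc_rows = []
    for g, entry in results["partial_correlations"].items():
        for key, val in sorted(entry.items()):
            mname, sc = key.split("|")
            pc_rows.append({
                "group": g, "metric": mname, "score": sc,
                "r": val.get("r"), "p": val.get("p"), "n": val.get("n"),
            })
    _write_tsv(
        pd.DataFrame(pc_rows, columns=["group", "metric", "score", "r", "p", "n"]),
        out / "partial_correlations.tsv",
    )
    outputs = sorted(out.glob("*.tsv"))
    _write_manifest(config, "report", [res_path], outputs)
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "normalize": stage_normalize,
    "metrics": stage_metrics,
    "stats": stage_stats,
    "report": stage_report,
}


def run_stage(stage_name: str, config: PipelineConfig) -> list[Path]:
    if stage_name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; choose from {STAGES}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("running stage %s -> %s", stage_name, config.out_dir)
    return _STAGE_FUNCS[stage_name](config)


def run_all(config: PipelineConfig) -> dict[str, list[Path]]:
    out = {}
    for stage in STAGES:
        if stage == "simulate" and config.subject_table is not None:
            continue
        out[stage] = run_stage(stage, config)
    return out
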