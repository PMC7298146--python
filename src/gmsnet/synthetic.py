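"""Synthetic gray-matter cohorts for similarity-network analysis.

Emulates the preprocessed inputs of a single-subject structural-covariance
study: spatially smoothed gray-matter probability maps on an isotropic 2 mm
grid, an integer-labeled parcellation (a reproducible surrogate for an
AAL-style 90-region atlas), and a subject table with group labels and
demographic covariates.

The generative model is deliberately simple but has the one property the
downstream method measures: spatial smoothness.  Each subject volume is a
shared anatomical template (per-parcel mean gray-matter levels plus a smooth
global modulation) plus a subject-specific Gaussian random field smoothed
with the same FWHM kernel, clipped to [0, 1].  Smoothing induces local
similarity between neighboring 3x3x3-voxel cubes, which is exactly the signal
the cube-correlation network extraction thresholds against a permutation
null.  Group effects are planted per parcel:

``decorrelate``
    add unsmoothed white noise inside the target parcels for one group,
    destroying local cube similarity (models regional similarity loss),
``correlate``
    attenuate the subject-specific noise field inside the target parcels,
    increasing shared (template-driven) structure,
``attenuate``
    scale down the mean gray-matter probability in the target parcels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter

from .errors import GmsnetError, SizingError

__all__ = [
    "EffectSpec",
    "CovariateModel",
    "SymptomModel",
    "CohortConfig",
    "SubjectRecord",
    "GMVolume",
    "Parcellation",
    "generate_parcellation",
    "generate_subject_volume",
    "generate_cohort",
    "iter_subject_volumes",
]

_MIN_PARCEL_VOXELS = 27

# White-noise std at magnitude 1.0 for the "decorrelate" effect; chosen large
# relative to the default smoothed-field sigma (0.1) so that a full-strength
# effect essentially abolishes local cube similarity in the target parcels.
_DECORRELATE_SCALE = 0.25


@dataclass(frozen=True)
class EffectSpec:
    """A planted regional group effect."""

    group: str
    region_ids: tuple[int, ...]
    mode: str  # "decorrelate" | "correlate" | "attenuate"
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in ("decorrelate", "correlate", "attenuate"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("effect magnitude must lie in [0, 1]")
        object.__setattr__(self, "region_ids", tuple(int(r) for r in self.region_ids))


@dataclass(frozen=True)
class CovariateModel:
    """Demographic covariate distributions (fixture realism only)."""

    age_mean: float = 26.0
    age_sd: float = 5.0
    age_min: float = 18.0
    education_mean: float = 13.0
    education_sd: float = 3.0
    p_male: float = 0.6


@dataclass(frozen=True)
class SymptomModel:
    """How symptom scores relate to network structure.

    With ``linked_metric=None`` (the default) scores are independent of the
    volumes, so metric-score partial correlations are null by construction.
    With a linked metric, a per-subject latent severity drives the score with
    correlation ``r`` and simultaneously degrades cube similarity (unsmoothed
    noise) within a fixed third of the parcels, so that more severe subjects
    have genuinely less efficient networks.  The regional concentration is
    what makes the metric response monotone: global noise mostly reshuffles
    which edges survive sparsity thresholding, whereas focal damage removes
    a node group's connections outright.
    """

    score_names: tuple[str, ...] = ("severity", "duration")
    linked_metric: str | None = None
    r: float = 0.0
    # upper bound on the white-noise std the latent severity can add
    latent_noise_scale: float = 0.25


@dataclass
class CohortConfig:
    """Study conditions for a synthetic three-group cohort."""

    n_per_group: tuple[int, int, int] = (5, 5, 5)
    group_names: tuple[str, str, str] = ("group1", "group2", "control")
    volume_shape: tuple[int, int, int] = (60, 72, 60)
    voxel_size_mm: float = 2.0
    smoothing_fwhm_mm: float = 6.0
    n_regions: int = 90
    effects: list[EffectSpec] = field(default_factory=list)
    noise_sigma: float = 0.1
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    symptom_model: SymptomModel = field(default_factory=SymptomModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 subjects")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        for eff in self.effects:
            if eff.group not in self.group_names:
                raise GmsnetError(f"effect group {eff.group!r} not in {self.group_names}")
            bad = [r for r in eff.region_ids if not 1 <= r <= self.n_regions]
            if bad:
                raise GmsnetError(f"effect region ids {bad} outside 1..{self.n_regions}")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: int
    education: float
    symptom_scores: dict[str, float]
    volume_ref: str | None = None


@dataclass
class GMVolume:
    """A 3D gray-matter probability map with its brain mask."""

    values: np.ndarray
    voxel_size_mm: float
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.values.shape != self.brain_mask.shape:
            raise ValueError("values and brain_mask shapes differ")


@dataclass
class Parcellation:
    """Integer label volume: 0 = background, 1..n_regions = parcels."""

    labels: np.ndarray
    region_names: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (voxel_size_mm * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def _ellipsoid_mask(shape: Sequence[int]) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid (the toy brain mask)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    out = np.zeros(tuple(shape), dtype=float)
    for g, s in zip(grids, shape):
        c = (s - 1) / 2.0
        r = s / 2.0
        out = out + ((g - c) / r) ** 2
    return out <= 1.0


def generate_parcellation(
    volume_shape: Sequence[int], n_regions: int, seed: int
) -> Parcellation:
    """Tile an ellipsoidal brain mask into ``n_regions`` contiguous parcels.

    Parcels are the nearest-centroid cells of a seeded k-means over in-mask
    voxel coordinates (convex, hence contiguous), relabeled 1..n_regions in
    lexicographic centroid order so labels are stable across runs.
    """
    shape = tuple(int(s) for s in volume_shape)
    mask = _ellipsoid_mask(shape)
    n_in = int(mask.sum())
    if n_in < n_regions * _MIN_PARCEL_VOXELS:
        # smallest cubic grid whose inscribed ellipsoid holds the parcels
        s_min = int(np.ceil((n_regions * _MIN_PARCEL_VOXELS * 6.0 / np.pi) ** (1.0 / 3.0)))
        raise SizingError(
            f"shape {shape} has only {n_in} in-mask voxels; "
            f"{n_regions} parcels need >= {n_regions * _MIN_PARCEL_VOXELS}. "
            f"Minimum feasible cubic shape: ({s_min}, {s_min}, {s_min})."
        )
    coords = np.argwhere(mask).astype(np.float64)
    rng = np.random.default_rng([int(seed), 0x9A7C])
    assign = None
    for attempt in range(8):
        _, lab = kmeans2(
            coords, n_regions, minit="++", seed=rng, iter=20
        )
        counts = np.bincount(lab, minlength=n_regions)
        if counts.min() >= _MIN_PARCEL_VOXELS:
            assign = lab
            break
    if assign is None:
        raise SizingError(
            f"could not grow {n_regions} parcels of >= {_MIN_PARCEL_VOXELS} voxels "
            f"inside shape {shape}; use a larger grid"
        )
    # relabel by centroid lexicographic order for determinism of naming
    cents = np.array(
        [coords[assign == k].mean(axis=0) for k in range(n_regions)]
    )
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0]))
    relabel = np.empty(n_regions, dtype=np.int32)
    relabel[order] = np.arange(1, n_regions + 1)
    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = relabel[assign]
    names = [f"R{k:03d}" for k in range(1, n_regions + 1)]
    return Parcellation(labels=labels, region_names=names)


def _subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject substream via stable hashing of the subject id."""
    return np.random.default_rng(
        [int(master_seed), zlib.crc32(subject_id.encode("utf-8"))]
    )


def _template(config: CohortConfig, parcellation: Parcellation) -> np.ndarray:
    """Shared anatomical template: per-parcel levels + smooth modulation."""
    rng = np.random.default_rng([int(config.seed), 0x7E4])
    n = parcellation.n_regions
    levels = 0.35 + 0.35 * rng.random(n)  # parcel mean GM probability
    lut = np.concatenate(([0.0], levels))
    vol = lut[parcellation.labels]
    sig = _fwhm_to_sigma_vox(config.smoothing_fwhm_mm, config.voxel_size_mm)
    # broad smooth modulation gives within-parcel gradients shared by subjects
    mod = gaussian_filter(rng.standard_normal(vol.shape), max(2.0 * sig, 1.0))
    mod_std = mod.std()
    if mod_std > 0:
        vol = vol + 0.08 * mod / mod_std
    if sig > 0:
        vol = gaussian_filter(vol, sig)
    mask = parcellation.labels > 0
    vol = np.clip(vol, 0.0, 1.0)
    vol[~mask] = 0.0
    return vol


def _subject_latent(config: CohortConfig, subject_id: str) -> float:
    rng = np.random.default_rng(
        [int(config.seed), 0x51A7, zlib.crc32(subject_id.encode("utf-8"))]
    )
    return float(rng.standard_normal())


def generate_subject_volume(
    config: CohortConfig,
    record: SubjectRecord,
    parcellation: Parcellation,
    template: np.ndarray | None = None,
) -> GMVolume:
    """One subject's gray-matter map under the cohort's generative model."""
    if record.group not in config.group_names:
        raise GmsnetError(
            f"subject group {record.group!r} not in config groups {config.group_names}"
        )
    if tuple(parcellation.labels.shape) != tuple(config.volume_shape):
        raise GmsnetError("parcellation grid does not match config.volume_shape")
    if template is None:
        template = _template(config, parcellation)
    mask = parcellation.labels > 0
    rng = _subject_rng(config.seed, record.subject_id)
    sig = _fwhm_to_sigma_vox(config.smoothing_fwhm_mm, config.voxel_size_mm)

    noise = rng.standard_normal(template.shape)
    if sig > 0:
        noise = gaussian_filter(noise, sig)
    s = noise[mask].std()
    if s > 0:
        noise = noise / s

    # "correlate": shrink the subject-specific field where shared structure
    # should dominate, before scaling to the cohort noise level
    for eff in config.effects:
        if eff.group == record.group and eff.mode == "correlate":
            sel = np.isin(parcellation.labels, eff.region_ids)
            noise[sel] *= 1.0 - eff.magnitude

    vol = template + config.noise_sigma * noise

    for eff in config.effects:
        if eff.group != record.group:
            continue
        missing = [
            r for r in eff.region_ids
            if not (parcellation.labels == r).any()
        ]
        if missing:
            raise GmsnetError(f"effect regions {missing} absent from parcellation")
        sel = np.isin(parcellation.labels, eff.region_ids)
        if eff.mode == "decorrelate":
            vol[sel] += (
                eff.magnitude * _DECORRELATE_SCALE * rng.standard_normal(int(sel.sum()))
            )
        elif eff.mode == "attenuate":
            vol[sel] *= 1.0 - eff.magnitude

    sm = config.symptom_model
    if sm.linked_metric is not None:
        # latent severity degrades cube similarity in a fixed subset of
        # parcels (the first third of region ids); the sigmoid bounds the
        # damage so thresholding always remains feasible
        u = _subject_latent(config, record.subject_id)
        w = sm.latent_noise_scale / (1.0 + np.exp(-u))
        n_hit = max(1, config.n_regions // 3)
        sel = (parcellation.labels >= 1) & (parcellation.labels <= n_hit)
        if w > 0:
            vol[sel] += w * rng.standard_normal(int(sel.sum()))

    vol = np.clip(vol, 0.0, 1.0)
    vol[~mask] = 0.0
    return GMVolume(values=vol, voxel_size_mm=config.voxel_size_mm, brain_mask=mask)


def _make_records(config: CohortConfig) -> list[SubjectRecord]:
    cov = config.covariate_model
    sm = config.symptom_model
    records: list[SubjectRecord] = []
    idx = 0
    for g, n in zip(config.group_names, config.n_per_group):
        for _ in range(n):
            idx += 1
            sid = f"sub-{idx:03d}"
            rng = np.random.default_rng(
                [int(config.seed), 0xC0F, zlib.crc32(sid.encode("utf-8"))]
            )
            age = max(cov.age_min, float(rng.normal(cov.age_mean, cov.age_sd)))
            sex = int(rng.random() < cov.p_male)
            edu = max(5.0, float(rng.normal(cov.education_mean, cov.education_sd)))
            scores: dict[str, float] = {}
            if sm.linked_metric is None:
                for name in sm.score_names:
                    scores[name] = float(rng.normal(25.0, 8.0))
            else:
                u = _subject_latent(config, sid)
                for name in sm.score_names:
                    eps = float(rng.standard_normal())
                    # higher latent -> noisier volume -> lower efficiency,
                    # so flip the sign to link the score positively to the metric
                    z = -sm.r * u + np.sqrt(max(0.0, 1.0 - sm.r**2)) * eps
                    scores[name] = 25.0 + 8.0 * z
            records.append(
                SubjectRecord(
                    subject_id=sid, group=g, age=age, sex=sex,
                    education=edu, symptom_scores=scores,
                )
            )
    return records


def iter_subject_volumes(
    config: CohortConfig,
    parcellation: Parcellation | None = None,
    records: list[SubjectRecord] | None = None,
) -> Iterator[tuple[SubjectRecord, GMVolume]]:
    """In-memory cohort stream (no disk I/O)."""
    if parcellation is None:
        parcellation = generate_parcellation(
            config.volume_shape, config.n_regions, config.seed
        )
    if records is None:
        records = _make_records(config)
    template = _template(config, parcellation)
    for rec in records:
        yield rec, generate_subject_volume(config, rec, parcellation, template)


def generate_cohort(
    config: CohortConfig, out_dir: str | Path
) -> tuple[list[SubjectRecord], Parcellation, pd.DataFrame]:
    """Write a full cohort to disk: NIfTI volumes, parcellation, subject TSV."""
    out = Path(out_dir)
    try:
        (out / "volumes").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise GmsnetError(f"cannot write to output directory {out}: {exc}") from exc

    parc = generate_parcellation(config.volume_shape, config.n_regions, config.seed)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    nib.save(
        nib.Nifti1Image(parc.labels.astype(np.int16), affine),
        str(out / "parcellation.nii.gz"),
    )
    records = _make_records(config)
    rows = []
    updated: list[SubjectRecord] = []
    template = _template(config, parc)
    for rec in records:
        vol = generate_subject_volume(config, rec, parc, template)
        rel = f"volumes/{rec.subject_id}_gm.nii.gz"
        nib.save(
            nib.Nifti1Image(vol.values.astype(np.float32), affine),
            str(out / rel),
        )
        rec = SubjectRecord(
            subject_id=rec.subject_id, group=rec.group, age=rec.age, sex=rec.sex,
            education=rec.education, symptom_scores=rec.symptom_scores,
            volume_ref=rel,
        )
        updated.append(rec)
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": round(rec.age, 4),
            "sex": rec.sex,
            "education": round(rec.education, 4),
        }
        for name, v in rec.symptom_scores.items():
            row[f"score_{name}"] = round(v, 4)
        row["volume_path"] = rel
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    return updated, parc, table


def load_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_volume(path: str | Path) -> GMVolume:
    """Read a gray-matter NIfTI; the brain mask is where values > 0."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    vox = float(img.header.get_zooms()[0])
    return GMVolume(values=data, voxel_size_mm=vox, brain_mask=data > 0)


def load_parcellation(path: str | Path) -> Parcellation:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    n = int(labels.max())
    names = [f"R{k:03d}" for k in range(1, n + 1)]
    return Parcellation(labels=labels, region_names=names)
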