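# Methods

`gmsnet` implements single-subject similarity-based gray-matter network
analysis: from a segmented gray-matter (GM) probability volume it builds a
binary similarity graph over small cortical patches, collapses that graph
onto a fixed parcellation to obtain a same-size weighted network for every
subject, characterizes the networks with graph-theoretic metrics across a
sparsity range, and compares three groups statistically. This note records
the model, the parameter choices, the numerical conventions, and what the
synthetic cohorts do and do not emulate.

## Cube similarity graphs

The subject's volume is tiled from voxel (0,0,0) in steps of 3 into
non-overlapping, axis-aligned 3×3×3-voxel cubes; trailing partial slabs are
dropped, and a cube is retained when at least half of its 27 voxels lie in
the brain mask (`min_gm_fraction = 0.5`; the inclusion rule is a package
choice — a cube straddling the mask edge carries mostly background). Keeping
cubes rather than single voxels preserves local 3D structure: similarity is
the Pearson correlation of two cubes' 27-voxel value vectors, which responds
to the spatial pattern inside the cube, not only its mean intensity. An
optional `rotation_mode="max_over_rotations"` scores each pair by the
maximum correlation over the 24 proper rotations of one cube's value block;
the default is the plain correlation.

**Permutation null and threshold.** Chance similarity is estimated by
sampling random cube pairs (default 100,000) and randomly permuting the 27
values of one member before correlating — the value histogram is preserved,
the spatial arrangement destroyed. The binarization threshold r\* is the
smallest observed correlation such that

    expected chance edges at r* / observed edges at r*  <  5%,

where the expected count is P(null > r\*) × (number of cube pairs). Because
the null tail probability is itself a Monte-Carlo estimate, the selection
rule uses an upper confidence bound on it (3 standard errors plus one
resolution unit). Without the bound the achieved rate hugs the 5% target and
an independently re-estimated rate exceeds it for about half the subjects;
with it, achieved rates settle near 4.5% and independent re-estimates stay
below 5% (across-subject SD ≈ 0.002–0.003). Only positive correlations can
survive (r\* > 0 is enforced). Constant-valued cubes have undefined
correlation; they are excluded from the graph but kept in the cube set so
that they still count toward regional cube totals.

## Atlas normalization

Cube graphs differ in size across subjects, and nearly every graph metric
depends on network size, so each cube graph is collapsed onto a fixed
parcellation (90 regions by default, mirroring an AAL-style atlas). A cube
belongs to the region holding the plurality of its voxels — plurality among
labeled voxels, ties to the lowest region id, cubes with no labeled voxel
dropped. The weight between regions i ≠ j is

    w_ij = (# cube edges between i and j) / (n_i × n_j),

the fraction of possible inter-regional cube pairs that are connected, hence
bounded in [0,1]. Within-region edges are excluded (the diagonal is zero by
construction) but reported in diagnostics as a per-region cohesion signal.
Regions that receive no cubes yield zero rows rather than missing values so
that downstream thresholding stays well defined; the event is warned about
and logged.

## Graph metrics over the sparsity grid

Weighted networks are binarized at each sparsity level S of the grid
0.10, 0.11, …, 0.34 (25 levels) by keeping the `round-half-up(S·n(n−1)/2)`
strongest positive weights; ties break by weight descending then (row, col)
ascending, which makes the selection deterministic and the edge sets nested
across S. The grid endpoints follow the common connectome-toolbox
convention for the range in which such networks remain small-world; both the
grid and the rounding rule are configurable/documented defaults. If a
network has fewer positive weights than requested, all are kept and the
achieved sparsity recorded.

On each binary graph the package computes the clustering coefficient Cp
(mean over nodes of 2E_i/(k_i(k_i−1)), zero for degree < 2), characteristic
path length Lp (mean shortest path over *connected* ordered pairs, with a
connectedness flag — this avoids infinities on fragmented graphs), global
efficiency Eglob (mean of 1/d over all ordered pairs, 1/∞ = 0), local
efficiency Eloc (mean over nodes of the global efficiency of each node's
neighbor subgraph), and the nodal centralities κ (degree) and e (mean
inverse distance to all other nodes, normalized by n−1). Nodal metrics are
computed on the binary graphs, consistent with degree being a count.
Distances come from breadth-first search (scipy's sparse shortest-path);
all metric formulas are implemented directly and verified against networkx
as an independent oracle.

Cp and Lp are normalized by the means of an ensemble of degree-preserving
random networks (default 100; the rewiring performs 10 attempted
double-edge swaps per edge, rejecting self-loops and multi-edges — the
Maslov–Sneppen procedure). This yields γ = Cp/C_random, λ = Lp/L_random,
and the small-world scalar **σ = γ/λ**; σ > 1 together with γ > 1 and λ ≈ 1
is the small-world signature. (Some texts write the ratio the other way;
the γ/λ form is the one under which "σ > 1" characterizes small-worldness,
and it is what this package computes.)

Each metric's curve over the grid is summarized by its trapezoidal area
under the curve (AUC), avoiding any single arbitrary threshold. The AUC of
a constant curve c equals c × 0.24 on the default grid.

## Group inference

AUC metrics are compared across the three groups with a classical one-way
ANOVA, followed by pooled-variance two-sample t tests. For the nodal
centralities each metric is corrected as its own Bonferroni family of
`n_regions` tests at α = 0.05; post hoc tests run only where the corrected
ANOVA is significant. "Aberrant" nodes are those significant in at least
one of κ or e.

**Network-based statistic.** Edge weights among the aberrant nodes are
Fisher z-transformed (atanh, with weights at 1 clipped to 1−10⁻⁶) and
compared pairwise between groups. Edges with |t| above the primary
threshold (default 3.1) form the suprathreshold graph; its connected
components are candidate effects, and the family-wise-error p of a
component of extent m is (1 + #{permutations whose maximal null component
extent ≥ m})/(B+1) over B label permutations (default 5,000). The |t| form
treats both directions symmetrically; the +1 convention keeps p > 0;
component size is measured by extent (edge count) only.

**Partial correlations.** Metric-symptom associations within each patient
group are Pearson correlations of residuals after linear adjustment for
age, sex (0/1), and education, with p from a t reference on n−2−k degrees
of freedom. Rank-deficient covariate designs raise an explicit error.

## Synthetic cohorts

The generator emits the inputs the analysis expects without any
acquisition or preprocessing chain: GM probability maps on an isotropic
2 mm grid, smoothed with a 6 mm FWHM Gaussian kernel — the two values that
define the resolution regime of the method — plus a parcellation and a
subject table. The brain mask is an axis-aligned ellipsoid inscribed in the
grid; parcels are nearest-centroid cells of a seeded k-means over in-mask
voxels (convex, hence contiguous; every parcel holds ≥ 27 voxels), relabeled
in lexicographic centroid order. A real atlas label volume can be supplied
as a drop-in replacement.

Each subject volume is a shared template (per-parcel mean GM levels drawn
once per cohort in 0.35–0.70, plus a broad smooth modulation) plus a
subject-specific Gaussian random field smoothed at the same FWHM and scaled
to σ = 0.1 within the mask, clipped to [0,1]. Spatial smoothness is the one
property the cube-correlation method measures, so it is the one property
the generator reproduces carefully; template intensity levels are free
parameters chosen to sit in a plausible GM-probability range. Group effects
are planted per parcel: *decorrelate* adds unsmoothed white noise (std
0.25 × magnitude) destroying local similarity; *correlate* shrinks the
subject-specific field so shared structure dominates; *attenuate* scales
down the mean GM level. Covariates echo a young-adult clinical sample (age
~N(26,5), education ~N(13,3), sex Bernoulli 0.6) and carry no inferential
weight. Symptom scores are independent of the volumes by default (a true
null for the correlation stage); the optional linked model draws a latent
severity per subject that degrades cube similarity within a fixed third of
the parcels (bounded by a sigmoid so thresholding stays feasible) and
drives the score with correlation r — focal damage is used because it
moves network efficiency monotonically, whereas global noise mostly
reshuffles which edges survive sparsity thresholding.

Randomness is governed by one master seed; per-subject streams derive from
a stable CRC-32 hash of the subject id, so results are independent of
processing order and thread count.

**What the synthetic data does not emulate:** scanner acquisition, bias
fields, head motion, segmentation error, anatomical asymmetries, realistic
regional volumes, or between-subject registration error. Passing tests
therefore demonstrate the correctness and calibration of the *pipeline* —
thresholds control spurious edges, statistics are calibrated, planted
effects of the designed kind are recovered — not performance on real MRI.

## Problem sizes used in the test and acceptance runs

Simulations are scaled to routine-CI sizes as the package's own test
conditions: the main cohort is 21 subjects (7 per group) on a 36×42×36 grid
with 90 regions; random ensembles use 10 networks where curves are computed
for every subject (100-network ensembles are exercised in the rewiring
invariance check); NBS calibration uses 150–200 null replicates × 500
permutations; planted-effect recovery uses 25–50 replicates of 12-region,
10-per-group cohorts. The defaults shipped in `PipelineConfig` remain the
full-scale values (25-level grid, 100 random networks, t = 3.1, 5,000
permutations, α = 0.05, 5% spurious-rate target).

## Known limitations

- The threshold search scans observed correlation values; with very few
  cubes the ratio criterion is grainy and the achieved rate conservative.
- Lp on disconnected graphs averages connected pairs only; comparing Lp
  between graphs with very different connectedness should consult the
  `connected` flag.
- The toy parcellation is spatially compact but anatomically meaningless;
  region names R001…R090 carry no lateralization beyond the reported
  hemisphere flag (centroid side of the midline).
- ANOVA and t tests assume exchangeable, roughly normal AUC values; the
  permutation-based NBS carries no such assumption.
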