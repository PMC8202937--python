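# Methods

This note documents the models and procedures implemented in `hipponet`,
the synthetic study conditions used to validate them, the numerical
choices, and the known limitations.

## Connectivity construction

Cleaning is defined per run as an exact orthogonal projection: the series
is bandpass filtered (zero-phase, frequency-domain brick wall) to
0.008–0.09 Hz, then residualized on the *bandpassed* mean/linear/quadratic
trend basis and on the bandpassed confound columns.  Filtering the trend
and nuisance regressors into the same frequency range keeps the whole
operator idempotent — re-cleaning cleaned data is a no-op — and avoids
reintroducing out-of-band variance through regression.  Rank-deficient
confound matrices lose their dependent columns (QR with pivoting) with a
logged warning.  Runs are cleaned independently and concatenated before
correlation; whether to correlate concatenated runs or average run-wise
matrices is a genuinely open choice and concatenation was selected (a
config option exposes the split).  Fisher-z values are atanh(r) with |r|
clipped to 1 − 1e-7 before the transform.

Group matrices set each subject's negative edges to 0 *before* averaging
("drop the edge, keep the node"), keeping shapes stable and matrices dense.
Motion QC excludes subjects with mean frame displacement strictly greater
than 0.15 mm; subjects lacking an FD value are reported as unassessable
rather than silently kept.

## Community detection

Modularity uses the Newman–Girvan form with resolution γ; Louvain is the
standard two-phase algorithm (greedy single-node moves to the best
neighboring community, then community aggregation, repeated), with the node
visitation order a seeded shuffle per pass.  After the final aggregation
level a last single-node refinement pass runs on the original graph, which
guarantees the returned partition is a true single-node local optimum of Q
— the property the tests check exhaustively on small instances.

At each γ the algorithm runs `n_iter` times; every run is scored
Q × mean pairwise z-Rand against the other runs at that γ, and the
best-scoring run represents the γ.  The representative-partition rule is an
artifact convention: the selection literature scores partitions this way
but does not fix which single partition is carried forward.  Pairwise
z-Rand means use unordered pairs (the factor cancels in ranking); duplicate
partitions are grouped so each unique pair is evaluated once.

The z-Rand score is the pair-counting z-statistic: the number of node
pairs co-clustered by both partitions, standardized by its exact mean and
variance under random relabelling (hypergeometric model, Brennan–Light
moments).  The analytic variance is cross-checked in the tests against an
explicit 40,000-permutation oracle at 5% tolerance.  Degenerate partitions
(all singletons, or a single community) have zero permutation variance and
score 0 by convention.  "Adjusted z-Rand" and "z-Rand" are treated as the
same statistic.

Resolution selection maximizes the representative weighted score among
resolutions whose representative partition separates the primary
sensory-motor seed networks.  The criterion is programmatic: each seed
set's modal community must be distinct from every other seed set's modal
community.  Neighbor-stability across nearby γ is visible in the sweep
report but is not an additional numeric rule — the reported procedure is
score maximization subject to the separation criterion.  Sub-community
re-partition sweeps a finer grid (0.75–1.1 by 0.05 by default) and returns
the partitions at local score peaks (strict one-sided comparisons at the
endpoints); the global peak is marked selected.

Split-half and cross-cohort comparisons are expressed as z-Rand plus a
label-agreement fraction, where communities are matched one-to-one by
maximum-weight bipartite matching on shared-node counts before counting
agreeing nodes.

## Path-length and lesion analysis

Edge weights invert to lengths d = 1/w, as stated; −log w was rejected as
unsupported.  Zero-weight pairs are absent edges; geodesics come from
Dijkstra on the remaining graph, and unreachable pairs are +inf.  Set-wise
path length is the mean over all cross-set pairs; infinite pairs are
excluded from the mean and surfaced as a disconnection fraction — dense
FC graphs essentially never disconnect, so when it does happen the
behavior must be visible rather than silent.

The random-removal null draws k nodes per iteration from all nodes
*outside the source, target and protected sets*; the focal community
remains in the pool.  This matters: when the focal set is the only bridge
between source and target, draws that never touch it produce a
near-constant null (zero variance).  Subjects whose null SD is exactly 0
are flagged and excluded from the group test.

Distance-matched control sets match the focal network's mean
centroid-distance to each reference set within ±1 SD.  No standard search
procedure exists for this constraint, so a seeded randomized greedy swap
with restarts and a bounded budget is used; infeasibility (no candidate
inside a band, or budget exhaustion) raises an error carrying the
best-achieved deviations.

Participation coefficients are computed on proportionally thresholded
weighted graphs (strongest d-fraction of upper-triangle edges, weights
retained — binarization is exposed as an option but weighted is the
default) across densities 5–20% at 1%.  Nodes in the bottom strength
quartile (computed on the full nonnegative matrix, per subject) are flagged
excluded because low strength makes PC unstable; nodes isolated at a
density get no value there.  Values are clamped to [0, 1] against float
round-off at the boundaries.  Group comparisons between subnetworks use
within-subject paired tests rather than a mixed model — a deliberate
simplification of scope.

## Hippocampal profiles and contrasts

Profiles average *raw* Fisher-z FC (negatives retained) from each of the
four hippocampal ROIs to the cortical members of each network; hippocampal
nodes are never part of the cortical partition.  Membership screening is a
one-sample t per (network, ROI) with Bonferroni over networks × ROIs; a
hemisphere-pooled variant is also emitted because pooling across
hemispheres is a free choice.  The long-axis contrast averages hemispheres
within subject and pairs anterior vs. posterior; laterality averages axis
positions and pairs left vs. right; df = n − 1 throughout.

## Representational-profile similarity

First-order RDMs are Pearson correlations between trial patterns, with
pairs invalidated on the diagonal, within a scanning run, touching an
incorrect trial, or touching a constant pattern.  Second-order profiles
vectorize the valid upper triangle over the *intersection* of all ROIs'
masks so every ROI pair is compared on identical trial pairs; unequal
supports would make profile correlations incomparable.  Pearson is used at
both orders (Spearman is exposed as an option).  Confound removal is OLS
per subject on off-diagonal upper-triangle entries (intercept included);
the diagonal never enters regressions.  The within-vs-between contrast
excludes self-pairs, and a constant profile matrix is reported as t = 0
(true zero effect) rather than NaN.

## Meta-analytic decoding

A binarized mask is Pearson-correlated with each term map over the whole
provided grid; ranking is by descending r with ties broken by term token
for stable output.  Constant maps are skipped and reported.  Masks are
built from partition labels through a node→grid assignment table; term
curation is a user-supplied exclude list.

## Synthetic study conditions

The generator is a latent-factor model: node series are weighted sums of
latent signals plus Gaussian noise, so FC structure, lesion topology and
the hippocampal gradient all follow from one mechanism whose parameters
are loadings, not target correlations.  Default conditions (chosen once, as
the study conditions): 6 networks × 20 nodes + 4 hippocampal ROIs,
40 subjects, T = 400 at TR 1.22 s, unit within-network loadings,
noise SD 1 — within-network Fisher-z FC ≈ 0.6 against a between-network
background ≈ 0.04, which keeps the full pipeline at desk-scale runtimes
while preserving the structural motifs the analyses assume.

Planted motifs and their rationale:

* **Bridge.** `VIS` and `DMN` share no latent; each shares one bridge
  channel with `MTN` (loading 0.6).  Their direct FC is ~0 while each
  couples to the bridge at ≈ 0.14, so removing `MTN` severs the only
  strong route.
* **Sensorimotor background.** `AUD` and `SMN` share an extra latent
  (loading 0.65), making them the most strongly coupled network pair.  At
  low resolution they merge, so the sweep must move up before the
  sensory-separation criterion passes — the behaviour that motivates
  resolution tuning in the first place, and the mechanism that makes the
  selection rule land on the correct plateau rather than the lowest
  passing γ.
* **Subdivision.** `DMN` splits into three subnetworks (7/7/6) with
  additional subnetwork latents (loading 0.8), recoverable exactly on the
  finer grid.
* **Spatial mirror.** `FPN` sits at the mirror image of `MTN` relative to
  the `VIS`/`DMN` clusters, so a distance-matched control set exists by
  construction.
* **Long axis.** Anterior hippocampal ROIs load 0.7 on `MTN` and 0.3 on
  `DMN`; posterior 0.35 and 0.6 — anterior > posterior coupling to the
  medial-temporal analogue, reversed for the default-mode analogue.
  Loadings are hemispherically symmetric, so laterality contrasts are
  exactly null and their p-values calibrate against uniformity.
* **Trial tuning.** Each network owns a latent trial × feature tuning map
  (demeaned per trial row so it drives pattern structure without leaking
  into univariate activity); ROI patterns add private noise, a shared
  per-trial amplitude multiplying an ROI-specific static map (the
  univariate confound), and spatial latents whose ROI loadings come from
  factorizing the kernel √(1 − d/d_max) over centroid distance.  Because
  RDM-level shared structure scales with the *square* of loading overlap,
  the induced profile-similarity confound is linear in distance — exactly
  the form the linear distance residualization removes.  This is a design
  requirement, not a convenience: the confound-control checks demand that
  a distance-only generator nulls out after residualization.
* **Terms.** One planted term per network (+1 on its elements over unit
  noise) on a grid of 84 elements per cortical node (10,080 total), plus
  20 pure-noise fillers.

What the generator does **not** emulate: hemodynamics (no HRF convolution
or physiological noise spectra), spatial autocorrelation within ROI
patterns, heavy-tailed motion artifacts, inter-subject topology
differences, or negative-weight community structure.  Passing tests
therefore validate the *analysis machinery* — recovery, calibration,
determinism — not robustness to every property of real fMRI data.

## Numerical choices

* All randomness flows from one top-level seed through named
  `SeedSequence` substreams, so stages are independently reproducible and
  reordering stages never perturbs another stage's draws.
* Louvain move tolerance 1e-12; symmetric matrices enforced at 1e-10;
  canonical partition labels are 1..K by descending size with
  smallest-member tie-break (label numbering is an artifact convention).
* Proportional thresholding keeps round(d · n_pairs) edges; ties at the
  cut break by stable (row, col) order.
* Matrix TSVs are written with 10 significant digits, making re-runs with
  an identical config and seed byte-identical.
* Test and acceptance problem sizes (reduced γ grid 0.5–3.0 by 0.1 with
  100 iterations, 1,000-draw nulls, 200-replicate calibrations, 12-node
  permutation oracles) were chosen as the smallest instances that measure
  each property with comfortable statistical margin.

## Limitations

* The sensory-separation criterion is programmatic (seed-node modal
  communities); in practice such criteria are often applied by visual
  inspection, which this formalizes.
* Mixed-effects group models are replaced by within-subject paired tests
  throughout.
* The matched-control search is one admissible realization of an
  underdetermined requirement; different search strategies can return
  different (equally feasible) sets.
* Distance residualization in RSA removes a genuinely shared component
  when networks are spatially coherent (as they are here, and in real
  cortex): on a tuning-only generator it shifts the group t by about 10%.
  That reflects the statistics of the design, not an implementation
  artifact.
* Voxel-level preprocessing, anatomical segmentation, GLM pattern
  estimation and database curation are upstream of this package and are
  accepted as inputs.
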