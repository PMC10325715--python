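# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions behind reproducible output.

## The circuit being modeled

The vertical lobe (VL) of *Octopus vulgaris* contains on the order of
25 × 10⁶ cells. Its sensory input arrives on ~1.8 × 10⁶ superior frontal
lobe (SFL) axons that cross the lobe making en-passant synapses. Dense
reconstruction of a small volume identified seven connected cell types and
a strongly stereotyped wiring plan:

* each **SAM** (simple amacrine cell, ~89.3% of cortex cells) receives
  exactly one SFL input, on a vesicle-filled "palm" wrapped around a large
  SFL bouton (LB, 6.41 ± 2.1 µm³), and relays it to LN dendrites, CAMs and
  ascending fibers (AFs);
* each **CAM** (complex amacrine cell, ~1.6%) integrates dozens to
  hundreds of inputs (observed maximum 514) from SFL small boutons
  (SB, 0.95 ± 0.88 µm³), SAMs, and a dedicated afferent class (**CIN**)
  that contacts CAMs via polyadic boutons (median 2.3 sites per bouton);
* SAMs and CAMs converge onto the **LN** output dendrites; no direct
  SFL→LN contacts exist;
* the only directed cycles are rare reciprocal AF–AF synapse pairs (n=4);
  neuromodulatory fibers (**NM**) mostly release extrasynaptically.

Every analysis in the package is a statistic over this structure.

## Feed-forwardness

**Statistic.** An edge participates in feedback iff it lies on a directed
cycle, i.e. iff its endpoints belong to one strongly connected component
(SCC); the statistic sums synaptic sites over such edges. Counting SCC
membership instead of backward edges in one topological sort makes the
statistic independent of the arbitrary order; for the reciprocal-pair-only
feedback actually observed the two formulations flag the same synapses.
An autapse is a cycle of length one and is counted.

**Null model.** Random graphs conserve the neuron set, the multiset of
unordered connected pairs and the per-pair synapse totals, randomizing
only direction. Default mode `per_pair` assigns each pair's whole bundle
one uniform direction (never creating reciprocal pairs); `per_synapse`
directs each site independently with probability ½. `per_pair` is the
default because the randomization is described over *pairs of connected
neurons*; both modes are exposed.

**p-value.** One-sided for "observed unusually low", permutation-inclusive:
p = (1 + #{null ≤ observed}) / (1 + n_perm), so p ∈ (0, 1], ties count
against significance, and p is never zero. Default n_perm = 10,000.
The hot loop runs on a pair-array representation with
`scipy.sparse.csgraph` SCCs (~1 ms per permutation at 444 neurons /
~10⁴ synapses); the user-facing `find_feedback` additionally returns the
condensation in topological order via networkx.

**Calibration.** `type_one_error_rate` direction-randomizes the input
(so the null holds by construction), runs the test on the randomized copy
and reports the fraction of p < α over replicates. Problem sizes used by
the test suite and acceptance script: 200 replicates at n_perm = 99
(with the add-one formula, p < 0.05 ⟺ at most 3 of 99 null draws at or
below the observed value), which keeps the full calibration to ~30 s.
Observed rates land at 0.02–0.05 — calibrated and slightly conservative,
as the add-one formula implies.

## Connectivity similarity and embedding

With adjacency **A** (A[i,j] = synaptic sites i→j, node order sorted by
id), shared outputs are **A Aᵀ** and shared inputs **Aᵀ A**; both are
exact integer products, checked against O(N³) shared-partner counting.
Autapses are excluded from the products by default (a self-synapse is not
a shared partner); an `include_autapses` flag restores them.

The embedding takes the top-k eigenvectors of the combined matrix
**A Aᵀ + Aᵀ A** (positive semidefinite, so a dense symmetric
eigendecomposition suffices), scaled by √λ, with the deterministic sign
convention that each eigenvector's largest-magnitude entry is positive.
k defaults to 100; the planar picture uses the first two dimensions —
a convention, since any informative pair of leading dimensions would do;
k and the projection are configurable. The type-level diagram keeps
edges with **strictly more than** `min_synapses` sites (default 10); the
boundary is intentionally strict. Node positions come from a seeded
networkx spring layout, and per-neuron display positions are the type
anchor plus `scale` × the neuron's (max-norm standardized) first two
embedding dimensions.

## Soma morphometry, classification and census

**Ellipsoid fit.** Voxel coordinates are scaled by the anisotropic voxel
size, their covariance eigendecomposed, and semi-axes set to √(5λᵢ) — the
moment match for a *uniform solid* ellipsoid (a surface shell would give
√(3λ); somata are solid). Coplanar masks raise an error naming the flat
axis.

**Features.** Volume = voxel count × voxel volume (the ellipsoid volume
4/3 π a b c is exported as an auxiliary column); surface area by the
Thomsen approximation (p = 1.6075, max relative error ≈ 1.06%; the exact
quadrature is available behind `exact=True` and serves as the test
oracle); sphericity by Wadell's Ψ = π^⅓ (6V)^⅔ / A.

**Classifier.** RBF-kernel SVM on standardized features, C and γ chosen
by a small grid inside stratified 5-fold CV, deterministic under the seed.
Validation is leave-one-out; the hyperparameters are selected once on the
full set and reused per fold (refitting the grid inside each fold is
noisier than helpful at n ≈ 110). Training mix defaults to the 110-cell
expert-typed composition (69 SAM / 16 CAM / 7 LN / 18 Other).

**Census.** fraction = class count / n; estimate = fraction × total
(default 25 × 10⁶ cells); upper bound = (fraction + validation error
rate) × total. Estimates conserve the total by construction.

**Vesicle separation.** Painted vesicle regions in 2-D sections are
separated by a watershed on the negated Euclidean distance transform
seeded at its local maxima; per vesicle the centroid and equal-area disc
radius √(area/π) are reported. Counts are an upper bound: at 30 nm
section thickness only the largest vesicles span two sections, and
double-counting across sections cannot be excluded.

## Skeletonization and wire length

Objects are thinned with Lee's 3-D medial-axis algorithm
(`skimage.morphology.skeletonize`), which preserves homotopy, so loops in
the object survive as skeleton cycles. Skeleton voxels become graph nodes;
edges join 26-neighbors with Euclidean weights after anisotropic scaling.
Spur branches shorter than `prune_voxels` (default 2) that end at a
junction are removed as rasterization hair; pruning is off-switchable.

Wire length: degree-2 chains are contracted into weighted super-edges
(results identical, large speedup); a super-edge counts iff it is itself a
shortest path between its endpoints — by the subpath property this equals
the union of all shortest leaf/branch-point paths, each edge counted once.
In an acyclic skeleton every edge qualifies (so unbranched objects, whose
only special nodes are their two leaves, get their full length — they
must, or a straight axon would measure zero); around a topological hole
only the shorter route counts and loops back to a single junction are
excluded. A component with no special node at all is a bare cycle and is
reported at its full circumference, cycle-flagged. Cycle detection
ignores fundamental cycles of ≤ 3 edges: mutually 26-adjacent voxels at
bends form triangles that are adjacency artifacts, not object loops.

Accuracy on rasterized ground truth: straight axis-aligned runs are exact;
oblique runs overshoot by the diagonal-stepping metric (bounded well
under 8% at 45°); thinning erodes rounded end caps by about one radius
per end, keeping a 50 µm tube of radius 1 µm within 5%.

## Bouton statistics

**LB/SB split.** A two-component Gaussian mixture is fitted on the
volumes and each bouton labeled by posterior, the higher-mean component
being LB. The fit is on the **linear** µm³ scale by default: measured
bouton volumes behave like two roughly normal components, and under a log
transform the small component's left tail (volumes near the detection
floor) is stretched into extreme outliers that a mixture collapses onto.
`scale="log"` is available for data where both components are genuinely
multiplicative. All-equal input degenerates to a single component with a
warning.

**Permutation tests.** Two-sample difference of group means; all
C(n_a+n_b, n_a) assignments are enumerated exactly when there are at most
10⁶ of them, otherwise Monte-Carlo with the add-one p. Multiple
comparisons use Holm's step-down procedure (the "sequential Bonferroni"),
via statsmodels.

**Densities and representation.** Per-axon density = 100 × count /
length; population mean ± SD over axons; zero-length axons are excluded
with a warning. The representation arithmetic: with on average m large
boutons per afferent and a one-input-per-target rule, an afferent is
represented in m ± √m target cells (Poisson); the expansion ratio is
n_target / n_source. `projected_span` returns both 100·n/density and
100·(n+1)/density — the mean axon length carrying n boutons versus the
mean length up to the (n+1)-th bouton of a Poisson process; printed
span figures are ambiguous between the two conventions, so both are
labeled rather than one asserted. Reported rounding (whole percentages
for connectivity fractions, two decimals for SDs, millions/thousands for
census totals) is centralized in `vlconn.reporting`.

## The synthetic-circuit generator

The generator exists so that every analysis has ground truth. Defaults
encode the measured study conditions:

* **counts** — 84 SFL axons, 108 SAMs, 53 CAMs, 24 LN processes, 55 CINs,
  32 AFs, 88 NMs (444 neurons), in a 260 × 390 × 27 µm volume;
* **wiring** — each SAM draws one SFL LB input; each CAM draws a
  log-uniform in-degree on [30, 514] ("dozens to hundreds") filled at the
  observed input mix (48% SFL / 42% SAM / 5% CIN / 5% NM), CIN synapses
  polyadic with 1 + Poisson(1.3) sites (median 2); each SAM adds
  Poisson(6.5) outputs over LN/AF/NM at the identified output counts
  109:70:2 (SAM→CAM edges are drawn from the CAM side to avoid double
  specification; the printed "35%" SAM→LN share is inconsistent with its
  own counts 109/271 = 40.2%, so the count-derived mix is used); CAMs
  make Poisson(10) en-passant LN contacts; CINs occasionally contact AFs.
  The type order SFL < CIN < SAM < NM < CAM < AF < LN makes everything
  acyclic by construction; exactly `n_reciprocal_af_pairs` (default 4)
  disjoint AF pairs then receive one synapse each way — the only cycles.
  A configuration demanding more SAMs than the SFL population's expected
  LB supply (n_SFL × rate × tract length) is rejected;
* **somata** — volumes per class: SAM truncated-normal 207.7 ± 26.1 µm³,
  CAM 337.2 ± 41.6 µm³, LN uniform on 464–2850 µm³, "Other" (glia,
  progenitor-like cells; no published statistics) truncated-normal
  400 ± 180 µm³ chosen to overlap SAM/CAM in volume so that shape, not
  size, separates it. Axis ratios produce the sphericity ordering
  SAM > CAM > Other (SAM roundish 1 : 0.95 : 0.9, CAM 1.5 : 1 : 0.85,
  LN 1.8 : 1 : 0.9, Other elongated 3.5 : 1 : 0.8, each log-jittered 5%);
  masks are ideal rasterized ellipsoids in random orientation. The soma
  raster voxel defaults to 256 × 256 × 240 nm — coarser than the
  8 × 8 × 30 nm imaging voxel, at which a 200 µm³ soma would span ~10⁸
  voxels; a SAM still covers ~13,000 voxels, ample for moment fitting,
  and a configuration leaving the smallest class under 50 voxels errors;
* **boutons** — LB placement is a homogeneous Poisson process at
  1.03 per 100 µm; the SB rate is not printed and is derived from the
  45 : 109 LB : SB output counts as 1.03 × 109/45 ≈ 2.49 per 100 µm;
  volumes come from the truncated-normal components above. 84 axons of
  100 µm yield ≈ 295 boutons, the reported bouton count (axon segments
  are only partially contained in such a volume);
* **tubes** — constant-radius tubes around polylines with the analytic
  centerline length and a cycle flag recorded, the ground truth for the
  wire-length pipeline.

**What the generator does not emulate:** electron-microscopy image
texture, membrane probability maps, segmentation or alignment artifacts,
vesicle ultrastructure, spatially structured synapse placement (positions
are uniform in the volume), columnar fasciculation, and soma surface
noise beyond axis jitter. Tests passing on synthetic circuits therefore
validate the *statistics* — not robustness to reconstruction error in
real volumes.

## Determinism

Every stochastic operation takes an explicit seed; a fixed configuration
and seed reproduces output bit-for-bit. The acceptance script derives all
sub-seeds from its single `--seed` argument. Eigenvector signs, node
orders and CSV column orders are fixed so that repeated runs produce
byte-identical files.

## Known limitations

* The generator's aggregate SAM out-degree is approximate (SAM→CAM edges
  are governed by CAM in-degrees), so per-SAM output counts are not a
  calibrated quantity.
* The wire-length estimator inherits thinning's end-cap erosion (~one
  radius per leaf) and diagonal-metric overshoot; both are small for
  neurite-like aspect ratios but systematic.
* The vesicle count is an upper bound by design.
* `scale="log"` mixture fits are provided but degrade when a component
  abuts zero volume; the linear default is recommended for bouton data.
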