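# Methods

This document defines every quantity the package computes, the default
parameters and their rationale, the synthetic-data model and its limits,
and the deliberate numerical choices.

## Parcellation and hemispheric blocks

The bundled atlas has 246 nodes, 123 per hemisphere, organized into 24
area groups per hemisphere (48 areas total; 210 cortical and 36
subcortical nodes). Node ids are 1-based and canonically ordered: left
hemisphere 1–123, right hemisphere 124–246, so the left/right
intra-hemispheric quadrants of a 246×246 adjacency are the leading and
trailing 123×123 blocks. Node centroids for toy forward models use the
medoid voxel (the member voxel minimizing the summed squared distance to
all member voxels, ties resolved to the smallest linear index), which is
guaranteed to lie inside the region.

## Trial segmentation and frequency bands

Recordings are segmented into 3-s trials; for the delta band, consecutive
3-s trials (consecutive by trial index) are concatenated into 12-s trials
so that at least three frequency bins fall inside the band. Bands:
delta 0.5–3 Hz (12-s trials), theta 4–7, alpha 8–13, low beta 13–20, high
beta 20–30, low gamma 30–50 Hz (3-s trials). Trial lengths are
sample-quantized: a "3-s" trial at 678.17 Hz is 2035 samples ≈ 3.0007 s,
so segment and band-average checks use a half-sample tolerance rather
than exact float equality.

## Beamformer

Linearly constrained minimum variance (LCMV) with:

- broadband covariance pooled over all trials (sample covariance of the
  concatenated, mean-removed data);
- Tikhonov regularization `C + λ·mean(diag eig)·I` with λ = 0.05 (5% of
  the mean eigenvalue), keeping the inverse stable at modest trial
  counts;
- dipole orientation per node chosen analytically as the generalized
  eigenvector of `(Lᵀ C⁻¹ L)⁻¹` with the **largest** output power
  ("max-power" criterion; `min_power` is available). The orientation
  eigenvector has an inherent sign ambiguity; all phase-lag estimators
  downstream are invariant to it.
- weights `w = C⁻¹ l / (lᵀ C⁻¹ l)` with `l = L·η`, giving exact unit gain
  `wᵀl = 1` (verified to 1e-10 in the acceptance suite).

## Connectivity: dwPLI

For each node pair, trial cross-spectra are computed with a Hann window.
With `Im sₖ` the imaginary cross-spectrum of trial k at one bin,

- PLI = |mean sign(Im sₖ)|
- wPLI = |Σ Im sₖ| / Σ |Im sₖ|
- **dwPLI** = ((Σ Im sₖ)² − Σ (Im sₖ)²) / ((Σ |Im sₖ|)² − Σ (Im sₖ)²),
  with 0/0 defined as 0.

The dwPLI is the debiased (U-statistic) estimator: it averages
`Im sⱼ · Im sₖ / (|Im sⱼ|·|Im sₖ| …)` over **ordered pairs of distinct
trials**, so under the null of no lagged coupling its expectation is 0,
whereas wPLI² is positively biased at finite trial counts. The acceptance
suite verifies |mean null dwPLI| < 0.01 at 40 trials while mean wPLI²
≈ 0.05. A worked example: Im s = (+1, +1, −1, +1) over four trials gives
PLI = wPLI = 0.5 but dwPLI = (2² − 4)/(4² − 4) = 0, which full
enumeration of the 12 ordered trial pairs confirms.

Per-bin dwPLI values are averaged over the bins inside each band (values
clipped to [0, 1]); requesting a band whose bin grid does not fit the
trial length (delta on 3-s trials) is an error rather than a silent
empty average. Negative per-bin dwPLI values (possible at finite
samples) are clipped at 0 before band averaging, keeping adjacency
weights valid edge weights.

## Graph measures

Each hemispheric quadrant is proportionally thresholded to keep the
strongest 10% of edges (ties broken lexicographically by node pair for
determinism); retained weights are **not** binarized. Edge lengths are
1/w. Then:

- **GE**: mean of 1/d(i,j) over all ordered pairs, with 1/∞ = 0, so
  disconnected pairs count as zero efficiency.
- **CPL**: mean of finite d(i,j); if no finite paths exist CPL is NaN and
  a warning is raised. (Computing CPL on finite distances only, rather
  than ∞, is the standard convention for possibly-disconnected graphs.)
- **T** (transitivity) and nodal clustering **CC**: Onnela's weighted
  form with weights normalized by the graph maximum,
  ŵ = w/max(w); T = Σᵢ Σ_{jk} (ŵᵢⱼŵⱼₖŵₖᵢ)^{1/3} / Σᵢ kᵢ(kᵢ−1).
  Note T is scale-invariant: multiplying all weights by a constant leaves
  it unchanged.
- **NE** (nodal efficiency): mean of 1/d(i,j) over j ≠ i.
- **BC**: Brandes' weighted betweenness with shortest-path tie detection
  at relative tolerance 1e-10; reported normalized by (N−1)(N−2) by
  default.
- **EVC**: leading eigenvector of the weight matrix, nonnegative,
  unit-norm.

All seven measures are cross-checked against independent brute-force
implementations (Floyd–Warshall, exhaustive path enumeration, explicit
triangle sums, power iteration) on random graphs to 1e-9.

## Network-based statistic (NBS)

Edge-wise two-sample pooled-t statistics between groups; edges exceeding
the primary threshold (default 3.45) form suprathreshold components
(connected components of the thresholded t-graph); the test statistic is
the component extent (edge count). Group labels are permuted (default
5000 permutations) and the maximum null component extent recorded per
permutation; the familywise-corrected p of an observed component of
extent e is (k+1)/(P+1) with k the number of null maxima ≥ e. Direction
is one-sided by default configuration of the calibration experiments
("A_gt_B" / "B_gt_A"), or "both", in which case each direction is
calibrated against its own one-sided null maxima. Public component edge
and node ids are 1-based (atlas convention).

The permutation stream indexes subject positions, so reordering subjects
within groups leaves the observed t-map and components bit-identical but
produces a different (statistically equivalent) realization of the
permutation null; p-values agree to Monte-Carlo accuracy.

## Group statistics and classification

Feature vectors are GE/CPL/T per band and quadrant
(`<measure>_<band>_<side>`, 36 features at six bands). LP vs RP
comparisons use the two-sided Wilcoxon rank-sum test (exact when both
n ≤ 10 without ties, normal approximation with tie/continuity correction
otherwise) with Benjamini–Hochberg FDR across features; features with
adjusted p < 0.05 are selected. Gaussian Naive Bayes is evaluated with
stratified 10-fold cross-validation repeated 100 times (fresh
partitions), reporting mean ± SD accuracy and per-class one-vs-rest
sensitivity, specificity, precision and ROC AUC from class posterior
probabilities, plus prevalence-weighted averages.

The cohort-matching battery recomputes two-group demographics: pooled
two-sample t from summary statistics, Fisher's exact test for 2×2
tables, the Freeman–Halton extension for r×c tables (full enumeration of
tables with the observed margins, summing probabilities ≤ the observed
table's, with 1e-7 relative slack against float noise), and Wilcoxon for
ordinal counts. The two continuous rows are reproducible only to the
third decimal because their published inputs are rounded to one decimal.

## Synthetic cohort model

Each coupled edge (i, j) shares a band-limited complex Gaussian carrier:
at each band bin, `X_j = √c·X_i·e^{−iφ} + √(1−c)·noise`, so the coupling
fraction c and lag φ fully determine the expected dwPLI. The expected
value has a closed form up to one quadrature: wPLI = √c·|sin φ| / E|Im s|
with E|Im s| the folded-normal mean integrated over the Exp(1)
distribution of |X_i|²; dwPLI converges to wPLI². The generator is
validated against the estimator on simulated trials.

Default three-group design: 22 HC, 25 LP, 16 RP (an unbalanced clinical
design). All edges carry a diffuse background coupling of 0.08 at 90°
lag (adjacency ≈ 0.27, keeping values away from the [0,1] clip
boundaries); subject matrices are the expected adjacency plus N(0, 0.05)
between-subject noise, symmetrized and clipped.

The implanted group effect is **focal**: the RP group's theta coupling is
raised by Δ = 0.10 on every edge of the clique over the first 25
right-hemisphere nodes (300 edges; adjacency increase ≈ 0.18 per edge,
3.6× the between-subject SD). A focal clique rather than a uniform shift
of the whole right block is essential: Onnela transitivity normalizes by
the quadrant's maximum weight, and a uniform shift under proportional
thresholding leaves the retained edge set and the normalized weights —
hence T — essentially unchanged. The boosted clique raises triangle
weights relative to the rest of the quadrant and moves GE (up), CPL
(down) and T (up) together, which is the qualitative pattern the
pipeline is designed to detect.

Limits of realism: carriers are Gaussian (no 1/f spectrum, no
nonstationarity), lead fields are toy dipole models rather than a
realistic head model, sensor noise is white, and adjacency-mode subjects
skip the forward/inverse chain entirely. The sensor mode exercises the
beamformer + connectivity path end to end but only at small node counts.

## Reproducibility

All randomness derives from a single root seed via `SeedSequence`
substreams per pipeline stage; the run manifest records a SHA-256 per
output file and is byte-identical across reruns of the same
configuration. Cohort generation is a pure function of its spec. The
full acceptance suite (`python scripts/acceptance.py --seed 1 --out
results/acceptance.json`) runs offline in about two minutes.
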