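# Methods

## The construction

`morphconn` estimates an individual structural connectome without tract
tracing or functional time series.  The regional descriptor is a vector of
morphometric features (vertex count, surface area, gray-matter volume,
thickness mean/SD, mean curvature, Gaussian curvature, fold index,
curvature index) measured per Desikan–Killiany region in native space, and
the inter-regional connection weight is the Pearson correlation of two
regions' standardized feature vectors.  The underlying assumption is that
regions with coordinated morphology (jointly large/thick/folded relative to
the rest of that brain) are more likely to be connected or co-developed.

Steps, per subject and session:

1. z-score each feature across the 68 regions (sample SD, `ddof=1`).  The
   standardization is strictly within-subject: pooling across subjects
   would leak population structure into a single-subject network, defeating
   the purpose of an individual connectome.  (A pooled mode is not offered
   for this reason; z-scoring is exposed only per subject/session.)
2. Pearson-correlate the 68 standardized feature vectors pairwise and take
   absolute values, so strong anti-correlations also become connections.
3. Binarize at sparsity s by keeping the k = round(s·2278) largest |r|
   off-diagonal pairs, over the sweep s = 0.20…0.40 in 0.01 steps, with
   s = 0.23 highlighted for cross-study comparison.  The sweep endpoints
   follow the usual requirements that the minimum sparsity leave no node
   isolated (a warning is emitted when violated) and the maximum preserve
   small-worldness.

### Numerical choices

* **k rounding** is round-half-away-from-zero; the ratio definition of
  sparsity does not determine the rounding rule, so one is fixed and
  tested.
* **Ties in |r|** are broken lexicographically by region-pair index.  Ties
  have probability zero on real-valued data but occur in constructed test
  matrices; a fixed total order also guarantees that edge sets are nested
  across the sweep, which the tests exploit.
* **Self-correlations** are excluded before ranking (no self-loops).
* Binarization requires the explicit absolute-valued matrix; passing a
  signed matrix is an error rather than a silent `abs`.

## Graph measures

* Clustering: Cᵢ = 2Eᵢ/(kᵢ(kᵢ−1)), defined as 0 for degree < 2; Cp is the
  unweighted mean over all 68 nodes.
* Path length: the harmonic-mean form
  Lp = [ (1/(N(N−1))) Σ_{i≠j} 1/d(i,j) ]⁻¹ with disconnected pairs
  contributing zero inverse distance.  Thresholded brain networks are not
  guaranteed connected, and this form absorbs disconnected pairs without
  arbitrary penalties.
* Betweenness: Freeman betweenness, unnormalized, each unordered pair
  counted once — on 68 nodes hub values then land in the tens-to-hundreds
  range, the scale on which the hub literature reports them.  A normalized
  option divides by (N−1)(N−2)/2.
* Hub rule: BC strictly greater than mean(BC) + SD(BC), with the sample SD
  (n−1).  Population-SD users can pass `ddof=0`; the choice moves the
  threshold by <1% on 68 nodes.

Shortest paths, betweenness accumulation and local clustering are computed
by igraph's C implementations.  The suite pins them against hand-written
brute-force oracles (explicit neighbor-pair counting, BFS, exhaustive
shortest-path enumeration) on every labeled graph with ≤ 5 nodes and on
seeded random graphs up to 30 nodes, and cross-checks betweenness against
networkx.

## Null models and small-worldness

Random comparison networks preserve node count, edge count and the full
degree sequence via Maslov–Sneppen double-edge swaps (default 10·k
attempted swaps, rejection-sampled to avoid self-loops and multi-edges; a
rigid graph that admits no swap yields a warning and the unswapped
network).  An Erdős–Rényi G(n, m) option preserving only the edge count is
available.  γ = Cp/Cp_rand and λ = Lp/Lp_rand use ensemble means over
`n_null` randomizations (default 100; the acceptance script uses 20 per
subject and the sanity tests 10 per run to stay inside their time budgets —
the ensemble mean's error enters both ratios only at O(1/√n_null)).
σ = γ/λ is stored as the exact quotient.

Real-vs-random comparisons use the classical pooled-variance two-sample
t-test across subjects (the paired alternative is a one-liner on the stored
tables), with Benjamini–Hochberg FDR correction across sparsities.

## Reliability

ICC(1,1) from one-way random-effects ANOVA:
MSB and MSW give ICC = (MSB − MSW)/(MSB + (k−1)·MSW), σ̂²_w = MSW,
σ̂²_b = (MSB − MSW)/k floored at zero; the raw (possibly negative) estimate
is reported alongside, since flooring hides small-sample behaviour.
Significance is F = MSB/MSW on (n−1, n(k−1)) df.  A two-way model is
deliberately not the default: the target estimand is the plain
between/total variance ratio with sessions exchangeable, and adding a
session effect changes the estimand.

Feature screening computes, per feature, the whole-brain mean per
subject/session and its ICC across subjects.  The selection default
p < 0.1 keeps seven of the nine candidates on the bundled reference screen
(dropping fold index and curvature index); both the p cutoff and an
optional ICC floor are configurable because the exclusion rule is a
convention, not a theorem — notably a feature can show moderate ICC with a
weak F-test when between-subject spread is small.

Nodal BC reliability is ambiguous (per node? per subject?); both
conventions are emitted: the node-mean of per-node ICCs (`icc`) and the
ICC of the node-mean BC (`icc_of_mean`).  Nodes with zero variance across
the cohort are skipped in the per-node average as uninformative.

## The synthetic cohort generator

The generator (`synthcohort`) emulates what the pipeline consumes — not
cortical geometry.  Its latent model, per cohort:

* orthonormal module signatures in feature space (entries O(1)), one per
  planted module (default 4 per hemisphere block), plus one global factor;
* each region loads on its module's signature with a **random sign** and
  jittered magnitude (default 1 ± 0.2), on the global factor with random
  sign and magnitude 0.6 ± 20%, plus idiosyncratic noise (SD 0.3);
* hub regions (default `lh_superiortemporal`) are near-pure global-factor
  regions (loading 1.2, residual noise 0.1).

Two design facts are load-bearing.  First, the per-feature z-score
subtracts the mean regional profile, so a factor loaded *uniformly* across
regions is annihilated before correlation; signed loadings survive
centering, and the absolute-value step converts the resulting
anti-correlations into edges — which is precisely the construction's
stated reason for using |r|.  Second, a hub built from module signatures
alone cannot beat within-module correlations (its cosine to any module is
bounded by 1/√n_modules); routing hub similarity through a dedicated
global factor gives it moderate-strength connections into every module,
which after thresholding makes it the bridge that shortest paths cross —
reliably the top-BC node.

Test–retest structure: subject effects (SD `between_sd`, default 0.5) and
session effects (SD `within_sd`, default 0.125) are i.i.d. Gaussian
perturbations of the same latent matrix, so both channels propagate
identically through any downstream statistic.  For smooth statistics
(whole-brain feature means) the expected ICC is the variance ratio
b²/(b²+w²) — the generator's `expected_icc`.  For *thresholded-network*
metrics the empirical ICC instead tracks the amplitude ratio b/(b+w):
a fixed-k edge set responds to perturbations through rank flips whose
count scales with the noise SD, not its square (measured Cp ICC saturates
near 0.65 for a 4:1 variance ratio across noise scales).  The defaults
are therefore stated in amplitude terms: 0.5 : 0.125 gives feature ICCs
≈ 0.94 and network-metric ICCs ≈ 0.8, the regime of a well-behaved
test–retest imaging cohort, and "session noise tuned to a 4:1 ratio"
means a 4:1 amplitude ratio throughout this package.

Native-scale mapping: vertex count, surface area and volume are log-normal
across regions (structural latent scaled by 0.5 in the exponent) with a
small (0.15) exponent coupling for the subject/session channel, keeping
the exp nonlinearity's distortion of variance ratios below ~0.01 ICC even
at large noise; the remaining features are affine with plausible
locations/scales (thickness ≈ 2.5 ± 0.25 mm, Gaussian curvature
≈ 0.025 mm⁻²).  Integer features are rounded.  What the generator does
*not* emulate: spatial autocorrelation on the cortical sheet, hemispheric
asymmetries, age/sex effects, scanner drift, or FreeSurfer segmentation
failure modes — so passing tests demonstrate the pipeline's statistical
correctness, not robustness to real-world imaging artifacts.

## Problem sizes and budgets

Defaults mirror a 55-subject, two-session cohort.  The test suite runs the
full 21-point sweep where the contract demands it and coarse 5-point grids
where only statistical behaviour is under test; planted-hub recovery uses
20 generator seeds at 55 subjects (single session), and the acceptance
script uses 20 nulls per subject and 5 recovery seeds.  These sizes are the
package's own choice of a desk-scale experiment; all of them rerun in about
a minute each.

## Known limitations

* Only the Desikan–Killiany atlas ships with the package; other atlases
  require a user-supplied `AtlasDefinition` and coordinate table.
* Bundled region centroids are hand-approximated MNI positions intended
  for viewer export, not for spatial statistics.
* Weighted and partial-correlation networks are out of scope.
* The ICC model assumes exchangeable sessions (no practice/ordering
  effects) and homogeneous within-subject variance.
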