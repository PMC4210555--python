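# Methods

## Model

The association model is the compressed mixed linear model

y = Xβ + Zu + e,  u ~ N(0, G), G = 2K σ²ₐ,  e ~ N(0, I σ²ₑ),

with y the phenotype (n individuals), X the fixed-effect design
(intercept plus optional structure covariates plus, during scanning, one
marker), Z the n×s incidence matrix assigning individuals to groups, and
K the s×s group kinship.  The factor 2 in G is implemented literally;
the likelihood only depends on the product λ·2K (λ = σ²ₐ/σ²ₑ), so the
factor affects how σ²ₐ is reported, not the fit.

Three model parameters beyond the variance components are optimized:

- **g**, the hierarchical clustering algorithm used to group individuals
  — UPGMA (average), UPGMC (centroid), COM (complete), FLE
  (Lance–Williams flexible-beta), WPGMA (McQuitty), WPGMC (median), SIN
  (single), WAR (Ward);
- **s**, the number of groups, parameterized as the compression level
  n/s (average individuals per group);
- **φ**, the operator collapsing the multiset of individual kinships
  between two groups into a single group-kinship value: average, median
  or maximum.

The endpoints recover the classical models exactly: at s = n the group
model is the standard individual MLM for every (g, φ); at s = 1 the
group effect is confounded with the intercept and marker tests equal
ordinary (GLM) regression tests.

## Individual kinship

Kinship is estimated from biallelic dosages by the Loiselle moment
estimator: with individual allele frequency p_hl = dosage/2 and panel
mean p̄_l,

k̃_ht = [ Σ_l (p_hl − p̄_l)(p_tl − p̄_l) + Σ_l p̄_l(1−p̄_l)/(n−1) ] / Σ_l p̄_l(1−p̄_l).

Both alleles of a biallelic locus contribute identical terms, so the
factor of two cancels in the ratio.  The (n−1) term is the small-sample
bias correction; negative estimates are retained because truncation
would distort the median/maximum group operators.  The ratio form (sum
of numerators over sum of denominators) weights loci implicitly by their
heterozygosity; per-locus weighting variants exist in the literature but
are not provided.  Missing genotypes are mean-imputed for kinship only;
association tests instead drop the individuals missing at the tested
marker.

## Compression

Individuals are clustered on the distance d = k_max − k̃ (shift-invariant
and strictly monotone in kinship; the transform is a package choice, as
is running the Euclidean-assuming linkages UPGMC/WPGMC/WAR on these
distances — inversions produced by the centroid methods are tolerated
because trees are cut by merge order, not height).  Seven linkages are
delegated to scipy.cluster.hierarchy; flexible-beta uses the
Lance–Williams recurrence d(k, i∪j) = α d(k,i) + α d(k,j) + β d(i,j)
with β = −0.25 (the customary default) and α = (1−β)/2, emitting a
scipy-format linkage matrix.  Tie-breaks take the first minimal pair in
a fixed scan order, so all trees are deterministic.

Cutting at s undoes the last s−1 merges (union-find over the merge
list).  Group kinship applies φ to all |i|·|j| cross pairs for i ≠ j and
to the within-group upper triangle *including self-kinships* on the
diagonal — including them keeps φ defined for singleton groups and makes
the s = n case reduce exactly to individual kinship.  The median and
maximum operators can break positive semidefiniteness; when the minimum
eigenvalue of the group matrix falls below −1e−8, the smallest diagonal
ridge ε ∈ {1e−6·2^k} restoring it is added and recorded
(`GroupModel.psd_ridge`).

## REML

The −2 restricted log-likelihood is profiled in λ through one symmetric
eigendecomposition.  With Q an orthonormal basis of the orthogonal
complement of col(X), A = Qᵀ(2ZKZᵀ)Q = W diag(ξ) Wᵀ and η = WᵀQᵀy:

−2LL(λ) = (n−q)(log 2π + 1) + log|XᵀX| + (n−q)·log( Ση²ᵢ/(1+λξᵢ) / (n−q) ) + Σ log(1+λξᵢ),

identical to the dense form log|V| + log|XᵀV⁻¹X| + yᵀPy at the profiled
σ²ₑ, at O(n−q) per λ after the decomposition.  λ is maximized on a
100-point log grid over [1e−9, 1e9] followed by bounded scalar
refinement (absolute tolerance 1e−9 in log₁₀λ, i.e. ~1e−8 relative in
λ); boundary hits simply return the boundary.  Eigenvalues of A below
zero (possible at the −1e−8 ridge tolerance) are clipped to zero.
BLUE and group BLUPs are recovered by one dense GLS solve at λ̂.

Under a null trait the REML estimate of λ follows the usual boundary
mixture — roughly half the replicates at exactly zero, the rest small
positive values — which is what the unit tests assert.

## Marker tests (P3D)

Variance components are estimated once on the marker-free model and held
fixed for every marker ("population parameters previously determined").
Each marker enters X as a fixed allele-dosage effect and is tested by a
Wald F-test under GLS with covariance V(λ̂): the data are whitened by
the Cholesky factor of V(λ̂) once and all complete markers are tested in
a single vectorized pass.  df1 = 1; df2 = n − rank([X | marker]), the
plain residual degrees of freedom (the choice of denominator df is
genuinely open; this one makes printed p-values reproducible).  Markers
collinear with X (monomorphic in the analyzed individuals) are flagged
untestable with p = 1 and excluded from q-value computation
(Benjamini–Hochberg via statsmodels).  Exact per-marker REML exists in
the test suite as an oracle; on synthetic panels its p-values rank-
correlate with P3D above 0.99.

## Optimization

`optimize_compression` evaluates every (linkage, φ) profile over the
level grid {1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 14, 16} mapped to
s = round(n/level), always augmented with the two endpoints s = 1 and
s = n, and returns the configuration with minimal −2LL.  Ties prefer the
larger compression level (downstream scan cost grows steeply with group
count), then the listed linkage order, then φ in the order
average < median < maximum.  The search is exhaustive (≤ 24 × 15 REML
fits), with one merge tree per linkage cut at all levels and one
spectral workspace shared across all fits.

## Power protocol

For each method (GLM = s 1; MLM = s n; CMLM = UPGMA+average optimized
over s; ECMLM = full 24-combination search):

1. fit the method's configuration and variance components on the
   observed (unspiked) phenotype;
2. scan all markers on the unspiked phenotype; the empirical threshold
   is the bottom α-quantile (default 5%, lower type-1 quantile) of these
   null p-values, so the null detection rate is ⌊αm⌋/m by construction;
3. for each marker j in turn, add a QTN effect y′ = y + d·sd_y·x_j
   (d in phenotypic-SD units, x the dosage), rescan marker j, and count
   a detection if p_j ≤ threshold.  Power is the detected fraction.

Variance components are *not* re-fitted per spiked phenotype: the spike
protocol inherits P3D.  This makes every spiked rescan a rank-one update
of cached whitened cross-products (Gram matrix of residualized markers),
so a full power curve costs one model fit plus O(m²) arithmetic.

Power-vs-FDR curves scan all m markers under each of the m spiked
phenotypes: at cutoff t, power is the fraction of spiked markers
detected and FDR is (detections of non-spiked markers)/(all
detections), pooled over replicates, the spiked marker itself excluded
from the false-positive count.  Raw FDR(t) need not be monotone;
`power_at_fdr` therefore reports the sup of power over cutoffs with
FDR ≤ q (standard step-function convention).

The variance explained by a QTN is π = 1/(1 + 1/(p(1−p)d²)), the
population R² of a locus whose two allele classes (frequency p) differ
by d phenotypic SDs — i.e. a {0,1}-coded (inbred or collapsed) locus.
For a heterozygous {0,1,2} dosage the explained variance has an extra
factor 2p(1−p) → 2·p(1−p); π is reported as the descriptive effect-size
label, matching its use for inbred panels.

## Synthetic panels

`simulate_panel` emulates the two confounders the method targets,
independently tunable:

- **structure**: Balding–Nichols subpopulation allele frequencies,
  p_sub ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral
  p ~ U(0.1, 0.9); F = Fst defaults to 0.1 (moderate differentiation,
  typical of the panels this model family is used on);
- **relatedness**: full-sib families gene-dropped from two unrelated
  founders per family, so pedigree kinship is 0.25 between sibs, 0.5 on
  the diagonal, 0 elsewhere.

The benchmark configuration is 2 subpopulations × 10 families × 5 sibs
(n = 100) with m = 500 markers.  Phenotypes are y = polygenic + noise
with polygenic covariance 2·K_pedigree·σ²ₐ, σ²ₐ = h²/mean(diag 2K) and
σ²ₑ = 1 − h² on the expected-variance scale, so λ = h²/(1−h²) exactly
(h² = 0.5 → λ = 1, used for parameter-recovery checks).  All draws come
from named substreams of one seed: adding markers never perturbs the
phenotype.

What the generator does **not** emulate: linkage disequilibrium beyond
family co-segregation, assortative mating, selection, genotyping error,
and phenotype missingness patterns.  Passing tests therefore demonstrate
correctness of the estimators and the internal consistency of the
method's claims (fit dominance, endpoint equivalence, calibration) on
idealized architecture — not field performance on any particular real
dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run at n = 100–200 and m = 200–2000,
sizes at which every dense oracle (O(n³) REML evaluations, brute-force
group kinship, per-marker lstsq scans) is exact and fast; the library
paths themselves scale to panels in the thousands.  Key tolerances:
kinship symmetry 1e−12; spectral vs dense REML 1e−8; PSD tolerance
−1e−8 with geometric ridge search from 1e−6; endpoint equivalences 1e−6
(s = n) and 1e−8 (s = 1); Monte-Carlo power comparisons ±0.03.

## Known limitations

- The same markers estimate kinship and are tested (no
  leave-one-chromosome-out correction).
- Only the three stated group-kinship operators; the minimum operator is
  deliberately absent.
- Single-trait, single-locus tests; no dominance terms.
- The FLE tie-break order is deterministic but need not match other
  implementations of flexible-beta clustering when distances tie.
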