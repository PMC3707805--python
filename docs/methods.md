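# Methods

This note documents the statistical procedures the package implements, the
conventions chosen where the field (or the underlying methods literature)
leaves them open, and what the synthetic data do and do not show.

## Data model

Genotypes are diploid biallelic autosomal SNP calls coded 0/1/2 as copies of
the alternate allele, with a distinct missing sentinel (never 0). Positions
are 1-based bp; coordinates are decimal degrees (WGS84 assumed). For PLINK
PED/MAP text — which carries no reference/alternate designation — the
in-file minor allele is taken as the alternate, ties broken
lexicographically, and a monomorphic site codes the unobserved (minor)
allele, so all dosages there are 0.

## Quality control

Stages run in a fixed order: individual screen → missingness → exact HWE →
LD pruning.

* **Tukey IBS screen.** Within each subpopulation of ≥ 3 individuals, all
  pairwise identity-by-state (IBS) distances form the pool whose quartiles
  set the fences. An individual whose *median* distance to the others
  exceeds Q3 + 1.5·IQR is an outlier (the median is a robust summary of
  "large distances to the rest"; mean and minimum are reasonable
  alternatives). A pair below Q1 − 1.5·IQR is related; the member with the
  higher missingness is dropped (ties: lexicographically larger id).
  Because the fences are quantiles of the current pool, rerunning the
  screen after exclusions can flag new extremes — roughly 0.7% of pairs per
  tail on homogeneous data. The marker filters, by contrast, are idempotent
  at fixed individuals, and `run_qc(tukey=False)` exposes exactly that.
* **Missingness.** A SNP is removed iff its missing rate strictly exceeds
  10% in at least one subpopulation.
* **HWE.** The conditional exact test (enumeration of heterozygote counts
  given the allele counts), per SNP per subpopulation, Bonferroni-corrected
  across SNPs × subpopulations at α = 0.05. Monomorphic samples have p = 1.
* **LD pruning.** Greedy left-to-right scan in map order; a SNP is kept iff
  |Kendall τ-B| < 0.5 against every kept SNP within 500 kb on the same
  chromosome. τ-B comes from the 3×3 genotype contingency table with tie
  correction; pairs with a missing call are dropped.

## Relationship matrices

* **IBS distance**: one minus the mean shared-allele fraction over jointly
  typed SNPs; sharing between dosages g, h is the allele-count overlap
  2 − |g − h|, with the het–het pair sharing both alleles.
* **Squared distance / covariance**: d²(i,j) is the mean squared dosage
  difference over jointly typed SNPs; the covariance is its double-centring
  c = −J d² J / 2, which on complete data equals the centred genotype Gram
  matrix over the SNP count (a tested identity).
* **IBD sharing** (Gusev-style normalization): chromosomes are cut into
  elementary intervals at all segment endpoints; interval weight
  F(s) = l_s/π_s where π_s counts the *pairs* covering the interval
  (reading "individuals sharing the segment" as sharing pairs keeps F
  consistent with the pairwise W); W_tot = ΣF; W_ij is the pair's covered
  weight over W_tot, and 1 − W_ij is the distance. Lengths are bp (a cM map
  is not assumed). W_tot = 0 yields all-zero W rather than an error.

## Ordination

Classical MDS eigendecomposes −½·J·D²·J. When negative eigenvalues are
present and correction is requested, the Cailliez additive constant — the
smallest c making D + c (off-diagonal) Euclidean, computed from the 2n×2n
companion eigenproblem — is added first; the constant and the corrected
spectrum are reported, and axis variance fractions refer to the positive
part of the corrected spectrum. The implementation reproduces R's
`cmdscale(add = TRUE)` constant to 1e-12 on a reference fixture.

Procrustes comparison is the symmetric form (both configurations centred
and scaled to unit sum of squares, reflections allowed); r = √(1 − m²), and
the permutation p permutes rows of the second configuration:
p = (1 + #{r_perm ≥ r_obs})/(B + 1). Site-level comparisons use per-site
means of individual coordinates against (longitude, latitude) pairs without
projection. Gaussian-mixture clustering of ordination coordinates fits all
combinations of k and four covariance parameterizations and selects by BIC.

## Differentiation

Weir–Cockerham (1984) variance components a, b, c per SNP; θ̂ = a/(a+b+c).
Combined Fst across SNPs is the ratio of sums (invariant to SNP order and
duplication). Per-SNP estimates keep their sign — needed to report the
fraction of SNPs with θ ≤ 0 — while the pairwise matrix clamps negatives to
zero. Pairwise combined Fst is restricted to subpopulations with ≥ 10
cleaned individuals (inclusive floor; on the shipped site table this keeps
exactly 46 subpopulations), configurable.

AMOVA is distance-based on squared Euclidean dosage distances (missing
calls mean-imputed per SNP), partitioned among groups / among
subpopulations within groups / within subpopulations, with variance
components from the standard expected-mean-square coefficients; negative
components are reported (flagged), not clamped. The among-group p shuffles
whole subpopulations among groups, preserving group sizes; its resolution
is limited by the number of distinct site-to-group assignments.

## Spatial statistics

Geodesic distances are great circles on a sphere of radius 6371.0088 km.
Individual-level geographic matrices inherit site coordinates (within-site
pairs at distance 0).

The autocorrelogram bins pairs into 24 distance classes — equal-count by
default, so no class is empty; equal-width is available — with the first
class closed at zero. Per class, r_h = (Σ pairs-in-class c_ij)/(Σ
incident-individual c_ii). The null permutes individuals' site labels
(preserving per-site sizes); per-class p-values are two-sided. The combined
P uses Fisher's statistic T = −2Σ log p_h, but its null distribution is
taken from the same permutation ensemble — each permutation's per-class
p-values are its ranks within the ensemble — so the combined p is itself a
valid permutation p despite the dependence between classes (plain Fisher
combination would not calibrate).

The Mantel test correlates upper triangles with a one-sided (≥)
permutation p. The bearing correlogram evaluates, on a 1° grid over
[0, 180), the Mantel correlation between the genetic matrix and
d_ij·cos²(α_ij − θ) with α_ij the initial great-circle bearing (the
Falsetti–Sokal cos² convention); the profile is 180°-periodic and its
argmax orients the cline. Bearings are degrees clockwise from geographic
north. Note that the profile of an exactly isotropic matrix is *not* flat
at finite n — configuration noise gives spreads of ~0.1–0.3 at 54 sites —
but it stays far below the spread of a genuine gradient.

## Gradient scan

The per-SNP geographic model is dosage ~ Binomial(2, logistic(a·x + b))
over standardized (east, north) individual coordinates, fitted by IRLS
vectorised across SNPs; the gradient score is ‖a‖, invariant to allele
relabelling. Fits reaching |coefficient| > 20 (separation) are flagged
non-converged and excluded from the scan. Individuals are placed at the
coordinates maximizing their joint binomial likelihood under the fitted
surfaces (BFGS from the centroid). Placement of the *same* individuals the
fits were trained on inherits fitting noise and correlates spuriously with
geography even under a null model (r ≈ 0.2 at 36 sites × 28 individuals);
null behaviour should be judged out-of-sample.

Local Moran's I over scores Z with binary window weights (|Δpos| ≤ 50 kb,
same chromosome): I_i = [n_i/((n_i−1)·S²)]·(Z_i−Z̄)·Σ_j w_ij (Z_j−Z̄),
where n_i is the in-window marker count (including i) and Z̄, S² are
genome-wide moments (window-local moments available behind a switch). The
one-sided p reshuffles scores over all markers; the default 10,000
permutations make the 5e-4 reporting threshold attainable (1,000 would
floor p at ~1e-3).

## Synthetic data

The generator emulates a grid-like national sampling design: by default the
54 shipped Dutch sites, ~300 km extent, 10–65 individuals per site in the
shipped table (constant per-site n in simulations), 2·10³–10⁵ SNPs. Site
allele frequencies are deterministic — p_s(site) = logistic(α_s + β_s·u)
with u the site's projection on the cline bearing scaled to a unit extent —
so individual binomial sampling is the only noise and parameter-recovery
targets are sharp. `cline_strength` (default 0.1, recovery runs use 0.2) is
the maximum frequency range a background SNP can span across the extent;
this puts mean pairwise combined Fst in the 10⁻³–10⁻⁴ band typical of
within-country structure. Outliers are frequency-shift outliers (δ = 0.15
on half the SNPs); related pairs copy 60% of one member's genotypes; steep
SNPs draw an unambiguous tilt (|t| ∈ [0.5, 1]) amplified 5×, since a
"steep" SNP with a near-zero underlying slope would be a contradiction.
The generator produces no LD beyond planted duplicates and no coalescent
realism: passing recovery tests shows estimator correctness under the
stated model, not robustness to real LD, ascertainment or admixture.

## Range-expansion simulator

A 4-neighbour deme lattice with deterministic demography and stochastic
genetics. Growth is logistic (N ← N + rN(1 − N/K)); emigration sends
m·N/4 to each open neighbour (migrants toward closed cells stay home, so
the front speed is uniform across the lattice and colonization order is
monotone in distance); demes below 0.5 individuals go extinct. Two waves:
a hunter-gatherer wave (K = 500, r = 0.5, m = 0.4) and a later farming
wave (K = 5000, r = 0.8, m = 0.8) that absorbs resident demes on contact
(full merger, γ = 1; the dual-layer mechanics of richer simulators are
deliberately collapsed, and γ is exposed). An optional discontinuity sets
K = 0 on a cell set between generations 70 and 35 before present; the
cells are then recolonized by neighbours. Genetics replays the recorded
deme sizes: each SNP starts uniform(0.05, 0.95) in the origin deme, each
generation every occupied cell resamples its frequency binomially (2N
gametes) from the migration-weighted parental pool, newly colonized cells
inherit the migrant pool, and there is no mutation. Sampled SNPs are
ascertained at pooled-sample MAF ≥ 0.03. Generation time (25 years) is
metadata only.

The default comparison scenario runs a 40×40 toy world: both waves start
in the southeast corner (Palaeolithic 220 and Neolithic 150 generations
before present — sized so the first front, which advances ≈ 0.3 cells per
generation under these parameters, colonizes the whole world before the
discontinuity window), 39 sample cells in a northwestern block of which 28
form the coastal strip emptied by the discontinuity, 1,000 SNPs, 20
diploid samples per cell. Scenario comparison computes, per scenario, the
pairwise combined Fst matrix (negatives clamped), its 2-D MDS and a
Procrustes test against the cell coordinates, plus the cross-scenario
Procrustes of the two MDS configurations and an OLS fit between the two
bearing profiles with (adjusted) R². The deterministic demography is
shared across genetic replicates.

## Problem sizes and tolerances

Oracle-equivalence checks run at 1e-12 (exact arithmetic oracles) or 1e-9
(float oracles). Calibration suites use 200 replicates with 99
permutations each — the discrete p-grid then puts P(p ≤ 0.05) exactly at
0.05 — and accept rejection counts within the central binomial band
[3, 18]. Recovery suites use 54 sites × 10 individuals × 2,000 SNPs over
20 seeds (bearing) or 10 seeds (gradient scan); the scenario comparison
uses 10 genetic replicates over the shared demographies. These sizes are
the package's own defaults for its validation suite; all are parameters.

## Known limitations

* The Tukey screen's false-flag rate is inherent to quantile fences; on
  very small subpopulations (< 3) it is skipped entirely.
* The SPA-style gradient model is a simplified binomial-logistic surface,
  not the published SPA likelihood; it preserves the scanned quantity
  (gradient steepness) with a fully specified estimator.
* The simulator's forward-drift genetics replaces backward-coalescent
  machinery; summary behaviour (founder-effect gradients, Fst scale)
  matches at toy scale but per-locus genealogies are not modelled, and
  there is no recombination map or mutation.
* Geographic coordinates enter ordination comparisons unprojected;
  over a ~300 km extent the distortion is negligible, and a planar
  projection hook exists for larger extents.
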