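# Methods

## Dosage coding and panel handling

The canonical marker coding is the allele dosage {0, 1, 2} with −1 as the
missing sentinel. The {0, 0.5, 1} score matrix used by the IBS computation
is always derived on the fly as dosage/2 and never stored, so the two
codings cannot drift apart. Filters run in a fixed order — genotype
missing-rate, genotype heterozygosity, marker missing-rate, monomorphic,
minor-allele frequency — with each rule counted against the panel state at
the time it runs and allele frequencies recomputed on the surviving
genotypes before the marker rules. MAF is computed on observed calls only,
before imputation, so imputation cannot manufacture polymorphism. The
built-in imputer fills missing calls from per-marker allele frequencies
(rounded expected dosage, or a Bernoulli draw under the inbred convention);
it is intentionally simple — no phasing or LD-aware imputation.

## Relationship matrices

* **IBS** — A = (GG′ + G₂G₂′)/K with G the 0/0.5/1 score matrix and
  G₂ = 1 − G. The formula is implemented literally; a consequence, asserted
  in the tests as a documented quirk, is that a heterozygous genotype has
  self-IBS 0.5. For the fully homozygous lines the package targets, the
  diagonal is exactly 1.
* **Additive (realized) relationship** — the centered, frequency-scaled
  marker cross-product with p_k taken from the panel actually passed in
  (the calibration panel, before any split). Monomorphic markers are a hard
  error because of the zero denominator.
* **Gaussian kernel** — squared Euclidean distance on dosages, divided by
  its off-diagonal mean so that the mean scaled distance is 1, then
  A* = exp(−D/θ). The scaling makes the θ grid 0.05–5 transferable across
  panels of different size and marker count; without it the useful
  bandwidth range would move with K.
* **LOCO kinships** — one additive matrix per chromosome from the
  complement marker set, used as the polygenic covariance in the GWAS.
* **QTL-masked kinship** — additive relationship after removing markers
  within ±20 cM (map units) of any QTL, windows taken as a union of closed
  intervals.

A diagonal ridge of 1e-8 is applied transiently wherever an inverse or a
Cholesky factor is needed (CD, REML, BLUP); stored matrices are never
perturbed.

## Population structure

IBS-PCA double-centers the IBS matrix (the classical-scaling construction,
so squared score distances reproduce the IBS-induced distances) and reports
eigenvalues, percent variance and √λ-scaled scores. The number of
subpopulations is the Tracy–Widom count of significant components plus one.
For the significance count the spectrum is recomputed from markers
standardized to unit variance: the unstandardized IBS spectrum has
heterogeneous per-marker variances that push the leading null eigenvalue
past the moment-corrected Marchenko–Pastur edge, and in simulation the test
then rejects a true single population ~25 % of the time at α = 0.05;
with the standardized spectrum the null rate is at its nominal level. The
sequential test uses the TW1 critical values 0.9793 (α = 0.05, the
default) and 2.0234 (α = 0.01) and an effective marker number estimated
from the remaining eigenvalues at each step.

Subpopulation assignment is k-means on the first k−1 score dimensions with
25 restarts under a fixed seed — a deterministic, dependency-free stand-in
for model-based qualitative assignment, sufficient because the groups only
serve as strata and as the within-group evaluation units. Fst follows the
Weir–Cockerham variance-components estimator in its diploid form
(ratio-of-sums over loci); observed heterozygosity is essentially zero for
inbred lines, and a haploid variant is available behind a flag.

## Training-set construction

* **Radius search** — candidate radii are midpoints of the sorted unique
  pairwise-distance grid; the expected U yield at a radius is the median
  over 20 probe passes; a bisection returns the largest radius whose
  expected yield reaches the target. Yield is non-increasing in r, which
  the bisection exploits.
* **U / SU** — the iterative sample-and-discard pass. A pass that
  overshoots the target is trimmed uniformly at random (methods are
  compared at fixed sizes); a pass that falls short — the radius is
  calibrated on the median — is redrawn, and after persistent shortfall the
  radius steps down the distance grid. The training-set invariant (all
  pairwise distances ≥ r; within strata for SU) holds for every draw.
* **CD** — the criterion is evaluated in calibration-set coordinates:
  contrasts e_i − 1/n over all n calibration genotypes, Z′MZ built from the
  training indicator with the intercept projector, λ = (1 − h²)/h² from a
  user-supplied heritability (default 0.85). The exchange accepts only
  strict improvements, runs at most 800 proposals (which reaches a stable
  objective at these panel sizes) and stops early when improvement stalls.
  At λ = 0 the criterion collapses to 1 exactly; it is non-increasing in λ.
* **S** — log-proportional allocation rounded by largest remainder. The
  literal formula can request more genotypes than a group holds (it does
  for group sizes 220/129 at target 300); the sampling path therefore caps
  allocations at the group size and redistributes the overflow by remainder
  order, while the uncapped arithmetic remains available for inspection.
  Singleton strata receive zero under the literal formula (log 1 = 0).

Splits are characterized by nearest-entry distances (min over training of
1 − IBS per validation genotype) and by per-subpopulation training-set
counts expressed as percent deviation from the random-sampling baseline.

## Mixed-model engine

One engine serves the CD criterion, the GWAS and all four prediction
models: y = Xβ + Σ u_k + e with u_k ~ N(0, σ²_k K_k). The single-kernel
case is solved exactly — spectral decomposition of the record-space kernel,
then a bounded one-dimensional search of the profiled restricted likelihood
over log₁₀ of the variance ratio (coarse 49-point grid bracket, then Brent
to 1e-10 on the exponent). Multi-kernel models use EM-REML (at most 500
iterations, relative change < 1e-6), with non-convergence flagged rather
than raised, and aliased kernel sets (e.g. a kernel numerically equal to
the identity, or duplicated kernels) flagged degenerate. BLUPs come from
the variance form ĝ = Σ σ²_k K_k Z′V⁻¹(y − Xβ̂) with GLS fixed effects;
the tests pin this against an independent Henderson mixed-model-equation
solve to 1e-6.

The GWAS tests each marker as a fixed effect with the LOCO kinship as
polygenic covariance. Variance components are estimated once per chromosome
under the null model and reused for every marker on that chromosome
(the population-parameters-previously-determined shortcut), and the marker
effect is tested by a 1-df Wald chi-square — deterministic, and calibrated
in simulation (type-I error 0.03–0.07 at nominal 0.05 with structure
present). Markers monomorphic within the training set get missing p-values.
The genome-wide 0.01 threshold divides the nominal level by the Li–Ji
effective number of tests, computed per chromosome from the marker
correlation eigenvalues via f(λ) = I(λ ≥ 1) + (λ − ⌊λ⌋) and summed;
eigenvalues are rounded to 8 decimals first so that exactly duplicated
markers land on the integer discontinuity. Detected markers are collapsed
greedily per chromosome within a ±20 cM peak window; a forced-QTL list can
be merged in for traits whose major loci are known a priori.

Per-QTL random effects (QTL and QGBLUP models) are rank-one kernels
x_q x_q′ on centered dosages, each with its own variance, fitted jointly by
EM-REML. QGBLUP with an empty QTL set reduces to GBLUP exactly. The RKHS
bandwidth is chosen by 5-fold cross-validation inside the training set,
ties to the smallest θ.

## Evaluation

Predictive ability is the Pearson correlation between observed and
predicted phenotypes over the validation set; undefined correlations
(fewer than 3 pairs, zero variance) are recorded missing, never zero.
Realization-level abilities are averaged on Fisher's z scale and
back-transformed; the standard error is reported on the z scale (stated in
output headers). Within-subpopulation ability repeats the computation per
group, with groups under 3 validation members flagged missing. The
experiment driver seeds realization i as base + i so any cell can be rerun
in isolation, detects QTL per realization on the training set only, and
logs cell failures without aborting the grid.

## Synthetic data

The generator emulates a structured panel of inbred breeding material with
a hierarchical Balding–Nichols model:

* **Subpopulations** — sizes (95, 55, 50, 30, 20) by default, mirroring the
  skewed group sizes of real diversity panels; per-subpopulation
  divergences F_s are spread geometrically (ratio 2 by default) around the
  target Fst (0.25) with larger groups more diverse, the pattern real
  panels show.
* **Within subpopulations** — a mixture of unique accessions (45 % by
  default, each with private drift F = 0.3 away from its subpopulation) and
  sibling families (geometric sizes, mean 6, minimum 2) whose members draw
  from a shared near-fixed family frequency (F = 0.65). This produces the
  heavy-tailed nearest-neighbour distance spectrum of real panels:
  near-duplicate sibs around distance 0.1 and isolated lines with no close
  relative. An earlier, flat design with exchangeable lines inside equal
  subpopulations turned out to be degenerate — distances concentrate, no
  genotype is better covered than any other, and differences between
  training-set construction methods reduce to validation-composition
  artifacts no real panel shows.
* **Traits** — a few large QTL (5 by default, drawn among markers with
  MAF ≥ 0.1) carrying a fixed share (0.2) of the genetic variance, a
  polygenic background over all other markers, and noise set from the
  realized genetic variance to hit the target heritability (0.7). The
  between-subpopulation share of the genetic variance is a ratio with only
  S − 1 degrees of freedom and otherwise swings from near 0 to near 1
  between draws; the generator pins it at its neutral expectation (the
  target Fst) so that trait draws stay in the regime of interest —
  predictive ability not reducible to population structure, which is the
  regime the benchmark methods were designed for and the one the package's
  directional claims are made in.
* **Plain Balding–Nichols mode** — singleton_frac = 1, singleton_fst = 0,
  diversity_spread = 1 gives the textbook model with exchangeable lines,
  used wherever a known true Fst must be recovered (the Weir–Cockerham
  check) or a clean null is needed (Tracy–Widom calibration).

What the generator does **not** emulate: linkage disequilibrium beyond
structure-induced correlation (markers are conditionally independent given
the hierarchy), heterozygosity (off by default; a rate option exists to
exercise the 0.5-score path), multi-environment phenotypes (inputs are
adjusted means), and epistasis. Passing tests therefore demonstrate the
machinery and the structure-driven phenomena, not LD-driven fine-mapping
resolution; GWAS hits identify the causal marker itself rather than a
linked proxy.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen so the full pipeline (panel generation → structure → five sampling
methods → REML/BLUP → aggregation) completes in minutes on one CPU:
panels of 100–500 lines with 400–5000 markers, 2000-marker study panels of
250 lines for the method comparison, 100 realizations per comparison
(10 independent panels × 10 sampling draws, so generator-level variability
is averaged over rather than conditioned on), 200 traits for heritability
recovery, 50 null and 100 power scans for GWAS calibration. Marker counts
are an order of magnitude below SNP-chip densities; because markers are
exchangeable in the generator, this scales the kinship-estimation noise
but not the structure of the problem.

## Known limitations

* The CD exchange is a greedy hill-climb from a random start; it matches
  exhaustive search on small instances (tested) but is not guaranteed
  globally optimal at scale, matching the behaviour of the published
  exchange algorithm.
* EM-REML converges slowly near variance-component boundaries; components
  are floored at 1e-12 and non-convergence is flagged in the result rather
  than raised.
* The GWAS reuses null-model variance components per chromosome; per-marker
  REML refits would be slower and change p-values slightly in small
  samples.
* Fst heterogeneity across loci is summarized by the ratio-of-sums
  estimator only; no per-locus confidence intervals.
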