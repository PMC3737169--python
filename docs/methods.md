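# Methods

## The mapping design and its encoding

The package models a two-panel multiparent RIL resource.  Each panel (pA,
pB) descends from eight inbred founders — seven unique lines plus one line,
AB8, shared between panels — that recombined freely for many generations
before lines were inbred.  A RIL genome is therefore a mosaic of founder
haplotypes, represented here as half-open bp segments per chromosome arm.
Genotype is never observed directly; what the analysis consumes is the
posterior a haplotype-inference HMM would produce: at every 10-kb grid
position, probabilities over the 36 founder-genotype states (8 homozygous +
28 unordered heterozygous pairs), collapsed to 8 *additive* probabilities by
giving heterozygous states half weight on each founder.  Rows sum to one by
construction and every downstream operation preserves that.

Phenotypes attach to F1 crosses between pA males and pB females from
matched subpopulations (pA1×pB2 or pA2×pB1 only).  The phenotype is a
count (offspring per vial after drug exposure), triplicated per cross, and
mapping is done on the 3-replicate cross means.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions the rest of the package is validated under.

* **Genetic map** — constant 2 cM/Mb (a typical euchromatic fly rate); the
  desk-scale genome is two 5-Mb arms, i.e. a 1000-point 10-kb grid.
  Arms named `2L`/`2R` belong to one chromosome and are concatenated on the
  cM scale for smoothing and peak finding, so a peak may span a centromere.
* **Founder SNPs** — positions uniform over arms; per SNP a target minor
  allele frequency is drawn (default uniform on (0.05, 0.5]) and the number
  of carrier founders is the nearest achievable count out of 8 (at least 1).
  The pA and pB panels share SNP positions and the AB8 haplotype.  Optional
  rare TE insertions carry 1–2 founders.
* **Mosaics** — breakpoints are a Poisson process on the cM scale with
  intensity `breakpoint_rate` per Morgan (default 50 = 2 × an effective 25
  generations of recombination; the realized map expansion of the real
  breeding design is not pinned down, so the rate is an explicit parameter
  rather than baked-in theory).  Founder identity per segment is uniform,
  so 1/8 of nominal breakpoints join identical founders and are merged; a
  configurable fraction of segments (default 1%) stays residually
  heterozygous.
* **HMM emulation** — at 1 − `soft_fraction` of grid points the true state
  receives probability ≥ `certainty` (default 0.95), the remainder spread
  over two random alternative states; the remaining 5% of points are
  "soft" (true-state mass 0.35–0.95), mimicking uncertainty near
  breakpoints.  `certainty=1` returns the one-hot truth.
* **Phenotypes** — replicate value = μ + β_s·S + Σ QTL contributions +
  block effect + cross-level polygenic deviate + vial deviate, rounded and
  floored at 0 (fecundity is a count).  Defaults: μ = 60 offspring,
  subpopulation shift 5, genetic variance V_g = 100 and vial variance
  V_e = 160 in count² units, chosen so broad-sense heritability is ≈ 0.38
  per vial and ≈ 0.65 for 3-replicate cross means — the regime the
  analysis is designed for.  Eight weekly blocks include four aberrant
  ones (one near-total knockdown at −45, three near condo saturation at
  +60…65) that the QC filter is supposed to remove.  QTL effect vectors
  are mean-centred per parent and rescaled so each QTL's realized
  between-cross variance equals its target share of V_g
  (`calibrate_qtl_effects`); the leftover genetic variance becomes the
  polygenic component.
* **Seeding** — one global seed fans out to per-component child seeds
  through a stable blake2s hash, so each stage is independently
  reproducible across processes.

What the generator does *not* emulate: linkage disequilibrium structure of
real founder haplotypes (SNP alleles are drawn independently per site),
segregation distortion, genotyping-driven correlation between nearby RILs,
condo (cage) spatial effects, and any pharmacokinetics of the drug.  A
passing suite therefore shows the estimators are correct under the stated
generative model, not that real data meet that model.

## Quality control and heritability

Whole blocks whose across-cross mean fecundity falls outside a window
(default 30–110 offspring; the upper bound sits just below vial saturation)
are dropped, and crosses whose mock-treatment control produced fewer than
50 offspring (strictly fewer) are removed.  Both filters are idempotent.

Heritability uses the one-way ANOVA (moment) estimator: with r replicates,
V_g = (MS_between − MS_within)/r (unbalanced data use the standard
coefficient n₀), V_e = MS_within, negative V_g truncated to zero;
H²_ind = V_g/(V_g+V_e) and H²_means = V_g/(V_g+V_e/r).  A REML fit would
differ only in finite-sample detail; the acceptance surface is parameter
recovery, not numerical identity with any particular mixed-model
implementation.

## Genome scan

Design matrix per position: intercept, subpopulation indicator, 7 paternal
and 7 maternal founder probabilities with the shared founder AB8 omitted as
reference (a full 8-column parameterization is singular against the
intercept because rows sum to one).  Genotype columns whose sum over
crosses is < 4.8 are dropped (strictly-less; dropping depends only on the
genotype structure, so a matrix of phenotype columns — the permutation
null, coverage simulations — shares each position's design and is fitted in
one pass).  The statistic is the partial F of the full model against
intercept+subpopulation; −log10(p) is capped at 300 on numerically perfect
fits, and rank deficiency falls back to the pseudo-inverse with df from the
numerical rank.

Smoothing is degree-1 tricube loess across genetic distance, span 0.005 (a
fraction of the points per chromosome; windows are widened to a minimum of
3 points with a warning).  Degree 1 with zero robustness iterations is a
fixed choice.  Because a local-linear fit is linear in y, the smoother is
precomputed as an n×n matrix per chromosome and applied to hundreds of
permutation profiles as a single matrix product.

## Permutation thresholds as peaks per scan

Permutations shuffle the cross-mean vector while genotypes and the
subpopulation covariate stay attached to the crosses (preserving the
genotype–subpopulation dependence under the null; whether residuals should
be permuted instead is undetermined, and this choice is ours).  Each
permutation gets the full scan plus smoothing.  Peaks are points that are
the (leftmost-tie) maximum of a centred window of `span` grid points
(default 50, incremented to odd) and at least `snr` × MAD×1.4826 of the
per-chromosome series (default S/N 1); this guarantees peak separation
greater than span/2.  Boundary points are only eligible when explicitly
requested.  For a grid of candidate thresholds the expected peaks per scan
is the mean genome-wide count over permutations; `threshold_for_rate`
inverts the (non-increasing) curve with linear interpolation.  Held-out
calibration — train the 0.5-rate threshold on one batch, count peaks on an
independent batch — is the module's central property.

## Intervals, founder effects, variance explained

Interval estimation refits the region *without* term dropping so df is
constant, and converts F to LOD = (n/2)·log10(RSS₀/RSS₁) (identical, to
machine precision, to (n/2)·log10(1+df₁F/df₂)).  The 2-LOD support
interval extends contiguously from the peak while LOD ≥ max−2.  The Bayes
credible interval normalizes 10^LOD over the region and takes discrete
equal-tail quantiles: the first grid point whose cumulative mass reaches
(1−coverage)/2 and 1−(1−coverage)/2 respectively (on an exactly flat
100-point curve this yields 96 points rather than a "central 95" — the
discrete convention includes the crossing point on both sides).  In
simulations at the default conditions the 95% BCI covers the true position
in ≈ 92–94% of replicates — slightly anticonservative, as expected when
10^LOD is treated as a posterior with 14 estimated genotype parameters —
while the 2-LOD interval is usually *narrower* than the BCI (it
under-covers in many-founder crosses; that is why the BCI is the calibrated
choice).

Founder effects are estimated per parental population by regressing
subpopulation-corrected residuals on that population's 8 probability
columns without intercept; founders with summed mass ≤ 4.8 are excluded
(reported missing, not zero) and means with fewer than 5 confident
(probability > 0.95) assignments are suppressed.

A QTL's share of cross-mean heritability is its incremental R² over the
subpopulation model divided by H²_means, capped at 1.  The incremental R²
is df-adjusted by default (1 − (RSS₁/(n−p₁))/(RSS₀/(n−p₀))): with 14
genotype regressors at n = 300 the raw statistic overstates each QTL's
share by roughly df₁/n of the residual variance (~5 percentage points),
which compounds across QTL; the raw form remains available via
`adjusted=False`.

## Multiple linked QTL

The two-position scan fits all pairs of positions in a window (default
14 cM) at least 2 cM apart — closer pairs are statistically
unidentifiable under RIL linkage — with both positions' founder regressors
jointly (term dropping applied), against the subpopulation-only null.  The
pair grid is thinned from the 10-kb grid to a configurable ~0.2 cM step
(0.5 cM in the test suite); all-pairs at 10 kb would be wasteful.  The
residual re-scan regresses out the best single-QTL model (subpopulation +
genotype at the peak) and re-scans the genome on the residuals with the
grand mean only, subpopulation being already absorbed.

## Marker association

A biallelic marker's RIL-level minor-allele probability is the dot product
of the additive probabilities at the nearest grid point (no interpolation)
with the founder allele vector (1 = minor allele across the combined
panel; ties at MAF 0.5 broken alphabetically); cross dosage is
paternal + maternal probability, on [0, 2].  The test model is
y = μ + β_s·S + β_m·M with a two-sided t test on β_m; variance explained is
incremental R² over subpopulation divided by H²_means.  Region-level
multiple testing is Bonferroni at 0.05/m.  The random-SNP null samples
markers (without replacement) from a QTL's widest confidence interval; a
candidate set fails when any random SNP explains more than every
candidate.  TE insertions are tested identically through presence/absence
dosages; because a single-founder TE's dosage is a linear combination of
the founder probabilities, its R² is bounded by the haplotype model's at
the same position.  No kinship correction is applied beyond the
subpopulation covariate.

Enrichment of candidate genes under mapped peaks assumes candidates fall
uniformly over the fine-mappable genome: the count under intervals
totalling L Mb out of M Mb is Poisson(n·L/M), and the p-value for seeing
two or more is 1 − P(Poisson ≤ 1).  The observed FDR at a threshold is
expected false positives / observed peaks, capped at 1.

## Problem sizes and numerical choices

The validation suite runs at a deliberate desk scale: two 5-Mb arms
(1000 grid positions), 300 RILs per panel, 300 crosses, 100–200
permutations in tests and 1000 per calibration pair in the acceptance
script, 200–300 interval-coverage simulations.  Monte Carlo replicate
counts were sized from the estimators' sampling error (e.g. the summed
variance-explained mean uses 24 phenotype replicates because a single
replicate has ~9-percentage-point sd).  Tolerances used in tests: 1e−9 for
probability row sums, 1e−10 for algebraic identities (LOD/F, brute-force
normal equations), binomial/Poisson 95% bounds for calibration checks.
Degenerate inputs are defined rather than accidental: zero-variance
phenotypes give F = 0 and H² = 0 (with warnings), perfect fits cap at
−log10(p) = 300, flat LOD curves return the whole region, monomorphic
markers raise, and an all-dropped position is recorded as untestable
(missing p) rather than zero.

## Known limitations

Founder SNP alleles are exchangeable across sites, so real LD structure
and allele sharing by descent are absent; association power estimates on
synthetic markers transfer only qualitatively.  The HMM emulation's error
model is site-independent, whereas real inference errors cluster near
breakpoints.  The peak finder is a plain windowed maximum — deliberately
simple, since the referenced implementation's internals are not public —
and the expected-peaks convention, while interpretable, does not control
family-wise error.  Interval coverage is approximate (see above), and
effect sizes at detected peaks carry the usual winner's-curse inflation,
which the package does not debias.
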