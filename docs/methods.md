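# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind each stage, what the synthetic data do and do not
emulate, and the design decisions taken where more than one reasonable
construction existed.

## Coordinates, formats, missing data

Coordinates are 1-based inclusive everywhere except explicit BED export
(0-based half-open). VCF input is restricted to biallelic SNP records with
GT; multiallelic and indel records are skipped and counted, matching an
upstream pipeline filtered to biallelic SNPs at MAF ≥ 0.05. Missing
genotypes are a distinct sentinel and never conflated with dosage 0.

## Synthetic cohorts

A cohort is a set of diploids from several populations, each population
with an inverted-haplotype frequency `p_inverted`; a sample's two
chromosome-scale orientation labels are independent Bernoulli(p) draws, so
karyotypes are Hardy–Weinberg within populations. Default frequencies
(0.3, 0.5, 0.7, 0.95, 1.0 at 33–45°N, 20 samples per population) form a
latitudinal cline with the ancestral orientation frequent only in the
south, the pattern the analysis is designed to resolve. The inversion
occupies 5.6–19.2 Mb of a 30-Mb chromosome (a ~13.6-Mb interval, matching
the scale of the motivating system); per-site θ = 10⁻⁵ yields ~3,000 SNPs
per cohort, a RAD-seq-scale marker density.

Genealogies are Kingman coalescent trees simulated per non-recombining
block, with infinite-sites mutations dropped as Poisson(θ/2 × branch
length); time is in units of 2N generations, so E[S] = θ·a₁. Blocks are
independent (free recombination between blocks). Background variation uses
~20 contiguous sub-megabase blocks tiling the flanks.

The inversion region itself is simulated as multiple sub-blocks at the same
spatial scale, all sharing the single chromosome-wide class assignment but
with independent within-class genealogies; each sub-block is a clean
two-deme split (no migration) at divergence `t_div_ci` (default 4, in 2N
units). This reflects the biology of inversion polymorphism: recombination
is suppressed *between* orientation classes, while within a class the
region exchanges freely. The distinction matters: simulating the inversion
as one non-recombining genealogy also hands every deep *within*-class
branch a perfect-LD clique spanning the whole interval, and in a
non-negligible fraction of replicates that clique carries more mutations
than the between-class stems, making the detection stage lock onto a
within-class haplotype partition that no genotype-only statistic can
distinguish from the inversion. With sub-blocks, only the between-class
fixed differences stand in long-range LD, as in real data.

A cohort can also be generated with `inversion_present=False`, in which
case the whole chromosome is tiled by background-sized blocks and all truth
karyotypes are ancestral homozygotes; this is the negative control for
detection. Note that `t_div_ci = 0` is *not* that control: it still models
a (zero-divergence) class structure and is used for null-FST checks.

What the generator does not emulate: demographic history (growth,
migration, bottlenecks), selection, intra-block recombination gradients,
indels, genotyping error, and read-level artifacts. Passing tests therefore
demonstrate correctness of the estimators and the detection logic under the
stated model, not robustness to real-data artifacts such as reference bias
or batch-structured missingness.

## LD scan and diagnostic loci

r² is the squared Pearson correlation of dosage vectors (composite LD),
pairwise-complete over jointly non-missing samples, with pairs under 10
joint samples skipped. Composite LD is phase-free and deterministic;
an EM haplotype-frequency r² would target the same quantity for unphased
diploids but adds an iterative fit without benefit here. Defaults:
MAF ≥ 0.05, r² ≥ 0.8.

Detection links sites in qualifying pairs separated by ≥ 1 Mb. The distance
gate is essential at this scale: short-range LD is ubiquitous and carries
no inversion signal. Components of the resulting graph with ≥ 50 supporting
pairs qualify; components whose positional spans overlap are merged, since
an inversion's site graph fragments into several near-clique components
(fixed differences, near-fixed sites) that are evidence of one
recombination-suppressed block. The region is the positional extent of the
largest merged block; absence of any qualifying block is a valid result.
Detected boundaries are identifiable only up to the bracket between the
outermost strongly linked SNP and the true breakpoint; with ~3,000 markers
on 30 Mb the median boundary error against the generating interval is a few
tens of kb (a few SNP spacings).

Diagnostic-locus selection clusters samples with 1-D k-means (k = 3,
deterministic: centers initialized at the score of the samples ranked at
quantiles 0.05/0.5/0.95) on a per-sample score: the mean standardized
dosage over a candidate site set, each site's sign oriented by its loading
on the set's leading principal axis (either allele may tag the inversion,
so the unsigned mean cancels between opposite-polarity sites). Each merged
LD component supplies one candidate axis (its own leading axis); the axis
whose clusters render the most loci concordant at ≥ 95% wins. Global
principal axes are not usable as candidates because two axes of comparable
variance make the SVD return an arbitrary rotation of their plane.

Orientation of the "inverted" label defaults to the globally commoner
haplotype class (matching the predominance of the derived orientation in
the motivating system) and is recorded in the region's metadata; passing
`ancestral_reference=<sample>` anchors the ancestral cluster instead, the
analogue of fixing orientation by cross-species synteny. The selection
procedure as a whole is a reconstruction — the criteria by which the
original diagnostic marker panels were chosen are not published beyond
"indicative of karyotype" — and is documented as such.

## Karyotype calls and frequencies

Calls threshold the mean oriented dosage: ancestral homozygote < 0.5,
heterozygote in [0.75, 1.25], inverted homozygote > 1.5; scores in the dead
zones, or samples missing more than half their loci, are UNRESOLVED and
excluded from frequency denominators. The dead zones guard mosaic or
error-ridden samples; all thresholds are configurable. Percentages are
reported to one decimal. The single-locus estimator is allele counting
(2·hom + het)/2n with a Wilson 95% interval.

## Population-genetic estimators

The SFS uses alt-allele counts over non-missing chromosomes; sites observed
in < 80% of chromosomes are dropped and the rest are down-projected to the
smallest complete count by the exact hypergeometric expectation
(projection is explicit here because the upstream tool that usually handles
missingness is out of scope). π = Σ i(n−i)ξᵢ / C(n,2); θ_W = S/a₁; D uses
the Tajima (1989) constants, with S the (possibly fractional) spectrum
total so that D·denominator ≡ π − θ_W holds identically. D is undefined
(NaN) for S = 0 or n < 4. Windows are half-open, start at 1 + k·step, and
only fully contained windows are emitted (edge handling is unspecified in
the source analyses; this convention is unambiguous). Both raw and per-bp
window values are available.

F_ST is the two-population Weir & Cockerham (1984) θ̂ from the a/b/c
variance components (allele frequencies, sample sizes, observed
heterozygote frequencies); monomorphic sites are skipped and negative
estimates are reported as computed, without clamping. Welch's t uses
Satterthwaite df; a degenerate comparison (both variances zero) returns
t = 0, p = 1 when means agree and is an error otherwise. One-way ANOVA
returns F = 0, p = 1 at zero total variance.

A calibration caveat verified against an independent coalescent engine
(msprime/tskit): the exact Tajima's D has a slightly negative neutral mean
(≈ −0.08 to −0.12 for n between 10 and 200 at moderate θ) because the
variance normalization is approximate. Calibration checks that require a
zero mean are therefore run on the numerator π − θ_W, which is exactly
mean-zero under neutrality; the D-based check is retained for transparency
and documented as failing for this reason, not as an implementation defect.
Similarly, Fisher's exact test only attains its nominal type-I rate where
the 2×2 margins are large enough that discreteness is negligible; the
calibration uses margins of 2,000 per group.

## Dating

The dating stage replaces a Bayesian relaxed-clock MCMC with a strict-clock
distance estimator: per family, rate = d(trout, Atlantic salmon)/(2×27.3 MY)
— the mean of the two trout-haplotype-to-salmon JC69 distances — and
TMRCA = d(anc, inv)/(2·rate). The 27.3-MY *Salmo*–*Oncorhynchus*
calibration is the offset of the fossil/molecular prior used in the
motivating analysis and is configurable. Estimates are exactly linear in
the calibration age. The scientific quantity (calibrated inversion TMRCA,
summarized by median and mean over ortholog families) is preserved and
testable by parameter recovery; posterior intervals are not produced.
Which trout copy anchors the calibration distance is not specified in the
source analyses; the mean of both is used.

Topology validation roots on the esociform outgroup pair and tests clade
membership as bipartitions of the NJ tree (scikit-bio's NJ on our JC69
matrices): both homeolog clades monophyletic, salmon+trout sisters within
each, inversion haplotypes sisters, and not identical (invariant families
carry no signal and are removed, mirroring the source filtering). JC69
distances require ≥ 100 comparable sites and error at p ≥ 0.75
(saturation). The simulated species tree fixes the remaining node ages
(root 112 MY, esociform split 85 MY, duplication 90 MY, salmonid TMRCA
51.8 MY, whitefish–grayling 40 MY) at published calibration offsets or
round interpolations between them; only `t_inv` and the substitution rate
(default 10⁻³ subs/site/MY, a typical teleost nuclear rate) matter to the
recovery tests.

## Enrichment

Two-sided Fisher p-values use the point-probability convention (sum of
hypergeometric probabilities of tables no more likely than observed) —
the dominant convention, stated here because the source names the test but
not the sidedness. The term universe is all annotated genes; each term is
tested once; no ontology-graph propagation is performed (there is no
indication the original analysis propagated parent terms, and the
annotation tool's internals are not reproducible). BH adjustment is
step-up, order-preserving, capped at 1. Significant terms require q ≤ α
and odds ratio > 1 (enrichment, not depletion).

## Pipeline

`run_pipeline` executes simulate → ldscan → karyotype → popgen → date →
enrich from one JSON config (defaults: r² ≥ 0.8, MAF ≥ 0.05, 1-Mb distance
gate, 50-kb/10-kb windows, S ≥ 100 filter, α = 0.05), writes every stage
output plus the resolved config, and closes with a manifest of sha256
checksums; identical config and seed reproduce identical checksums. A
failing stage aborts the run with the stage named and leaves a `.partial`
marker.

## Problem sizes

Defaults were chosen so a full simulated analysis runs in seconds and the
complete recovery suites in minutes on one CPU: cohorts of 100 diploids and
~3,000 SNPs, 20-cohort detection/karyotyping batteries, 200 ortholog
families of 10 kb, 10⁴-replicate type-I calibrations, and 100-replicate
enrichment batteries. These sizes hold the Monte-Carlo error of every
asserted quantity comfortably below its test tolerance.

## Known limitations

Single inversion per chromosome (largest LD block only); no phasing, no
split-read or assembly evidence; karyotype thresholds are heuristic and
data-scale dependent; the strict clock ignores rate variation across
lineages and sites, so per-family ages are noisier than a relaxed-clock
posterior; enrichment ignores the ontology graph and gene length biases;
the simulators' idealizations listed above bound what green tests imply
about field data.
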