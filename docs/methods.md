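# Methods

## Study design emulated

The package targets a reciprocal-cross experiment between two subspecies
lineages (called A and B throughout): two families, each crossed in both
directions, give four colonies; each colony contributes eight workers (two
dominant reproductives, two subordinate reproductives, two sterile nurses,
two sterile foragers) and each worker a head and an abdomen RNA library —
64 libraries, 32 per reproductive status. Cross direction `initial` means
an A mother and B father; `reciprocal` the reverse. A maternal bias that is
genuinely parent-of-origin looks the same in both directions; a bias that
tracks the lineage flips between them. This is the identifying contrast of
the whole analysis and is preserved exactly in the simulator and the
classifier.

## Variant preparation

Parental variants pass three gates (phred quality ≥ 20, depth ≥ 5, ≥ 2
alternate-allele observations). Queen (diploid) calls are further
restricted to homozygous-alternate sites: a heterozygous queen transmits
either allele, so her het sites cannot anchor a read to a parent. Sites
called in both parents are subtracted on (contig, position) — even with
different alternate alleles both alternate genomes deviate from the
reference there, so the site cannot discriminate. The surviving
parent-unique SNPs are substituted into the reference to build the two
alternate genomes. Indels are rejected with an explicit error; multi-allelic
records are split per alternate allele before filtering; unsorted input is
sorted internally with a warning rather than refused. Coordinates are
1-based inclusive at every VCF-facing interface and 0-based half-open for
BED and in genome strings; conversion lives only in the I/O layer.

## Read assignment

"Zero-mismatch alignment" is realized as exact substring matching of each
read against both parental genomes. This reproduces the decisive property
of the original strategy — a read covering an informative SNP matches
exactly one parental genome — without an external spliced aligner, at the
scale this package operates (simulated or desk-scale data). A read matching
both genomes covers no informative SNP and is discarded; a read matching at
more than one locus is discarded as ambiguous (the analogue of a
non-uniquely mapped read); a read matching neither genome (sequencing
error, foreign sequence) is discarded. Every retained assignment records
the informative SNPs it covers.

Counting is per (gene, SNP, library) with each covered SNP incremented once
per read. At the gene level a read spanning several informative SNPs of one
gene is counted **once** by default (deduplication), because repeating the
same read at every SNP would inflate the effective sample size of the
per-gene model; the per-SNP table keeps the per-SNP view. Both aggregation
modes are available (`gene_level_counts(..., dedup=...)`) since the choice
cannot be pinned down from the original description.

The zero-maternal filter removes, from **all** libraries, any SNP with zero
maternal reads in at least one library. Its purpose is to catch
mis-called queen genotypes (a queen wrongly called homozygous-alternate
whose missing allele matches the drone would inflate paternal counts). A
SNP simply absent from a library's rows counts as zero there, so the
function takes the library universe explicitly. In the count-level
simulation there is no miscall mechanism, so the pipeline applies this
filter only in the sequence-level (reads) mode by default; it can be forced
on either way. The filter is deliberately asymmetric and conservative: at
low per-SNP depth it preferentially erodes strongly paternally biased
genes (the maternal count is the one that must never be zero), a property
worth keeping in mind when interpreting paternal-side results at shallow
depth.

The analyzed gene universe requires ≥ 2 surviving SNPs per gene and
nonzero allelic data in every family × direction cell. Zero paternal
totals are set to 1 before model fitting to avoid complete separation;
the substitution count is logged and recorded on the returned table.

## Per-gene inference

Each gene's maternal/paternal totals across libraries are fit with a
binomial GLM (logit link). Factors — cross direction, family, and
reproductive status in the joint mode — use sum-to-zero (effects) coding,
so the intercept β₀ is the grand-mean logit of the maternal proportion and
testing β₀ = 0 asks whether the allelic ratio deviates from 0.5 averaged
over conditions (treatment coding would instead test the ratio at the
reference levels). Overdispersion is absorbed quasi-likelihood style: the
Pearson statistic over residual degrees of freedom scales the squared
standard errors, and the intercept test uses a *t* reference on the
residual df — standard practice at these sample sizes. The dispersion
estimate is used as-is, with no floor at 1. The fit itself is delegated to
a standard IRLS implementation (statsmodels); an independently written
textbook IRLS in the test suite verifies coefficients to 1e-8 and p-values
to 1e-6.

Degenerate cases: a gene fit perfectly by the model (zero Pearson
residuals) has a zero standard error; its intercept p-value is defined as
1 when β₀ = 0 (exactly balanced counts) and 0 otherwise. Genes with fewer
than two positive-total libraries, saturated designs (df ≤ 0) or
non-converged fits are excluded with a log entry.

The default analysis fits reproductive and sterile workers separately
(covariates: direction, family), mirroring per-status gene lists; a joint
fit with status as a third factor is available (`status="both"`). BH
adjustment is applied within each analysis across its fitted genes.

## Conservative proportion and classification

Per-library maternal proportions are averaged hierarchically: tissue means
within (colony, worker type), then worker-type means, then colony means,
then the grand mean across the four colonies with equal weight. This
discards depth information on purpose — no deep library or well-sampled
colony can dominate — and is the quantity the 0.6/0.4 gate is applied to.

Classification of a significant gene (q < 0.05):

* **MATERNAL** — grand mean > 0.6 and all four colony means > 0.5;
* **PATERNAL** — grand mean < 0.4 and all four colony means < 0.5;
* **LINEAGE_A / LINEAGE_B** — after recoding each direction's proportion
  to the lineage-A allele (identity in the A-mother direction, 1 − p in
  the other), both directions above 0.6 (A-biased) or below 0.4
  (B-biased); the parent gates are checked first, and the two families of
  labels are mutually exclusive by construction;
* **BIALLELIC** otherwise.

The per-colony same-side requirement operationalizes "the same direction
in both crosses and both replicates"; its exact original form is not
specified, and this is the natural conservative reading. Note that
lineage-biased genes are balanced on average, so their intercept test is
usually not significant — the classifier guards against leakage into the
parent classes rather than guaranteeing lineage sensitivity, matching how
such genes behave in this design.

## Synthetic data generator

Count level: per gene and library, total allelic depth is
negative-binomial with mean `mean_allelic_depth × size factor × DE
multiplier` and gamma-Poisson dispersion `nb_dispersion`; the maternal
count is beta-binomial with intraclass correlation `overdispersion_rho`
(the beta-binomial is the concrete overdispersion mechanism chosen — the
analysis only assumes *some* overdispersion exists, which quasibinomial
fitting absorbs). Counts are split across the gene's SNPs by a multinomial
draw for totals and a multivariate-hypergeometric draw for the maternal
share, so maternal + paternal equals depth at every SNP exactly. Gene
classes: MATERNAL/PATERNAL genes hold `maternal_prop_imprinted` (default
0.9) and its complement in every library; LINEAGE genes hold it for the
favored lineage, so the maternal proportion flips between directions;
BIALLELIC genes sit at 0.5. Worker type and tissue have no effect on the
allelic proportion by default (the bias is modeled as conserved across
phenotypes); an optional logit shift for reproductive workers
(`status_effect_on_prop`) supports testing the status factor. Age and
weight are standard-normal nuisance covariates consumed only by the DE
stage.

Defaults and their reasoning: `snps_per_gene_mean = 13` (the observed
median SNP count per gene in this design); `mean_allelic_depth = 1000`
reads/gene/library for the pipeline default, reflecting deep bulk
libraries (tens of millions of reads) of which a small fraction covers a
given gene's informative SNPs — recovery and calibration experiments in
the tests use 50 to probe the shallow-depth regime; `nb_mean = 50` for the
whole-gene expression matrix (a typical mid-expression gene; no value is
prescribed by the design); `nb_dispersion = 0.3`, `overdispersion_rho =
0.05`, library size factors lognormal with σ = 0.15 — typical bulk-RNA
magnitudes; `frac_de = 0.1` of genes differentially expressed at
|log2FC| = 2.

Sequence level: one colony (one queen, one drone) per call, since read
assignment is a per-colony operation; the count-level generator covers the
full four-colony design. A random reference contig carries non-overlapping
gene models; parent-unique SNPs are placed inside genes (queen's as
diploid hom-alt calls, drone's as haploid calls); reads are error-free
fixed-length substrings of the haplotype dictated by each gene's class,
with per-read parent-of-origin truth. Error-free is the right default
because the matching is exact — errors would only discard reads, which an
optional uniform error rate can demonstrate. When
`plant_filter_violations` is on, spurious calls (low quality, low depth,
het queen, shared-by-both-parents) are added to the VCFs; they are not in
the haplotypes, so read assignment is exact **only if** the filter cascade
removes them — making the end-to-end audit sensitive to every filter.

Randomness: one root seed; every purpose (design, truth, each gene, size
factors, sequences) draws from a deterministic substream
(`SeedSequence(seed, spawn_key=...)`), so identical configs produce
byte-identical artifacts regardless of call order.

What the generator does not emulate: spliced transcripts and introns,
mapping biases, PCR duplicates, lane effects, allele-specific mapping
artifacts, real linkage between SNPs of a gene beyond the shared
beta-binomial draw, and genotype miscalls at count level. Passing
recovery tests therefore demonstrate the statistical machinery and the
filter logic, not robustness to alignment artifacts in real libraries.

## Differential expression

A deliberately plain NB stage, not a re-implementation of the shrinkage
estimator used in the original analyses (whose exact gene counts are
consequently out of scope here): median-of-ratios size factors over
all-positive genes, per-gene method-of-moments dispersion on normalized
counts, an NB log-linear GLM with log size-factor offset and covariates
(family, age, weight, direction), a Wald test on the status coefficient,
BH across tested genes, and a total-count ≥ 10 prefilter. Tissues are
analyzed separately (stratification rather than a tissue factor), matching
how the per-tissue gene lists are defined.

## Set statistics

Hypergeometric enrichment uses the survival function of the hypergeometric
distribution (upper tail at k − 1), BH across terms, with the background
scheme: candidate genes against all observed genes; maternal/paternal
subsets against all parent-of-origin genes; up-regulated genes against all
DE genes of the same tissue. The 2 × 2 independence test uses the Yates
continuity correction (|ad − bc| reduced by N/2, floored at 0) — the
convention under which nearly proportional label-count tables give exactly
χ² = 0, p = 1, and the default of the statistical environment this
analysis style comes from. Reciprocal-best-hit orthologs take tabular
similarity-search output (query, subject, evalue, score); per query the
best hit is lowest e-value, ties broken by highest score then lexicographic
subject id, gated at e ≤ 1e-3; pairs are kept only when the two directions
designate each other. Running the similarity search itself is out of
scope — any outfmt-6-style table works.

## Problem sizes

Unit tests run on 10–200-gene experiments; the headline suites use
500-gene experiments over 20 seeds (recovery), 2 × 1000 null genes
(calibration) and a 10-gene sequence-level colony with ~2400 reads
(assignment audit). The acceptance script uses 5 recovery seeds. These
sizes give Monte-Carlo error comfortably inside the asserted margins while
keeping the whole suite fast.

## Known limitations

* Exact-substring read assignment ignores splicing; real data need a
  spliced aligner upstream, after which the counting and inference stages
  apply unchanged to the resulting per-SNP counts.
* The intercept test has little power for lineage-biased genes by design;
  lineage calls require the bias to reach significance through
  overdispersion, so lineage sensitivity is low (leakage into parent
  classes, the harmful direction, is what the tests bound).
* The DE stage has no dispersion shrinkage and is underpowered at very
  small fold changes relative to shrinkage-based tools.
* The zero-maternal filter erodes strongly paternally biased genes at
  shallow per-SNP depth (see above).
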