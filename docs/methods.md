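# Methods

## The experimental design being modelled

`platmut` analyses clone-based mutagenesis assays: an ancestral single-cell
clone is expanded, descendant clones are treated (or mock-treated) and
re-cloned, and all genomes are sequenced at moderate depth (~30x). Any
mutation present in exactly one descendant and absent from the ancestor and
all sibling clones must have arisen during the treatment window, so
per-clone unique-mutation counts are direct measurements of mutagenicity.
Two mutational processes are modelled: a **direct** process producing the
substitution classes expected at platinum intrastrand purine-purine
crosslinks — C>A with a 3′ C neighbour (GpG adducts read on the pyrimidine
strand, NCC>NAC) and T>A with a 5′ C (ApG adducts, CTN>CAN) — and an
**indirect** broad background process resembling spontaneous mutagenesis.

## Synthetic data generator

The generator is the forward model of the pipeline and defines the study
conditions used in the test suite.

* **Reference genome.** I.i.d. bases at a stationary GC content
  (default 0.42, vertebrate-like), single contig by default. Genes are
  non-overlapping intervals with random strands, placed with
  exponential gaps so they cover ≈ `gene_fraction` (default 0.3) of the
  genome; lengths uniform in 500–3000 bp. Real genomes have isochores,
  repeats and overlapping transcripts; none of that is emulated, so tests
  passing here say nothing about mapping artefacts or repeat-driven errors.
* **Mutation planting.** Per clone, the SNV count is
  Poisson(group mean); each SNV is assigned to direct vs background by the
  group's mixture weight, a channel is drawn from that process's 96-channel
  probabilities, and a genomic site is drawn uniformly among positions
  matching the channel's pyrimidine-centred trinucleotide context on either
  strand. Direct-process mutations falling inside genes are placed on the
  transcribed strand with probability `ts_bias` (default 0.65; 0.5 = no
  bias). 1-bp indels are planted at `indel_rate` per SNV (defaults 0.08
  direct / 0.05 background, deletion:insertion odds 2:1); the indel model
  is a stand-in — no empirical indel-generating process is claimed. Sites
  are unique across clones, matching the unique-mutation design.
* **Default burdens.** The default three-arm design uses
  human-lymphoblastoid-scale burdens per clone over the treatment window:
  mock 169, cisplatin 701 (excess 532), carboplatin 493 (excess 324), with
  direct-mixture weights 0.5 / 0.4 and mixture weight 0 for mock. The
  direct signature puts 60% of its mass on the four NCC>NAC channels and
  40% on the four CTN>CAN channels and zero elsewhere; the background is
  near-uniform with mildly elevated C>T and T>C. These are the package's
  chosen emulation of the assay conditions; the exact direct/background
  split per drug is not an observable of the real experiment.
* **Counts.** Per sample and site, coverage ~ Poisson(30). The mutated
  clone of a het site draws supporting reads Binomial(coverage, 0.5)
  (heterozygous planting only; homozygous/subclonal fractions are left to
  the caller of the API). All other reads miscall with probability
  `seq_error_rate` (default 10⁻³, uniform over the three non-reference
  bases), and spurious indel support arises at the same rate. Clean
  "noise" sites (default 10x the planted count) exercise specificity
  without whole-genome scans. There is no read-level simulation: no
  mapping error, strand bias of errors, or base-quality structure.
* **Randomness.** One master seed feeds named sub-streams (`genome`,
  `planting`, `counts`, `nmf`), so every stage is independently
  reproducible and two runs with the same config are byte-identical.

## Variant calling

Candidate detection at a site requires exactly one sample with
alternate-allele frequency ≥ `min_vaf` and coverage ≥ `min_cov`, and every
other sample clean with reference-allele frequency ≥ `min_other_ref_freq`
and coverage ≥ `min_cov`. Defaults (0.2 / 0.93 / 7) were chosen on the
synthetic fixture to satisfy the false-positive calibration property at
30x; all three are exposed in the config. Sites with a zero-coverage
sample are skipped and logged. Shared variants fail the uniqueness test by
construction, which is what makes ancestral polymorphisms invisible to the
caller.

The score is the one-sided Fisher exact p-value comparing the mutated
sample's (alt, ref) counts with those of the non-mutated sample having the
lowest reference-allele frequency (the "noisiest clean" sample), reported
as −log₁₀ p and clamped at p = 10⁻³⁰⁰. Indels are scored identically on
(support, coverage − support). The threshold per mutation type is the
smallest observed score such that every control clone keeps at most 5
SNVs / 1 insertion / 1 deletion (inclusive ≥ comparison; the sweep visits
observed scores only, so calibration is reproducible without continuous
search). Note that at the default noise conditions (30x, error 10⁻³) the
candidate filters alone already reject essentially all noise sites, so
calibrated thresholds are typically 0; the calibration machinery matters
at higher error rates or lower coverage.

Coordinates are 0-based half-open internally and 1-based in TSV/VCF
output. Calls keep reference-strand alleles; pyrimidine normalization
happens only at spectrum time. Insertion calls cannot recover the inserted
base from count data, so their VCF ALT is written as anchor + `N`.

## Spectra and strand bias

The 96-channel order is frozen in `platmut.channels`: classes C>A, C>G,
C>T, T>A, T>C, T>G, each expanded by 5′ then 3′ flank alphabetically.
Doublet substitutions are adjacent same-sample SNV pairs, classified into
the canonical doublet classes with reverse-complement strand normalization;
runs of ≥ 3 consecutive SNVs are excluded and logged. Indels are bucketed
on two axes (length 1 / 2–4 / 5+; homopolymer run 0–1 / 2–4 / 5+) rather
than a full 83-class catalogue, which the underlying assay cannot populate
at desk scale. Strand bias uses an exact two-sided binomial test against
0.5 per substitution class — exact at small counts, where a Poisson
approximation would be loose. Rate normalization exposes `genome_gb`
explicitly because "per Gb" conventions (haploid reference vs diploid
genome) differ between studies; the worked example reproduces
169/(3.0 × 75 cycles) = 0.75 per Gb per cycle with the haploid-reference
convention.

## NMF decomposition

Generalized Kullback–Leibler divergence with the classical multiplicative
updates (the Brunet-style scheme standard in the signature field), not
Frobenius — appropriate for count data. Defaults: 50 random restarts,
max 2000 iterations, stop when the relative divergence decrease falls
below 10⁻⁸; a 10⁻¹² floor inside update denominators prevents division by
zero without adding pseudocounts to the data. The best restart by final
divergence wins; the divergence trace of a single run is non-increasing
(a property the tests assert). Signatures are column-normalized with the
scale folded into exposures, so exposures are in mutation-count units and
sum to ≈ each sample's total. For joint fits across genomes with different
triplet backgrounds, `fit_relative=True` factorizes column-normalized
spectra and rescales exposures by sample totals afterwards. `pick_rank`
reports divergence and restart-stability (mean matched cosine across
restart pairs) per candidate rank and deliberately selects nothing. k = 2
is the rank used throughout the replication workflow.

### Identifiability of the exposure split

With one broad component and one peaked component, exact two-component
factorizations form a one-parameter family: replacing the direct signature
D by (D + αB)/(1 + α) and adjusting exposures fits the data equally well
for any α up to the feasibility edge set by the cohort's highest-purity
sample (profiling the divergence along this ridge on synthetic data gives
a constant value to two decimals). The multiplicative-update fit lands
near that edge, so fitted background exposures are depressed by roughly
α × (direct burden), where α ≈ min over samples of
(background/direct) burden. Two practical consequences, both visible in
the tests: (1) recovering planted exposures accurately requires a cohort
with weight diversity including a high-direct-share arm that pins the
direct component — which is how the joint two-cell-line decomposition is
run in practice; (2) comparisons of fitted background exposures between
groups with very different direct burdens inherit a systematic transfer
and should be read qualitatively. The split-property test therefore uses
the realistic joint cohort (two similar drugs at three clones each,
decomposed together with mock arms and a peak-dominated high-dose arm at
five clones), under which background exposures are statistically
indistinguishable in ~83% of seeds while direct exposures always separate.

PCA mean-centres normalized spectra per channel and decomposes by SVD;
each axis's sign is fixed by making its largest-magnitude loading
positive. Cosine comparison against reference signature tables validates
the 96 channel labels and reports the first mismatch.

## Group statistics

Pooled-variance Student's t (two-sided) is the default, with Welch
available (`equal_var=False`); degenerate zero-variance inputs return
t = 0, p = 1 for equal means and p = 0 flagged by ±∞ otherwise. Excess
burdens are differences of group means against the matched mock group of
the same cell line. Relative mutagenicity is 100 × excess/reference-excess
with the unrounded value retained alongside the integer percent. No
multiple-testing correction is applied — raw pairwise p-values are
reported, as is conventional for these small-panel comparisons — and the
number of comparisons is implicit in the report. Dose trend is a
non-strict monotonicity flag over mock ≤ IC25 ≤ IC50 group means.

## Problem sizes

The demo pipeline uses a 3 Mb genome, three arms × 4 clones plus 3 control
clones, ~5500 planted mutations and ~60k count rows; it completes in well
under a minute on one CPU. The test suite's simulated cohorts use 100 kb –
1 Mb genomes chosen so each statistical property is tested at a sample
size where its expected effect exceeds three standard errors. The
acceptance script's cohorts match the corresponding tests.

## Known limitations

* Synthetic counts have no mapping or alignment artefacts, so the caller's
  measured specificity is an upper bound on real-data behaviour.
* Multi-allelic sites, subclonal mutations shared by clone subsets, and
  structural variants are out of scope, as in the unique-mutation design.
* The NMF exposure split carries the identifiability caveat above.
* The indel generator and 2-axis indel classes are deliberately simple;
  they support counting and dose-trend analyses, not indel-signature
  inference.
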