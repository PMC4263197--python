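# Methods

This note documents the models, rules and numerical choices behind
`imputemerge`, in the order data flows through the pipeline.

## Data model and formats

Genotype probabilities are per-marker triplets (P(AA), P(AB), P(BB))
relative to the marker's written allele order; the all-zero triplet
encodes a missing genotype, mirroring the `missing=0` convention of
probability-file tooling.  Triplets are stored and re-emitted exactly
as read — no renormalization on I/O — and written with three decimals
by default (configurable).  Metric columns live in [0, 1] with −1 as
the only sanctioned "undefined" sentinel, printed literally as `-1`.
Coordinates are 1-based and fully closed in files; segment intervals
are half-open internally so disjointness is checkable, and emitted
inclusive.

GEN files exist in two dialects for the first of the five leading
columns: stock imputation output puts a secondary snp_id there, some
merge tooling the chromosome.  Both are supported behind an explicit
`dialect` flag (default `impute2_5col`) because merged output must
interoperate with standard tools.

The PLINK text reader drops markers monomorphic in the file, with a
warning: a .ped exposes only the alleles it contains, so the second
allele of such markers is unrecoverable, and they carry no imputation
information (any MAF filter would remove them anyway).

## Build conversion

A precomputed 7-column table maps (old chromosome, position, label) to
new coordinates or marks the marker `unmapped`.  Application order:
drop indeterminate mappings, update names, update chromosomes, update
positions; the survivors are re-sorted by (chromosome, position).  Two
survivors landing on the same position with the same allele pair is an
error (a real collision), not a silent merge.  Chain-file parsing is
out of scope by design; the table is the interface.

## Strand harmonization

Study and reference alleles must sit on the same physical strand.  The
per-marker decision procedure, in order:

1. non-palindromic, allele sets equal → keep;
2. non-palindromic, equal after complementing (A↔T, C↔G) → flip;
3. palindromic (A/T, C/G): if both study and reference MAF are at or
   below `maf_ambiguity_bound` (default 0.4), compare minor alleles —
   equal → keep, complementary → flip;
4. otherwise arbitrate by LD: over up to `window` (default 100)
   nearest non-palindromic matched neighbors, compare the sign of the
   study-side dosage correlation with the reference-side correlation
   (orientations normalized so allele-order reversals do not fake a
   strand flip).  Neighbors are informative when |r| ≥ 0.2 in the
   reference; fewer than 3 informative neighbors → discard.  A strict
   majority of inverted signs → flip; of consistent signs → keep;
   a tie → discard;
5. incompatible allele sets → discard.

A flip relabels the alleles with their complements and leaves the
0/1 / dosage encoding untouched — the encoding's meaning follows the
relabeled alleles.  The 0.4 ambiguity bound and the |r| ≥ 0.2 /
3-neighbor rules are this package's concrete realization of the
"MAF and LD pattern" criteria, which are stated qualitatively in the
practice this implements; correlations are computed on dosages (the
choice between genotype- and haplotype-level LD being open, dosage
level works for both phased and unphased neighbors).  Optional input
QC before the strand check removes markers below 95% call rate or 5%
MAF, and can remove all palindromic markers outright (off by default;
palindromic removal changes little when LD arbitration is available).

## Segmentation and stitching

Two schemes:

* **Marker blocks** ("SNPlets"): cores of exactly `core_size`
  (default 30,000) consecutive markers, the last core smaller, with
  `buffer_size` (default 700) markers appended on each side, truncated
  at chromosome ends.  Buffer counts refer to study markers.
* **Base-pair windows**: `window` (default 6 Mb) cores starting at the
  first imputation target, with `buffer` (default 250 kb) flanks.
  A terminal remnant, any window overlapping the centromere interval
  (supplied as a 3-column table; no genome is built in), and any
  window without a study-typed (type-2) marker merge into the segment
  immediately upstream (a violating *first* window merges downstream,
  the only direction available).  "Approximately 6 Mb" is realized as
  exactly the configured window; remainders are handled by the
  terminal-merge rule.

Stitching drops every buffer-region row so each marker has results
from exactly one segment, records the originating segment per marker,
raises on a marker owned by two cores, and raises on a core marker
missing from its segment's output.

## The imputation engine

A deliberately simple, fully deterministic k-nearest-haplotype model
(the pipeline's pluggable stand-in for an HMM engine; any tool
emitting GEN + info files can replace it).  For each study haplotype
and untyped marker: take the nearest `flank` (default 50) typed
markers, rank reference haplotypes by Hamming agreement over that
window, keep the top `k` (default 5; ties to the lower reference
index), and set the allele-1 probability to the agreement-weighted
vote.  Genotype triplets are the product over the individual's two
haplotypes.  Typed markers pass through as probability-1 triplets
(type 2); segments with no typed marker are refused.  With the study's
own haplotypes in the panel and k = 1 the truth is reproduced exactly.

The per-marker **info score** is the ratio-of-variances certainty
metric: with expected dosage e_i = 2·P(AA) + P(AB) and posterior
dosage variance v_i,

  info = 1 − mean(v_i) / (2·θ·(1−θ)),  θ = mean(e_i)/2,

which is 1 for fully certain polymorphic markers and −1 (undefined)
for monomorphic or all-missing ones.  It is invariant under AA↔BB
relabeling.  `exp_freq_a1` is the expected frequency of the marker's
first written allele.

## Masked evaluation

`mask_markers` removes a seeded random fraction (or an explicit list)
of typed markers before imputation and keeps the originals as truth.
Two scores per masked marker: hard-call concordance (argmax triplet
when the max probability reaches `call_threshold`, default 0.9 — the
threshold is a package choice, exposed on the CLI) over samples with
non-missing truth and a callable imputed genotype; and allelic R², the
squared Pearson correlation between truth hard dosages and imputed
expected dosages, undefined for constant vectors or fewer than two
usable samples.  The signed correlation is emitted alongside for
diagnostics.  Summaries are equal-weight means per MAF bin (widths 0.1
and 0.01 both supported), with undefined values excluded.

Concordance is a misleading headline at low MAF: always predicting the
major homozygote already exceeds 90% concordance below 5% MAF, so the
real quality gradient should be read from info/R² by MAF bin.  The
dataset-level merge gate is mean masked concordance ≥ 0.80.

## Merging

Datasets are gated (n ≥ 100 samples, dense genome-wide platform,
masked concordance ≥ 0.80; reasons recorded), then markers are
cross-matched by (chromosome, position, unordered allele pair) — never
by label — and kept when the info score is strictly above 0.7 in every
eligible dataset.  Labels: plurality wins; plurality ties go to the
larger rs number, or the lexicographically larger label when neither
candidate is rs-style (a deterministic extension of the larger-rs
rule); a label attached to more than one position drops all positions
bearing it (reported, not fatal).  Rows are aligned to the first
eligible dataset's allele order; a reversed row swaps P(AA)↔P(BB) per
sample (the symmetric swap, assumed for the probability file since
only the info file's treatment is explicit in practice) and its
exp_freq_a1 enters the average as 1 − value.  Merged info rows: snp_id
`---`, type = numeric minimum, all other columns the equally weighted
mean with −1 inputs ignored (all −1 → −1).  Whether exp_freq_a1 should
stay anchor-relative or be forced to the minor allele is ambiguous in
the practice this follows; both are implemented behind
`minor_allele_orientation`, default minor-allele (fold the averaged
frequency above 0.5), decided by the averaged value itself.
Duplicated sample ids keep the copy from the higher-call-rate dataset;
missing call rates or exact ties go to the earlier dataset in plan
order with a warning.  Sample identity is exact id match; genotype-
based duplicate detection is out of scope.

## Quality control

Hard calls (argmax at threshold 0.9 — the threshold behind published
call-rate tables being unstated, this is a package default) drive
per-marker and per-sample call rates.  Tables report SNPs dropped and
remaining at thresholds {0.95, 0.98, 0.99}; the sample table applies
the 99% marker filter first and *reports* samples without removing
them.  The MAF spectrum (thresholds 0.05 … 0.0001) is computed after
the info > 0.7 and 99% call-rate filters from hard calls (a
dosage-based MAF is available behind a flag), excluding markers
without at least one copy of a minor allele.  Every summary satisfies
dropped + remaining = total exactly.

## Population structure

KING-robust between-family kinship is computed over markers
non-missing in both samples; duplicate pairs score ≈ 0.5,
parent-offspring ≈ 0.25.  Relative clusters are connected components
of the φ̂ > 0.125 graph; one representative is kept per cluster
(highest call rate, ties to the smallest id).  Relatives are removed
*before* pruning and PCA, matching the order of the protocol this
follows.  LD pruning keeps markers with MAF > 10% and greedily removes
the later member of any pair with dosage r² at or above the bound
within sliding 100-marker windows (step 5 — unstated in the source
protocol, chosen as a package default); an optional thinning cap
toward ~100k markers exists for full-genome inputs, off at desk scale.
PCA standardizes genotypes by 2p̂ and √(2p̂(1−p̂)), mean-imputes
missing cells per marker, drops monomorphic markers, and uses an exact
eigendecomposition of the sample covariance (adequate at desk scale;
a randomized solver would slot in behind the same interface for large
inputs).  Variance-explained fractions are non-increasing and sum
to ≤ 1; with two diverged subpopulations only PC1 carries appreciable
variance.

## Synthetic data

The generator emulates the statistical structure each stage assumes:
ancestral allele frequencies ~ Uniform(0.05, 0.95); subpopulation
frequencies Beta-distributed around them with divergence F
(Balding–Nichols); founder haplotypes per subpopulation; panel and
study haplotypes produced by mosaic copying between founders with a
per-marker switch rate (0.02 by default), which induces the block LD
the imputer and the LD strand check rely on.  Mosaic copying was
chosen over coalescent simulation for speed and dependency-freedom.
Platforms observe overlapping marker subsets built from a shared core
(overlap 0.6 of a platform's markers by default); injected artifacts —
complement flips on 2% of non-palindromic markers, a constant build
offset with 2% unmapped markers, 5 duplicate samples, 2% missingness —
are recorded in a truth store.  Identical configuration and seed give
identical fixtures.

What the generator does *not* emulate: realistic human demography or
recombination maps, genotyping batch effects, platform-specific error
modes, indels, and the X chromosome.  Passing tests therefore
demonstrate that the pipeline's logic is correct and self-consistent
on data with the right coarse structure, not that any particular
accuracy level transfers to real cohorts.

## Scale of the shipped experiments

Tests and examples run at desk scale: panels of 150–600 markers and
60–400 haplotypes, 3 platforms × 40–60 samples, SNPlet cores of 200
markers with 30-marker buffers in the pipeline defaults.  The
segmentation functions themselves default to the field-standard
30,000/700 and 6 Mb/250 kb parameters and are tested at those sizes.
Headline counts from production-scale studies (tens of millions of
markers, tens of thousands of samples) depend on the underlying
cohort data and are not reproduced here.

## Known limitations

* The toy imputer has no recombination-map awareness and no
  phasing-uncertainty model; its accuracy is below HMM engines,
  which is acceptable for exercising the surrounding pipeline.
* Phasing is consumed, not performed: study haplotypes must be
  supplied (by an external tool, or the simulator's truth store).
* The `certainty` info column is carried as an opaque metric and
  merged by the generic averaging rule; no formula is imposed.
* Strand LD arbitration needs polymorphic, LD-bearing neighbors;
  isolated palindromic markers at high MAF are discarded rather than
  guessed.
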