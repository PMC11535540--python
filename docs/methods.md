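# Methods

This note records the models the package implements, the conventions and
parameter choices behind them, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Coordinates and formats

All intervals are 0-based half-open, the native convention of BED and
bedGraph; 1-based browser-style positions must be converted on input
(`formats_io.from_one_based`). Gene annotation is consumed as a "GTF-lite"
transcript table (TSV) rather than full GTF: the pipeline needs only
transcript and CDS bounds per transcript. Signal tracks are 4-column
bedGraph with strictly disjoint bins per chromosome; overlapping bins are
rejected rather than resolved.

## Screen statistics

**Counting region.** For each gene the disruptive region runs from the TSS
to the stop codon of the transcript with the longest ORF (ties: longer
transcript span, then lexicographically smallest transcript id). On the +
strand this is `[tx_start, cds_end)`; on the − strand `[cds_start, tx_end)`.
The three bases of the stop codon fall inside the region — whether the
original analyses included them is unknowable from their description, and
at screen scale the 3 bp are immaterial; the choice is fixed here for
determinism. Base pairs covered by two or more gene models (either strand)
cannot be attributed to a single gene and are excluded from every gene;
fully nested genes can end up with an empty region and are then untestable.

**Counting.** Insertions are deduplicated to unique
(chromosome, position, orientation) triples per pool; only insertions
inside a gene's counting region *and* oriented with the gene's strand
(sense = disruptive for a gene-trap cassette) are counted. Merging two
pools of the same kind is a union at the insertion level followed by
deduplication, which is exactly what concatenating the raw libraries
before mapping would produce.

**Pool totals.** The mutational-index denominator "total sense insertions"
is ambiguous when insertions fall in ambiguous-overlap regions. The
default (`assigned`) counts only insertions assigned to a unique counting
region, which makes MI invariant to intergenic/antisense background; the
alternative (`all-sense`) counts every unique insertion that is sense to
at least one raw gene-model span. Both are exposed on the CLI
(`--total-mode`).

**MI and significance.** MI is carried both as a ratio and as log₂. The
degenerate values 0 (a = 0 < b) and +∞ (b = 0 < a) are kept as such for the
point estimate — no pseudocount enters any reported statistic; a
pseudocounted variant exists only for plotting. The two-sided Fisher test
is computed by the method of small p-values on the exact integer
hypergeometric distribution: numerators C(n₁,x)·C(n₂,m−x) are built with
an exact integer recurrence, tables are compared by integer comparison
(ties are exact, no floating-point slack), and the final division is the
only floating-point operation. This makes the implementation agree with a
full-enumeration rational oracle to < 10⁻¹² over all tables with margins
≤ 30 (verified exhaustively in the test suite) while remaining fast for
pool totals in the hundreds of thousands. Genes with a + b = 0 are
excluded from testing *and* from the BH family — including them would
deflate the correction with untestable hypotheses. BH adjustment delegates
to statsmodels (`fdr_bh`), checked in tests against the literal step-up
definition. Hits at fcpv < 0.05 are classed repressor (MI > 1) or
activator (MI < 1); MI exactly 1 is never significant in practice and
would be left unclassed.

## LAD annotation

The genic NL score is the overlap-weighted mean of the log₂-ratio track
over `[region_start − flank, region_end + flank)` with flank 10 kb,
clipped at chromosome ends; `is_lad` is strictly score > 0 (a score of
exactly 0 is iLAD). Genes with no overlapping bins get NaN and are
excluded from downstream contrasts rather than imputed. Promoter scores
use a symmetric TSS ± 500 bp window (strand only locates the TSS); active
promoters are those with activity strictly > 0.3. The proximal-peak
classifier (nearest peak midpoint within 100 kb of the TSS; matched if the
other condition has a peak midpoint within 1 kb) is an interpretive
reading — the underlying analyses never define "proximal" or peak matching
— so both distances are parameters, and when both conditions' proximal
peaks are unmatched the gain is reported (the gain check runs first).

## Differential response

The built-in DE caller is deliberately simple — a desk-scale caller for
synthetic counts, not a negative-binomial GLM: per-gene Welch t-test on
log₂(count + 1) with BH correction, log₂FC as the difference of group
means of the same transform, and a TPM-like activity proxy from the
control count share (genes are treated as equal-length). DE tables read
from files are used as-is: their padj column is never recomputed.

The activity filter drops control TPM < 0.3 (a gene at exactly 0.3 is
kept, matching the stated exclusion rule "< 0.3"; note the *promoter*
activity filter above is the opposite-edged "> 0.3" — both quoted rules
are implemented literally). Matching sorts by descending control TPM with
a stable gene-id tie-break, walks blocks of 20 (last block may be short),
and samples per block without replacement; blocks where LAD genes
outnumber iLAD genes contribute all their iLAD genes and record the
shortfall, which the `MatchedSet` bookkeeping exposes. The rank-sum test
uses the exact null for combined n ≤ 25 without ties and the tie-corrected
normal approximation otherwise; the spread test is classic Levene
(mean-centered) with Brown–Forsythe (median-centered) as an option.

## TRIP analysis

Expression per barcode and sample is (cDNA share) / (gDNA share), shares
taken within the sample — invariant to global rescaling of either library.
A raw cDNA/gDNA ratio mode exists because the normalization used upstream
of published tables is not always specified. Barcodes need gDNA strictly
> 100 in *every* sample; knockdown log₂FC is the log of the ratio of mean
normalized expression across replicates, with zero-control barcodes
flagged and excluded rather than patched. A barcode's LAD status comes
from the genic-style point score (position ± 10 kb against the DamID
track, `is_lad` ⇔ score > 0). Replicates whose total cDNA falls below a
configurable floor are flagged for exclusion, never dropped silently.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given a seed; a root seed is split into
fixed, named substreams (genome, screen, damid, de, trip, lads) so a whole
pipeline run reproduces byte-identically from one integer.

* **Genome**: non-overlapping genes (log-normal lengths, median 20 kb,
  σ = 0.5 — a human-like scale with a moderate spread so per-gene
  insertion expectations stay within a factor of a few of the mean),
  exponential intergenic gaps, a few chromosomes. Real genomes have
  overlapping and nested genes; overlap handling is exercised separately
  with crafted models.
* **Screen**: genic sense insertions land in genes ∝ counting-region
  length, uniformly within the region, and go HIGH with probability
  θ/(1+θ) — θ is the planted effect (1 neutral, 4 repressor, 0.25
  activator in the benchmarks). Antisense (50% of genic) and intergenic
  (40% of all) insertions split 50/50 between pools; duplicate sites are
  injected at rate 0.05; pool totals are realized, not balanced — the MI
  normalization absorbs the imbalance. The default depth is ~100 expected
  genic sense insertions per gene per pool, the regime of a saturating
  haploid screen. Not modeled: FACS gate impurity, insertion hotspots,
  fitness effects of knockouts.
* **DamID track**: bin values are Normal(μ_in, σ) when the bin midpoint is
  inside a planted LAD, Normal(μ_out, σ) otherwise (defaults +1/−1,
  σ = 0.5, 2-kb bins); planted LADs alternate with gaps at exponential
  lengths (mean 1 Mb, ~30% of the genome). Real tracks have autocorrelated
  noise, mappability gaps and graded LAD borders; consequently the
  LAD-call benchmarks condition on genes lying well inside domains, and
  border behaviour should not be over-read.
* **Expression / DE counts**: control expression is log-normal per stratum
  with LAD genes a two-component mixture — 75% silent (location e⁻⁸,
  far below the TPM-0.3 floor) and 25% "escapers" at location e^0.5 versus
  e² for iLAD (σ = 2 ln-units). This reproduces the defining structure of
  LAD expression: most LAD genes off, expressed LAD genes a ~1:15 minority
  of the expressed catalogue and still several-fold below the iLAD median,
  with enough lowly expressed iLAD genes that blockwise matching is
  feasible at every expression level. Responsive genes (fractions per
  stratum, defaults 0.25 up / 0.10 down in LAD and 0.10/0.10 in iLAD)
  scale their treatment mean by 2^lfc, lfc ~ N(1, 0.25²); counts are
  gamma-Poisson (NB) at dispersion 0.05 and depth 2 × 10⁷, which puts
  reads-per-gene in the range of a standard ~30 M-read library. Not
  modeled: gene length in TPM, compositional renormalization after
  perturbation (treatment means are depth-anchored so the planted lfc is
  exact), batch effects.
* **TRIP**: barcodes integrate uniformly; per-barcode abundance is
  log-normal (gDNA mean ~1000, so the >100 filter trims only the planted
  5% low-gDNA barcodes); log₂ expression is a baseline minus a 3-log₂ LAD
  penalty, plus Δ (default 0.5) for LAD barcodes in knockdown samples,
  plus per-sample N(0, 0.5) noise; cDNA counts are Poisson around
  abundance-weighted expression shares. Not modeled: promoter identity of
  the reporter, barcode sequencing errors, position effects within LADs.

Because the generators draw from exactly the distributions the statistics
assume (independent insertions, Gaussian track noise, NB counts), passing
benchmarks demonstrate correctness of the implementations and calibration
under the stated model — not robustness to the artifacts of real
sequencing data.

## Benchmark problem sizes

The statistical acceptance checks run at the study conditions they probe:
2,000-gene screens at ~100 sense insertions per gene per pool (20 seeds
each for null calibration and for recovery of 50 + 50 planted effects);
100-gene track fixtures over 10 seeds for LAD calls; 5,000-gene tables
over 50 seeds for matching quality; 4,000-gene, 6 vs 6 count matrices over
20 seeds for the response contrast; 600-barcode pools over 50 seeds for
TRIP recovery. The exact-test oracle comparison is exhaustive over all
2×2 tables with margins ≤ 30 (~164k tables). These sizes make the whole
suite run in about two minutes on one CPU while keeping every proportion
estimate's binomial error well below the margins being asserted.

## Known limitations

* The simple DE caller is not a substitute for NB-GLM inference on real
  counts; it exists so the pipeline is exercisable end-to-end on synthetic
  data, and its p-values are anti-conservative for very low counts.
* `screen_overlap` and `set_enrichment` treat hit sets as unordered; no
  significance is attached to overlap fractions.
* The `all-sense` totals mode and the proximal-peak defaults are
  documented interpretations of under-specified procedures; conclusions
  sensitive to them should be checked under both settings.
* Levene's test on heavy-tailed log₂FC distributions (mean-centered
  variant) is sensitive to outliers; the Brown–Forsythe option is the
  robust alternative.
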