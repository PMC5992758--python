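# Methods

`ffpecall` calls somatic SNVs/indels, DNA gene fusions and copy-number
alterations (CNAs) from targeted capture sequencing of formalin-fixed
paraffin-embedded (FFPE) tumor specimens against an unmatched pooled-normal
control. FFPE chemistry damages and fragments DNA, inflating low-VAF
substitution artifacts (classically strand-asymmetric C>T near fragment
ends), and clinical specimens bring low tumor purity and no matched normal.
The design principle throughout is therefore *non-parametric statistics plus
internal controls estimated from the data itself*: no assumptions are made
about Phred calibration or platform error rates, and every filter threshold
that is a rate is estimated from the sample being analysed, not hard-coded.

## SNV/indel calling

**Extraction.** At every target position the tumor and control allele counts
(A/C/G/T, plus left-aligned `ins:<seq>`/`del:<len>` keys anchored at the
preceding base) form a 2×2 table per non-reference allele. A one-sided
Fisher's exact test (enrichment in tumor; upper hypergeometric tail) emits a
candidate when p ≤ `alpha_extract` (default 1e-4) and the tumor alt count is
at least `min_alt` (default 3). Sidedness is a deliberate choice: somatic
calling is directional. A zero-depth control produces the degenerate-table
p of 1.0; such candidates are emitted with a warning flag rather than
silently dropped, since the alpha cut would otherwise hide a coverage
failure.

**Noise-filter cascade.** Eight filters in Illumina mode, nine in Ion mode,
in three sets. All set-1 verdicts are evaluated unconditionally, so the
PASS/FAIL state is invariant to their order; the reported `FILTER` is the
first failing name in the documented order.

*Set 1* — per-site read-level tests (per-test alpha default 1e-4):

- **misalignment** — alt-supporting reads carrying an excess of additional
  non-reference mismatches, tested with a binomial tail against the per-base
  mismatch rate estimated from all reads in a ±10-column window (panel-wide
  rate as fallback). Zero usable control reads → pass with an
  "insufficient control" annotation.
- **strand-bias** — one-sided Fisher test of alt fwd/rev vs ref fwd/rev, in
  the direction in which the alt strand ratio is the more extreme; vacuous
  with zero alt reads.
- **within-long-homopolymer** — fail if the variant (for indels: the anchor
  or the following base) lies inside a single-base run of length ≥ 8
  (inclusive threshold).
- **MQ0** — fail if MQ0 coverage / (MQ0 + counted depth) exceeds 0.1
  (strict inequality; mapping-quality-zero reads are tallied per site by the
  prep filters but never counted toward alleles).
- **read-end-call** — one-sided Fisher test of alt vs ref calls within 5 bp
  of a read end; vacuous below two alt observations.
- **surrounded-by-dust** — count window positions (±10) carrying a
  sub-candidate non-reference allele at 2–25% VAF with ≥ 2 reads, and test
  against the panel-wide rate of such "dusty" positions with a binomial
  tail. This captures the halo of correlated noise around FFPE artifacts.
- **abnormal-BQ-drop** (Ion indels only) — fail when mean base quality
  downstream of the event drops by more than 10 relative to upstream,
  averaged over supporting reads.

*Set 2* — **second Fisher pass**: supporting reads whose extra-mismatch
count is extreme under a Poisson model of the internal-control mismatch rate
(tail < 1e-3, minimum 2 mismatches) are removed; the terminal 5 bp of every
read are trimmed from counting; the tumor/control table is rebuilt and the
one-sided Fisher test re-run at `alpha_extract`. Reference-side trimmed
counts are reconstructed from per-position tallies of calls within the trim
window; erroneous-read removal is applied to supporting reads only (the
reference pool is large enough that the correction is negligible there).

*Set 3* — **VAF-lees**: the VAFs of candidates surviving sets 1–2 are
modelled as a beta mixture fitted by EM; k = 1..10 is selected by ICL-BIC
(−2 logL + (3k−1) log n + 2·classification entropy), with ties toward
smaller k and early stopping after two consecutive non-improving k. The
M-step maximises each component's weighted beta likelihood with a
safeguarded (step-halving) Newton update in (log α, log β), making the
update a valid GEM step: the observed-data log-likelihood is monotone.
Initialisation is quantile-block method-of-moments with 5 seeded restarts.
A component whose mean lies in the 1–3% band is the error component; each
candidate is then tested with the beta-binomial upper tail of
(alt | depth) under that component's (α, β). Calls consistent with the
error distribution (p > 0.01) are removed as lees. Fewer than 20 usable
VAFs, or no component in the band, disables the filter for the run. There
is no hard VAF cutoff anywhere.

**Germline heuristic** (unmatched control): candidates matching a
SNP-database record (chrom, pos, ref, alt) or with VAF in [0.40, 0.60] or
above 0.96 are removed. This is exact band arithmetic, not a test.

**Multiple testing.** No FDR layer is applied beyond `alpha_extract`; the
cascade is a sequence of vetoes by design, and this is intentional.

## Fusion calling

Reads are locally aligned with an external `bwa mem` subprocess (`-a -Y`,
seed 12, score threshold 16 — permissive enough to report ~20 bp split
arms). The **2map** step keeps reads whose left and right portions (each
≥ 20 bp) map to two different genes; read-coordinate overlap between the
halves (junction microhomology) is trimmed from the left segment so all
reads of a junction yield one consistent breakpoint representation, and
reads split across three loci are dropped as ambiguous. Breakpoints are
clustered within ±5 bp with a majority vote on the junction; PCR duplicates
(identical segment spans) are collapsed before support counting. The
**virtual fusion** step builds a 2×200 bp junction reference from the
breakpoints (orientations respected) and rescues unassigned reads that
align full-length (edlib infix alignment, identity ≥ 0.95) across the
junction with ≥ 1 base on each side; a read counts toward at most one
candidate (best identity, ties dropped). In paired-end mode, discordant
pairs whose mates map unsplit to the two genes within 1 kb of the
breakpoints on the correct sides add `pair_support`, reported separately
and, by default, not added into the ranking total: split evidence pinpoints
breakpoints, pairs corroborate. Candidates must touch at least one
user-indicated gene. Ranking reports the S/N ratio (own support over the
strongest other candidate, infinity when alone) and the normalized support
count (support / all mapped reads).

## CNA calling

Targets are cut into ≤ 100 bp bins; per-bin depth is LOWESS-regressed on GC
(span 0.5, ≥ 50 usable bins required — with fewer bins the correction is
disabled rather than extrapolated) and corrected multiplicatively toward
the panel median. Bins with GC outside the central 98% of the panel's GC
distribution are flagged: high-GC regions are a known weakness of
depth-ratio CNA calling on small panels and no fix is attempted. The
per-bin logR = log2(tumor/control corrected depth) is median-centred
(assuming a majority-neutral panel; the offset is logged).

Segmentation is circular binary segmentation with a standardized
Mann–Whitney rank statistic: within windows of 500 bins, the arc (i, j]
maximising |z| of the rank sum (continuity-corrected) is tested with a
label-permutation p (1000 permutations); splits with p ≤ 0.01 recurse until
width < 3 bins. Window results are compiled to chromosome scale by merging
adjacent terminal segments whose levels a Mann–Whitney test cannot
distinguish. Two post-passes follow, both standard CBS practice: splits
whose level difference is below 1.5 robust noise SDs (MAD of first
differences) are undone, and every surviving boundary is re-localized to
the argmax of the two-sample rank statistic between its flanking segments —
the global arc search localizes imprecisely when a window holds more than
two copy levels. A constant (zero-variance) stretch is never split.

The **abortion** pass discards segments where more than 30% of bins deviate
from the segment median by > 0.5 logR (single-bin segments are never
aborted; the fraction rule is vacuous). Surviving segments are classified
by bootstrapping the segment median (1000 resamples, 95% interval): AMP if
the lower bound clears +0.8 logR, DEL if the upper bound is below −0.8,
else NEUTRAL; segments under 3 bins are NEUTRAL by fiat. The ±0.8 defaults
correspond to ≥ 4 copies / deep loss at full purity; attainable logR scales
with tumor purity, so these are configurable.

## Synthetic data

The generators emulate the study conditions the callers target, through
standard formats (FASTA/BED/SAM/FASTQ) so callers are exercised via their
public interfaces, and are byte-reproducible under a fixed seed.

- **Reads**: uniform starts over the panel, 150 bp, base quality ~N(36, 2),
  MAPQ 60 (configurable MQ0 fraction). Planted variants appear in a read
  covering the site with probability purity × allele fraction (0.5 for
  heterozygous events); indel carriers get rebuilt sequence and CIGAR, with
  planted indels recorded left-aligned to match caller output.
- **FFPE damage**: C>T at 1e-3/base on forward-strand reads (G>A on
  reverse-strand reads, i.e. C>T on the sequenced strand of the damaged
  template), with 3× enrichment in the terminal 5 bp; applied to the
  foreground sample only. Parameters are declared, not fitted to any real
  dataset. Sequencing error is an additional uniform 1e-3 substitution in
  both samples.
- **Negative controls**: same-truth mode plants identical variants in both
  samples at full heterozygous VAF, with FFPE noise in the tumor only — a
  correct somatic caller returns nothing.
- **Fusions**: chimeric reads with uniform split positions across a planted
  junction (optionally jittered), random strand, plus background gene reads
  and random-gene-pair noise chimeras; `clean_junction` screens breakpoints
  for 2 bp of microhomology so clean fixtures are exactly recoverable.
- **Depth profiles**: Poisson bins around base × 2^logR with an optional
  multiplicative linear GC bias.

Not modelled: fragment-size distributions, sequencer-specific error
spectra, alignment ambiguity (reads are emitted at their true positions;
mapping noise enters only through the MQ0 machinery and the fusion
aligner), germline variation beyond the planted sites, and subclonal
structure. Passing tests therefore demonstrate the statistics and the
plumbing, not robustness to mapping artifacts in real genomes.

## Numerical and scale choices

Fisher tails are upper hypergeometric survival functions (scipy); tests
verify them against exhaustive enumeration with exact integer arithmetic to
1e-12 for margins ≤ 200, and beta-binomial tails against direct log-space
summation to 1e-9 for depths ≤ 2000. The EM is reproducible bit-for-bit
under a fixed seed. Benchmarks run at desk scale: the dilution-series
sensitivity experiment uses a 50 kb panel at ~970× mean depth with 50
planted heterozygous variants at 10% tumor fraction (≈ 320k reads per
sample, about a minute end to end on one core); segmentation and mixture
recovery suites use 20 seeded replicates each. These sizes were chosen so
the full suite runs comfortably on a laptop while keeping the statistical
regimes (depth, VAF, noise) of the targeted-panel setting.

## Known limitations

Indels are assumed aligner-mapped and short (default cap 10 bp); large
indels and structural variants beyond the targeted fusion genes are out of
scope, as are whole-exome/-genome tuning, allele-specific copy number,
purity/ploidy estimation and matched-normal joint genotyping. The germline
VAF-band heuristic necessarily removes true somatic variants falling in the
heterozygous band; a matched normal, when available, is the better filter.
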