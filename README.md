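# ffpecall

Somatic variant calling tailored to **FFPE targeted sequencing**: an
SNV/indel caller, a DNA gene-fusion caller and a copy-number (CNA) caller
that share one design principle — non-parametric statistics plus internal
controls estimated from the data itself. The intended user analyses
capture-panel sequencing of formalin-fixed paraffin-embedded tumor
specimens against an *unmatched* pooled-normal control, where chemical
damage inflates low-VAF artifacts, tumor purity is low, and no matched
normal or panel of normals exists.

## What it computes

**SNV/indels** — at each target position, tumor vs control allele counts
are compared with a one-sided Fisher's exact test
(p = P(X ≥ alt_T) under the hypergeometric null of the 2×2 table);
candidates then pass a cascade of noise filters (eight for Illumina data,
nine for Ion): misalignment, strand-bias, within-long-homopolymer, MQ0,
read-end-call, surrounded-by-dust, abnormal-BQ-drop (Ion indels), a second
Fisher pass after erroneous-read removal and read-end trimming, and a
"VAF-lees" filter. The lees filter models the candidate VAF distribution as
a beta mixture f(v) = Σ_k w_k Beta(v; α_k, β_k) fitted by EM with ICL-BIC
model selection (k = 1..10); a component with mean in the 1–3% band is the
error distribution, and calls whose beta-binomial upper-tail
P(X ≥ alt | depth, α, β) exceeds the cutoff are removed as residual error
"lees". No hard VAF cutoff is applied anywhere. A germline heuristic for
the unmatched setting removes SNP-database sites and VAFs in
[0.40, 0.60] ∪ (0.96, 1].

**Fusions** — local alignments (external `bwa mem`) feed a split-read
"2map" step (left/right read halves in two different genes ⇒ breakpoints),
a virtual-fusion rescue step (re-alignment of unassigned reads across a
constructed junction reference) and, for paired-end data, a discordant-pair
step. Candidates are ranked by support; the S/N ratio (top support ÷
strongest other candidate, ∞ when unique) and the normalized support count
(support ÷ mapped reads) summarize specificity and sensitivity.

**CNAs** — per-bin depth is LOWESS-corrected for GC, the
logR = log₂(tumor/control) series is segmented by circular binary
segmentation with a standardized Mann–Whitney rank statistic and a
permutation test (windowed, then compiled to chromosome scale), segments
with excessive internal fluctuation are *aborted*, and the rest are
classified AMP/DEL/NEUTRAL by a bootstrap interval of the segment median
against ±0.8 logR.

A seeded synthetic-data module generates FFPE-like fixtures (reads with
strand-asymmetric C>T damage concentrated near read ends, dilution series,
fusion chimeras, copy-number depth profiles) with known ground truth, so
the whole suite is testable without any external data.

## Worked example

```python
from pyfaidx import Fasta
from ffpecall.core_io import load_targets
from ffpecall.simulate import simulate_reference, plant_variants, simulate_snv_reads
from ffpecall.snv import SnvConfig, call_variants

ref = simulate_reference(n_genes=4, lengths=4000, seed=41)
variants = plant_variants(ref, 12, seed=42, kinds=("snv", "ins", "del"))
paths = simulate_snv_reads(ref, ref.genes, variants, purity=0.2, depth=600,
                           outdir="demo", seed=43)
fa, bed = ref.write("demo")
res = call_variants(paths["tumor_sam"], paths["control_sam"],
                    load_targets(bed), Fasta(fa), SnvConfig(seed=1))
print(res.stats["n_candidates"], res.stats["n_pass"])
called = {(c.pos, c.alt) for c in res.candidates if c.status == "PASS"}
print(sum((p, a) in called for p, _, a, _ in variants), "/", len(variants))
```

prints

```
12 12
12 / 12
```

twelve candidates extracted, all twelve passing the cascade, and all twelve
planted variants (SNVs, insertions and deletions at expected VAF
0.2 × 0.5 = 10%) recovered. The same pipeline is available from the shell:

```bash
ffpecall snv --tumor tumor.bam --control control.bam --targets panel.bed \
         --ref genome.fa --platform illumina --out calls.vcf
ffpecall fusion --reads reads.fastq --ref genome.fa --genes genes.bed \
         --gene ALK --out fusions.bedpe
ffpecall cna --tumor tumor.bam --control control.bam --targets panel.bed \
         --ref genome.fa --out segments.seg
ffpecall simulate snv --seed 1 --out fixtures/
```

Outputs are VCF v4.2 (FILTER holds PASS or the first failing filter name;
INFO carries counts, VAF, both Fisher p-values, the lees p and every
verdict), BEDPE plus a FASTA of virtual junction sequences, and a
SEG-style table with bootstrap bounds and abortion flags.

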