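"""Seeded generators of synthetic FFPE-like fixtures with known ground truth.

Everything here is deterministic under a fixed seed and writes standard
formats (FASTA/BED/SAM/FASTQ/TSV), so the callers are exercised through
their public interfaces.  The generators emulate the study conditions the
callers are built for: targeted-capture depth with optional GC bias,
heterozygous/somatic variants diluted by tumor purity, FFPE-like
strand-asymmetric C>T (G>A on reverse-strand reads) substitution noise with
3x enrichment in the terminal 5 bp of reads, chimeric reads across a planted
fusion junction, and piecewise-constant copy-number states.  They do not
model fragment-size distributions, sequencer-specific error profiles or
alignment ambiguity: reads are emitted at their true positions.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Optional, Sequence

import numpy as np

from .cna import DepthBin
from .core_io import BASES, TargetRegion, encode_bases

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode_rows(codes: np.ndarray) -> list[str]:
    return _DECODE[codes].view(f"S{codes.shape[1]}").ravel().astype(str).tolist()


@dataclasses.dataclass
class SimulatedReference:
    """A synthetic contig carrying labelled gene intervals."""

    contig: str
    sequence: str
    genes: list  # TargetRegion with labels

    @property
    def codes(self) -> np.ndarray:
        return encode_bases(self.sequence)

    def write(self, outdir: str) -> tuple[str, str]:
        os.makedirs(outdir, exist_ok=True)
        fasta = os.path.join(outdir, "reference.fa")
        bed = os.path.join(outdir, "genes.bed")
        with open(fasta, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i : i + 80] + "\n")
        with open(bed, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.label}\n")
        return fasta, bed


def simulate_reference(
    n_genes: int = 4,
    lengths: int | Sequence[int] = 3000,
    gc_profile: float | Sequence[float] = 0.45,
    spacer: int = 500,
    seed: int = 0,
    contig: str = "simchr",
) -> SimulatedReference:
    """Random gene-bearing contig with per-gene GC control."""
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        warnings.warn("simulate_reference called with n_genes=0: empty reference")
        return SimulatedReference(contig, "", [])
    lens = [lengths] * n_genes if isinstance(lengths, int) else list(lengths)
    gcs = [gc_profile] * n_genes if isinstance(gc_profile, (int, float)) else list(gc_profile)
    parts: list[str] = []
    genes: list[TargetRegion] = []
    pos = spacer
    parts.append(_random_seq(rng, spacer, 0.5))
    for i, (L, gc) in enumerate(zip(lens, gcs)):
        genes.append(TargetRegion(contig, pos, pos + L, label=f"GENE{i + 1}"))
        parts.append(_random_seq(rng, L, gc))
        parts.append(_random_seq(rng, spacer, 0.5))
        pos += L + spacer
    return SimulatedReference(contig, "".join(parts), genes)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p).astype(np.uint8)
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# SNV/indel read simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    variants: list = dataclasses.field(default_factory=list)  # (pos, ref, alt, allele_fraction)
    fusion: Optional[dict] = None
    cn_segments: list = dataclasses.field(default_factory=list)
    noise: dict = dataclasses.field(default_factory=dict)
    seed: int = 0


def plant_variants(
    ref: SimulatedReference,
    n_variants: int,
    seed: int = 0,
    allele_fraction: float = 0.5,
    spacing: int = 400,
    kinds: Sequence[str] = ("snv",),
) -> list[tuple]:
    """Choose well-separated variant sites inside the gene intervals and
    non-reference alleles for them."""
    rng = np.random.default_rng(seed)
    codes = ref.codes
    sites: list[int] = []
    gene_spans = [(g.start + 50, g.end - 50) for g in ref.genes]
    total = sum(e - s for s, e in gene_spans)
    attempts = 0
    while len(sites) < n_variants and attempts < n_variants * 200:
        attempts += 1
        u = int(rng.integers(0, total))
        for s, e in gene_spans:
            if u < e - s:
                p = s + u
                break
            u -= e - s
        if all(abs(p - q) >= spacing for q in sites):
            sites.append(p)
    sites.sort()
    from .pileup import left_align_indel

    out = []
    for i, p in enumerate(sites):
        kind = kinds[i % len(kinds)]
        if kind == "snv":
            refb = BASES[codes[p]] if codes[p] < 4 else "A"
            alt = BASES[int((codes[p] + rng.integers(1, 4)) % 4)]
            out.append((p, refb, alt, allele_fraction))
            continue
        # record indels in left-aligned form, matching caller output
        if kind == "ins":
            seq = encode_bases(_random_seq(rng, int(rng.integers(1, 4)), 0.5))
            pos_la, seq_la = left_align_indel(codes, p + 1, "ins", seq)
            alt = "ins:" + "".join(BASES[c] for c in seq_la)
        else:
            n = int(rng.integers(1, 4))
            pos_la, _ = left_align_indel(codes, p + 1, "del", codes[p + 1 : p + 1 + n])
            alt = f"del:{n}"
        anchor = pos_la - 1
        refb = BASES[codes[anchor]] if codes[anchor] < 4 else "A"
        out.append((anchor, refb, alt, allele_fraction))
    return out


def _apply_ffpe(
    codes: np.ndarray,
    reverse: np.ndarray,
    rng: np.random.Generator,
    rate: float,
    end_factor: float,
    end_window: int,
) -> None:
    n, L = codes.shape
    dist = np.minimum(np.arange(L), L - 1 - np.arange(L))
    pcol = np.where(dist < end_window, rate * end_factor, rate)
    chunk = 20000
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        hit = rng.random((e - s, L)) < pcol[None, :]
        fwd = ~reverse[s:e]
        block = codes[s:e]
        block[(block == 1) & hit & fwd[:, None]] = 3  # C>T on forward reads
        block[(block == 2) & hit & reverse[s:e, None]] = 0  # G>A on reverse reads


def _apply_seq_error(codes: np.ndarray, rng: np.random.Generator, rate: float) -> None:
    n, L = codes.shape
    chunk = 20000
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        block = codes[s:e]
        hit = (rng.random((e - s, L)) < rate) & (block < 4)
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            block[hit] = (block[hit] + shift) % 4


def _simulate_sample(
    ref: SimulatedReference,
    targets: Sequence[TargetRegion],
    variants: Sequence[tuple],
    vaf_scale: float,
    depth: float,
    read_len: int,
    rng: np.random.Generator,
    sam_path: str,
    sample: str,
    ffpe_rate: float = 0.0,
    ffpe_end_factor: float = 3.0,
    ffpe_end_window: int = 5,
    seq_error: float = 1e-3,
    mq0_frac: float = 0.0,
    baseq_mean: float = 36.0,
    baseq_sd: float = 2.0,
) -> int:
    """Write one coordinate-sorted SAM of simulated reads; returns read count."""
    codes_ref = ref.codes
    spans = [(t.start, max(t.end - read_len, t.start + 1)) for t in targets]
    weights = np.array([e - s for s, e in spans], dtype=float)
    total_len = sum(t.end - t.start for t in targets)
    n_reads = int(round(total_len * depth / read_len))
    if n_reads == 0:
        with open(sam_path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{ref.contig}\tLN:{len(ref.sequence)}\n")
        return 0
    which = rng.choice(len(spans), size=n_reads, p=weights / weights.sum())
    starts = np.empty(n_reads, dtype=np.int64)
    for i, (s, e) in enumerate(spans):
        m = which == i
        starts[m] = rng.integers(s, e, size=int(m.sum()))
    starts.sort()
    reverse = rng.random(n_reads) < 0.5
    codes = codes_ref[starts[:, None] + np.arange(read_len)[None, :]].copy()

    special: dict[int, tuple] = {}  # read index -> indel variant applied
    for pos, refb, alt, af in variants:
        lo = int(np.searchsorted(starts, pos - read_len + 1))
        hi = int(np.searchsorted(starts, pos, side="right"))
        if hi <= lo:
            continue
        carrier = rng.random(hi - lo) < vaf_scale * af
        idx = np.arange(lo, hi)[carrier]
        if alt in BASES:
            codes[idx, pos - starts[idx]] = BASES.index(alt)
        else:
            k = len(alt.split(":", 1)[1]) if alt.startswith("ins:") else 0
            for i in idx:
                a = pos - int(starts[i]) + 1
                # the event plus >=1 flanking base must fit inside the read
                if i not in special and 1 <= a <= read_len - k - 1:
                    special[int(i)] = (pos, alt)

    if ffpe_rate > 0:
        _apply_ffpe(codes, reverse, rng, ffpe_rate, ffpe_end_factor, ffpe_end_window)
    if seq_error > 0:
        _apply_seq_error(codes, rng, seq_error)
    quals = np.clip(np.rint(rng.normal(baseq_mean, baseq_sd, size=codes.shape)), 2, 40).astype(np.uint8)
    mapq = np.full(n_reads, 60, dtype=np.int64)
    if mq0_frac > 0:
        mapq[rng.random(n_reads) < mq0_frac] = 0

    seq_strings = _decode_rows(codes)
    qual_strings = (quals + 33).view(f"S{read_len}").ravel().astype(str).tolist()
    cigar_default = f"{read_len}M"
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{ref.contig}\tLN:{len(ref.sequence)}",
    ]
    for i in range(n_reads):
        if i in special:
            pos_v, alt = special[i]
            seq_s, cigar = _indel_read(codes_ref, int(starts[i]), read_len, pos_v, alt)
            qual_s = qual_strings[i][: len(seq_s)]
        else:
            seq_s, cigar, qual_s = seq_strings[i], cigar_default, qual_strings[i]
        flag = 16 if reverse[i] else 0
        lines.append(
            f"{sample}.{i}\t{flag}\t{ref.contig}\t{starts[i] + 1}\t{mapq[i]}\t{cigar}"
            f"\t*\t0\t0\t{seq_s}\t{qual_s}"
        )
    with open(sam_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return n_reads


def _indel_read(codes_ref: np.ndarray, start: int, read_len: int, pos: int, alt: str) -> tuple[str, str]:
    """Read sequence and CIGAR for a read carrying an indel anchored at pos."""
    a = pos - start + 1  # bases through the anchor
    if alt.startswith("del:"):
        n = int(alt.split(":", 1)[1])
        rest = read_len - a
        seq = np.concatenate([codes_ref[start : pos + 1], codes_ref[pos + 1 + n : pos + 1 + n + rest]])
        cigar = f"{a}M{n}D{rest}M"
    else:
        ins = alt.split(":", 1)[1]
        k = len(ins)
        rest = read_len - a - k
        seq = np.concatenate(
            [codes_ref[start : pos + 1], encode_bases(ins), codes_ref[pos + 1 : pos + 1 + rest]]
        )
        cigar = f"{a}M{k}I{rest}M"
    return "".join("ACGTN"[c] for c in seq), cigar


def simulate_snv_reads(
    ref: SimulatedReference,
    targets: Sequence[TargetRegion],
    variants: Sequence[tuple],
    purity: float,
    depth: float,
    outdir: str,
    read_len: int = 150,
    seed: int = 0,
    ffpe_rate: float = 1e-3,
    ffpe_end_factor: float = 3.0,
    seq_error: float = 1e-3,
    same_truth_control: bool = False,
    control_depth: Optional[float] = None,
) -> dict:
    """Simulate a tumor (foreground) and control (background) read set.

    Tumor reads carry the planted alleles at expected VAF = purity x allele
    fraction plus FFPE-like noise; the control is clean.  In same-truth mode
    (negative control) both samples share the planted variants at full
    heterozygous VAF and only the tumor carries FFPE noise -- a correct
    somatic caller should then emit nothing.  Returns paths and a truth
    table; byte-identical outputs under a fixed seed.
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tumor_sam = os.path.join(outdir, "tumor.sam")
    control_sam = os.path.join(outdir, "control.sam")
    n_t = _simulate_sample(
        ref, targets, variants, 1.0 if same_truth_control else purity, depth, read_len,
        rng, tumor_sam, "t", ffpe_rate=ffpe_rate, ffpe_end_factor=ffpe_end_factor,
        seq_error=seq_error,
    )
    control_vars = variants if same_truth_control else []
    n_c = _simulate_sample(
        ref, targets, control_vars, 1.0, control_depth or depth, read_len,
        rng, control_sam, "c", ffpe_rate=0.0, seq_error=seq_error,
    )
    truth_path = os.path.join(outdir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tallele_fraction\texpected_vaf\n")
        scale = 1.0 if same_truth_control else purity
        for pos, refb, alt, af in variants:
            fh.write(f"{ref.contig}\t{pos}\t{refb}\t{alt}\t{af}\t{scale * af:.4f}\n")
    truth = SimTruth(
        variants=list(variants),
        noise={
            "ffpe_rate": ffpe_rate,
            "ffpe_end_factor": ffpe_end_factor,
            "seq_error": seq_error,
            "depth": depth,
            "purity": purity,
            "same_truth_control": same_truth_control,
        },
        seed=seed,
    )
    return {
        "tumor_sam": tumor_sam,
        "control_sam": control_sam,
        "truth": truth_path,
        "sim_truth": truth,
        "n_tumor_reads": n_t,
        "n_control_reads": n_c,
    }


# ---------------------------------------------------------------------------
# fusion read simulation
# ---------------------------------------------------------------------------

def clean_junction(ref: SimulatedReference, gene_a: str, gene_b: str, seed: int = 0) -> tuple[int, int]:
    """Pick breakpoints near the gene midpoints with no junction
    microhomology (the bases flanking the junction differ on both sides for
    2 bp), so the planted junction is exactly recoverable from alignments."""
    rng = np.random.default_rng(seed)
    genes = {g.label: g for g in ref.genes}
    seq = ref.sequence
    ga, gb = genes[gene_a], genes[gene_b]
    for _ in range(200):
        pa = int(rng.integers((ga.start + ga.end) // 2 - 200, (ga.start + ga.end) // 2 + 200))
        pb = int(rng.integers((gb.start + gb.end) // 2 - 200, (gb.start + gb.end) // 2 + 200))
        if all(seq[pa + 1 + i] != seq[pb + i] for i in range(2)) and all(
            seq[pa - i] != seq[pb - 1 - i] for i in range(2)
        ):
            return pa, pb
    return (ga.start + ga.end) // 2, (gb.start + gb.end) // 2


def simulate_fusion_reads(
    ref: SimulatedReference,
    gene_a: str,
    gene_b: str,
    bp_a: int,
    bp_b: int,
    out_fastq: str,
    n_support: int = 20,
    read_len: int = 150,
    junction_jitter: int = 0,
    noise_chimeras: int = 0,
    n_background: int = 500,
    seed: int = 0,
) -> dict:
    """Chimeric reads across a planted junction (split position uniform along
    the read, random strand), optional random-gene-pair noise chimeras, and
    background reads from the gene bodies.  The junction joins the sequence
    up to and including bp_a to the sequence from bp_b onward."""
    rng = np.random.default_rng(seed)
    seq = ref.sequence
    genes = {g.label: g for g in ref.genes}
    reads: list[tuple[str, str]] = []
    for i in range(n_support):
        s = int(rng.integers(1, read_len))
        jit = int(rng.integers(-junction_jitter, junction_jitter + 1)) if junction_jitter else 0
        ja, jb = bp_a + jit, bp_b + jit
        chunk = seq[ja + 1 - s : ja + 1] + seq[jb : jb + (read_len - s)]
        if len(chunk) < read_len:
            continue
        if rng.random() < 0.5:
            chunk = chunk.translate(_RC)[::-1]
        reads.append((f"fus.{i}", chunk))
    labels = list(genes)
    for i in range(noise_chimeras):
        ga, gb = rng.choice(len(labels), size=2, replace=False)
        pa = int(rng.integers(genes[labels[ga]].start + read_len, genes[labels[ga]].end - read_len))
        pb = int(rng.integers(genes[labels[gb]].start + read_len, genes[labels[gb]].end - read_len))
        s = int(rng.integers(30, read_len - 30))
        chunk = seq[pa + 1 - s : pa + 1] + seq[pb : pb + (read_len - s)]
        reads.append((f"noise.{i}", chunk))
    for i in range(n_background):
        g = genes[labels[int(rng.integers(0, len(labels)))]]
        s = int(rng.integers(g.start, g.end - read_len))
        reads.append((f"bg.{i}", seq[s : s + read_len]))
    with open(out_fastq, "w") as fh:
        for name, s in reads:
            fh.write(f"@{name}\n{s}\n+\n{'I' * len(s)}\n")
    return {
        "fastq": out_fastq,
        "gene_a": gene_a,
        "gene_b": gene_b,
        "bp_a": bp_a,
        "bp_b": bp_b,
        "n_support": n_support,
        "n_reads": len(reads),
    }


_RC = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# depth-profile simulation
# ---------------------------------------------------------------------------

def simulate_depth_profile(
    cn_segments: Sequence[tuple[int, int, float]],
    n_bins: int,
    base_depth: float = 200.0,
    gc_bias: float = 0.0,
    bias_tumor_only: bool = False,
    bin_size: int = 100,
    seed: int = 0,
    chrom: str = "simchr",
) -> tuple[list, list, np.ndarray]:
    """Poisson tumor/control depth-bin series over planted copy-number
    segments (start_bin, end_bin, logR); GC per bin uniform on [0.3, 0.7]
    with multiplicative linear bias ``1 + 2*gc_bias*(gc - 0.5)``.  Returns
    (tumor_bins, control_bins, true per-bin logR)."""
    rng = np.random.default_rng(seed)
    logr = np.zeros(n_bins)
    for s, e, v in cn_segments:
        logr[s:e] = v
    gc = rng.uniform(0.3, 0.7, size=n_bins)
    bias = 1.0 + 2.0 * gc_bias * (gc - 0.5)
    lam_c = base_depth * (np.ones(n_bins) if bias_tumor_only else bias)
    lam_t = base_depth * (2.0 ** logr) * bias
    t_depth = rng.poisson(lam_t).astype(float)
    c_depth = rng.poisson(lam_c).astype(float)
    tumor, control = [], []
    for i in range(n_bins):
        s = i * bin_size
        tumor.append(DepthBin(chrom, s, s + bin_size, float(gc[i]), t_depth[i], masked=t_depth[i] == 0))
        control.append(DepthBin(chrom, s, s + bin_size, float(gc[i]), c_depth[i], masked=c_depth[i] == 0))
    return tumor, control, logr
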