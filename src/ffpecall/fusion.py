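"""DNA gene-fusion detection from targeted capture reads.

Strategy: local alignment (an external ``bwa mem`` subprocess) yields, per
read, zero or more local alignments with read-coordinate extents.  The 2map
step finds reads whose left and right portions map to two different genes,
giving the fusion breakpoints directly from the split.  The virtual-fusion
(VF) step builds a junction reference from the 2map breakpoints and rescues
support reads whose alignment on one side was too short for split mapping,
by re-aligning unassigned reads across the constructed junction (edlib infix
alignment).  In paired-end mode, discordant pairs whose mates straddle the
junction add corroborating pair support.  Candidates are ranked by support;
the S/N ratio (top support over the strongest other candidate, infinity when
unique) and the normalized support count (support over all mapped reads)
summarize specificity and sensitivity.

At least one gene of the searched fusion must be named by the user; reads
split across three or more loci are dropped.
"""

from __future__ import annotations

import dataclasses
import os
import subprocess
import tempfile
from collections import defaultdict
from typing import NamedTuple, Optional, Sequence, Union

import edlib
import numpy as np
import pysam
from pyfaidx import Fasta

from .core_io import TargetRegion, load_targets

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AlignerNotFoundError(RuntimeError):
    pass


class Breakpoint(NamedTuple):
    chrom: str
    pos: int  # 0-based last aligned base before the junction on this side
    orientation: str  # '+' : fused segment lies at/upstream of pos; '-' : downstream


@dataclasses.dataclass
class LocalAlignment:
    """One local alignment of (part of) a read, in original read coordinates."""

    name: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # '+'/'-'
    q_start: int  # 0-based, original read orientation
    q_end: int  # exclusive
    read_len: int
    mapq: int = 60
    is_read2: bool = False


@dataclasses.dataclass
class FusionCandidate:
    gene_a: str
    gene_b: str
    bp_a: Breakpoint
    bp_b: Breakpoint
    split_support: int = 0
    vf_support: int = 0
    pair_support: int = 0
    sn_ratio: float = 0.0
    norm_support: float = 0.0
    virtual_ref: Optional[str] = None
    junction_index: Optional[int] = None  # index of the first bp_b-side base
    support_read_names: set = dataclasses.field(default_factory=set)
    junction_obs: list = dataclasses.field(default_factory=list)

    def total_support(self, include_pairs: bool = False) -> int:
        t = self.split_support + self.vf_support
        return t + self.pair_support if include_pairs else t

    @property
    def name(self) -> str:
        return f"{self.gene_a}>>{self.gene_b}"


@dataclasses.dataclass
class FusionConfig:
    min_seg: int = 20  # bp required on each side for a 2map split
    merge_tol: int = 5  # breakpoint clustering tolerance (bp)
    vf_flank: int = 200  # flank per side of the virtual junction reference
    vf_min_identity: float = 0.95
    max_seg_overlap: int = 10  # max read-coordinate overlap of the two halves
    pair_max_dist: int = 1000  # mate-to-breakpoint distance window
    include_pairs_in_ranking: bool = False
    bwa: str = "bwa"
    bwa_min_seed: int = 12
    bwa_min_score: int = 16


# ---------------------------------------------------------------------------
# local alignment via external aligner
# ---------------------------------------------------------------------------

def _ensure_index(reference: str, bwa: str) -> None:
    if not os.path.exists(reference + ".bwt"):
        subprocess.run(
            [bwa, "index", reference],
            check=True,
            stdout=subprocess.DEVNULL,
            stderr=subprocess.DEVNULL,
        )


def align_local(
    reads: Union[str, Sequence[str]],
    reference: str,
    config: Optional[FusionConfig] = None,
    workdir: Optional[str] = None,
) -> tuple[dict, dict]:
    """Locally align FASTQ reads with ``bwa mem``, returning per-read local
    alignments and the original read sequences.

    ``reads`` is a FASTQ path, or a pair [R1, R2] in paired-end mode.
    Returns (alignments_by_name, read_seqs) where alignments_by_name maps a
    read name to its list of :class:`LocalAlignment` and read_seqs maps the
    name to the read sequence in original orientation (paired mode keys are
    suffixed /1 and /2).  Raises :class:`AlignerNotFoundError` when the
    aligner binary is missing.
    """
    cfg = config or FusionConfig()
    fastqs = [reads] if isinstance(reads, str) else list(reads)
    try:
        _ensure_index(reference, cfg.bwa)
    except FileNotFoundError as exc:
        raise AlignerNotFoundError(
            f"local aligner '{cfg.bwa}' not found on PATH; install bwa or pass pre-aligned input"
        ) from exc
    own_tmp = workdir is None
    tmpdir = workdir or tempfile.mkdtemp(prefix="ffpecall_bwa_")
    sam_path = os.path.join(tmpdir, "aln.sam")
    cmd = [
        cfg.bwa, "mem",
        "-k", str(cfg.bwa_min_seed),
        "-T", str(cfg.bwa_min_score),
        "-a", "-Y", reference, *fastqs,
    ]
    try:
        with open(sam_path, "w") as out:
            subprocess.run(cmd, check=True, stdout=out, stderr=subprocess.DEVNULL)
    except FileNotFoundError as exc:
        raise AlignerNotFoundError(
            f"local aligner '{cfg.bwa}' not found on PATH; install bwa or pass pre-aligned input"
        ) from exc
    alignments: dict[str, list[LocalAlignment]] = defaultdict(list)
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            name = a.query_name or ""
            if a.is_paired:
                name += "/2" if a.is_read2 else "/1"
            seq = a.query_sequence
            if seq and not a.is_secondary and not a.is_supplementary:
                seqs[name] = revcomp(seq) if a.is_reverse else seq
            L = a.infer_read_length() or (len(seq) if seq else 0)
            qas, qae = a.query_alignment_start, a.query_alignment_end
            if a.cigartuples and a.cigartuples[0][0] == 5:  # leading hard clip
                qas += a.cigartuples[0][1]
                qae += a.cigartuples[0][1]
            if a.is_reverse:
                q_start, q_end = L - qae, L - qas
            else:
                q_start, q_end = qas, qae
            alignments[name].append(
                LocalAlignment(
                    name=name,
                    chrom=a.reference_name or "",
                    ref_start=a.reference_start,
                    ref_end=a.reference_end or a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    q_start=q_start,
                    q_end=q_end,
                    read_len=L,
                    mapq=a.mapping_quality,
                    is_read2=a.is_paired and a.is_read2,
                )
            )
    if own_tmp:
        try:
            os.remove(sam_path)
            os.rmdir(tmpdir)
        except OSError:
            pass
    return dict(alignments), seqs


# ---------------------------------------------------------------------------
# 2map step
# ---------------------------------------------------------------------------

def assign_gene(aln: LocalAlignment, genes: Sequence[TargetRegion]) -> Optional[str]:
    """Longest-overlap gene assignment; ties are dropped (None)."""
    best: Optional[str] = None
    best_ov = 0
    tied = False
    for g in genes:
        if g.chrom != aln.chrom:
            continue
        ov = min(aln.ref_end, g.end) - max(aln.ref_start, g.start)
        if ov <= 0:
            continue
        if ov > best_ov:
            best, best_ov, tied = g.label, ov, False
        elif ov == best_ov:
            tied = True
    return None if tied else best


def _junction_sides(left: LocalAlignment, right: LocalAlignment) -> tuple:
    """Breakpoint coordinate and orientation for the read-left and
    read-right segments of a split read."""
    if left.strand == "+":
        j1 = left.ref_end - 1
        o1 = "+"
    else:
        j1 = left.ref_start
        o1 = "-"
    if right.strand == "+":
        j2 = right.ref_start
        o2 = "-"
    else:
        j2 = right.ref_end - 1
        o2 = "+"
    return (j1, o1), (j2, o2)


def twomap_step(
    alignments_by_name: dict,
    genes: Sequence[TargetRegion],
    user_genes: Sequence[str],
    config: Optional[FusionConfig] = None,
) -> list[FusionCandidate]:
    """Find reads whose left and right portions (each >= min_seg bp) map to
    two different genes; cluster their breakpoints into candidates."""
    cfg = config or FusionConfig()
    if not user_genes:
        raise ValueError("at least one gene of interest must be indicated")
    user = set(user_genes)
    clusters: dict[tuple, list] = defaultdict(list)  # key -> [(pa, pb, dup_key, name)]
    for name, alns in alignments_by_name.items():
        segs = []
        for a in alns:
            if a.q_end - a.q_start < cfg.min_seg:
                continue
            gene = assign_gene(a, genes)
            if gene is None:
                continue
            segs.append((a, gene))
        if len({g for _, g in segs}) > 2:
            continue  # split across three loci: ambiguous, dropped
        if len(segs) < 2:
            continue
        segs.sort(key=lambda t: t[0].q_start)
        left, gl = segs[0]
        right, gr = segs[-1]
        if gl == gr:
            continue
        overlap = left.q_end - right.q_start
        if overlap > cfg.max_seg_overlap:
            continue
        if overlap > 0:
            # microhomology: both halves extend into each other.  Trim the
            # overlap from the left segment so every read of a junction
            # yields the same (equivalent) breakpoint representation.
            left = dataclasses.replace(left)
            if left.strand == "+":
                left.ref_end -= overlap
            else:
                left.ref_start += overlap
            left.q_end -= overlap
        (j1, o1), (j2, o2) = _junction_sides(left, right)
        sides = [(gl, left.chrom, j1, o1), (gr, right.chrom, j2, o2)]
        sides.sort(key=lambda s: (s[0], s[1]))
        (ga, ca, pa, oa), (gb, cb, pb, ob) = sides
        dup_key = (
            min(left.ref_start, right.ref_start),
            max(left.ref_end, right.ref_end),
            left.strand,
        )
        clusters[(ga, ca, oa, gb, cb, ob)].append((pa, pb, dup_key, name))
    candidates: list[FusionCandidate] = []
    for (ga, ca, oa, gb, cb, ob), obs in clusters.items():
        if ga not in user and gb not in user:
            continue
        obs.sort(key=lambda t: (t[0], t[1]))
        current: list = []
        for o in obs:
            if current and (
                abs(o[0] - current[0][0]) > cfg.merge_tol
                or abs(o[1] - current[0][1]) > cfg.merge_tol
            ):
                candidates.append(_make_candidate(ga, ca, oa, gb, cb, ob, current))
                current = []
            current.append(o)
        if current:
            candidates.append(_make_candidate(ga, ca, oa, gb, cb, ob, current))
    return candidates


def _make_candidate(ga, ca, oa, gb, cb, ob, obs) -> FusionCandidate:
    uniq = {}
    for pa, pb, dup_key, name in obs:
        if dup_key not in uniq:
            uniq[dup_key] = (pa, pb, name)
    pairs = [(pa, pb) for pa, pb, _ in uniq.values()]
    # majority vote on the junction among de-duplicated split reads
    vals, counts = np.unique(np.array(pairs), axis=0, return_counts=True)
    pa_mode, pb_mode = (int(v) for v in vals[np.argmax(counts)])
    cand = FusionCandidate(
        gene_a=ga,
        gene_b=gb,
        bp_a=Breakpoint(ca, pa_mode, oa),
        bp_b=Breakpoint(cb, pb_mode, ob),
        split_support=len(uniq),
    )
    # every contributing read name -- including collapsed duplicates -- is
    # claimed, so the VF step cannot re-count the same fragment
    cand.support_read_names = {name for _, _, _, name in obs}
    cand.junction_obs = pairs
    return cand


# ---------------------------------------------------------------------------
# virtual fusion rescue
# ---------------------------------------------------------------------------

def _side_sequence(reference: Fasta, bp: Breakpoint, flank: int, five_prime: bool) -> str:
    contig = reference[bp.chrom]
    n = len(contig)
    if bp.orientation == "+":
        lo = max(0, bp.pos - flank + 1)
        seq = str(contig[lo : bp.pos + 1]).upper()
        return seq if five_prime else revcomp(seq)
    lo = bp.pos
    hi = min(n, bp.pos + flank)
    seq = str(contig[lo:hi]).upper()
    return seq if not five_prime else revcomp(seq)


def build_virtual_fusion(
    cand: FusionCandidate, reference: Fasta, flank: int = 200
) -> str:
    """Construct the junction sequence: ``flank`` bp into gene A up to bp_a
    joined to ``flank`` bp of gene B from bp_b onward, orientations
    respected.  Requires at least one split read."""
    if cand.split_support < 1:
        raise ValueError("virtual fusion requires at least one split read")
    five = _side_sequence(reference, cand.bp_a, flank, five_prime=True)
    three = _side_sequence(reference, cand.bp_b, flank, five_prime=False)
    cand.virtual_ref = five + three
    cand.junction_index = len(five)
    return cand.virtual_ref


def vf_step(
    read_seqs: dict,
    candidates: Sequence[FusionCandidate],
    config: Optional[FusionConfig] = None,
) -> None:
    """Rescue reads missed by 2map: a read counts as VF support when it
    aligns full-length (identity >= vf_min_identity) across the junction of
    exactly one candidate's virtual reference, with at least one base on
    each side.  Ties between candidates are dropped."""
    cfg = config or FusionConfig()
    live = [c for c in candidates if c.virtual_ref]
    if not live:
        return
    assigned = set()
    for c in live:
        assigned |= c.support_read_names
    for name, seq in read_seqs.items():
        if name in assigned or not seq:
            continue
        best: Optional[FusionCandidate] = None
        best_id = cfg.vf_min_identity
        tie = False
        for c in live:
            ident = _junction_identity(seq, c.virtual_ref, c.junction_index)
            if ident is None:
                continue
            if ident > best_id:
                best, best_id, tie = c, ident, False
            elif ident == best_id and best is not None:
                tie = True
        if best is not None and not tie:
            best.vf_support += 1
            best.support_read_names.add(name)


def _junction_identity(seq: str, vref: str, junction: int) -> Optional[float]:
    """Best full-read identity of ``seq`` (either orientation) aligned as an
    infix of the virtual reference, provided the alignment crosses the
    junction with >= 1 base on each side; None when it does not qualify."""
    best = None
    for s in (seq, revcomp(seq)):
        res = edlib.align(s, vref, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0:
            continue
        for start, end in res["locations"]:
            if start is None:
                continue
            if start < junction <= end:  # end is inclusive
                ident = 1.0 - d / max(len(s), 1)
                if best is None or ident > best:
                    best = ident
                break
    return best


# ---------------------------------------------------------------------------
# paired-end evidence
# ---------------------------------------------------------------------------

def paired_end_step(
    alignments_by_name: dict,
    candidates: Sequence[FusionCandidate],
    genes: Sequence[TargetRegion],
    config: Optional[FusionConfig] = None,
) -> None:
    """Count discordant pairs: R1 and R2 mapping to the two genes of a
    candidate (neither read split), each mate within pair_max_dist of the
    corresponding breakpoint on the correct side."""
    cfg = config or FusionConfig()
    by_fragment: dict[str, dict[str, list]] = defaultdict(lambda: {"1": [], "2": []})
    for name, alns in alignments_by_name.items():
        if name.endswith("/1"):
            by_fragment[name[:-2]]["1"] = alns
        elif name.endswith("/2"):
            by_fragment[name[:-2]]["2"] = alns
    for frag, mates in by_fragment.items():
        a1, a2 = mates["1"], mates["2"]
        if len(a1) != 1 or len(a2) != 1:
            continue  # unmapped mate or split mate: not simple pair evidence
        g1, g2 = assign_gene(a1[0], genes), assign_gene(a2[0], genes)
        if g1 is None or g2 is None or g1 == g2:
            continue
        for cand in candidates:
            pair = {cand.gene_a: cand.bp_a, cand.gene_b: cand.bp_b}
            if {g1, g2} != set(pair):
                continue
            if frag + "/1" in cand.support_read_names or frag + "/2" in cand.support_read_names:
                continue
            if _mate_near(a1[0], pair[g1], cfg.pair_max_dist) and _mate_near(
                a2[0], pair[g2], cfg.pair_max_dist
            ):
                cand.pair_support += 1
                cand.support_read_names.update({frag + "/1", frag + "/2"})
            break


def _mate_near(aln: LocalAlignment, bp: Breakpoint, max_dist: int) -> bool:
    if aln.chrom != bp.chrom:
        return False
    if bp.orientation == "+":  # fused side extends upstream of bp
        return aln.ref_end <= bp.pos + 1 and bp.pos + 1 - aln.ref_start <= max_dist
    return aln.ref_start >= bp.pos and aln.ref_end - bp.pos <= max_dist


# ---------------------------------------------------------------------------
# ranking and orchestration
# ---------------------------------------------------------------------------

def rank_candidates(
    candidates: Sequence[FusionCandidate],
    mapped_read_total: int,
    include_pairs: bool = False,
) -> list[FusionCandidate]:
    """Sort by total support (descending); sn_ratio = own support over the
    best other candidate's support (infinity when alone or all others have
    zero support); norm_support = support / all mapped reads."""
    if mapped_read_total <= 0:
        raise ValueError("mapped_read_total must be positive")
    cands = sorted(
        candidates,
        key=lambda c: (-c.total_support(include_pairs), c.gene_a, c.gene_b),
    )
    totals = [c.total_support(include_pairs) for c in cands]
    for i, c in enumerate(cands):
        others = totals[:i] + totals[i + 1 :]
        best_other = max(others) if others else 0
        c.sn_ratio = float("inf") if best_other == 0 else totals[i] / best_other
        c.norm_support = totals[i] / mapped_read_total
    return cands


@dataclasses.dataclass
class FusionResult:
    candidates: list
    mapped_read_total: int


def call_fusions(
    reads: Union[str, Sequence[str]],
    reference_fasta: str,
    genes: Union[str, Sequence[TargetRegion]],
    user_genes: Sequence[str],
    paired: bool = False,
    config: Optional[FusionConfig] = None,
    workdir: Optional[str] = None,
) -> FusionResult:
    """End-to-end fusion calling: local alignment, 2map, VF rescue and, in
    paired-end mode, the paired-end step; candidates returned ranked."""
    cfg = config or FusionConfig()
    gene_regions = load_targets(genes, merge=False) if isinstance(genes, str) else list(genes)
    alignments, seqs = align_local(reads, reference_fasta, cfg, workdir)
    mapped_total = len(alignments)
    candidates = twomap_step(alignments, gene_regions, user_genes, cfg)
    reference = Fasta(reference_fasta)
    for c in candidates:
        build_virtual_fusion(c, reference, cfg.vf_flank)
    vf_step(seqs, candidates, cfg)
    if paired:
        paired_end_step(alignments, candidates, gene_regions, cfg)
    ranked = rank_candidates(candidates, mapped_total, cfg.include_pairs_in_ranking)
    return FusionResult(candidates=ranked, mapped_read_total=mapped_total)


def write_bedpe(result: FusionResult, path: str) -> None:
    cols = (
        "#chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tname\tscore\t"
        "strand_a\tstrand_b\tsplit_support\tvf_support\tpair_support\tsn_ratio\tnorm_support\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in result.candidates:
            sn = "inf" if np.isinf(c.sn_ratio) else f"{c.sn_ratio:.3f}"
            fh.write(
                f"{c.bp_a.chrom}\t{c.bp_a.pos}\t{c.bp_a.pos + 1}\t"
                f"{c.bp_b.chrom}\t{c.bp_b.pos}\t{c.bp_b.pos + 1}\t"
                f"{c.name}\t{c.total_support()}\t{c.bp_a.orientation}\t{c.bp_b.orientation}\t"
                f"{c.split_support}\t{c.vf_support}\t{c.pair_support}\t{sn}\t{c.norm_support:.3g}\n"
            )


def write_virtual_fasta(result: FusionResult, path: str) -> None:
    with open(path, "w") as fh:
        for c in result.candidates:
            if c.virtual_ref:
                fh.write(f">{c.name}|junction={c.junction_index}\n{c.virtual_ref}\n")
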