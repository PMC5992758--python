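"""Input handling for targeted-panel sequencing data.

Loads capture targets (BED), the reference genome (FASTA via pyfaidx) and
aligned reads (SAM/BAM via pysam), and applies the prep filters (mapping- and
base-quality gates) that every caller shares.  Coordinates are 0-based
half-open internally; 1-based only in VCF/SEG output.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class BedParseError(ValueError):
    pass


class BedValidationError(ValueError):
    pass


@dataclasses.dataclass
class TargetRegion:
    """One capture-target interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None
    gc: Optional[float] = None

    def __len__(self) -> int:
        return self.end - self.start


def load_targets(path: str, merge: bool = True) -> list[TargetRegion]:
    """Load a BED file of capture targets.

    Returns regions sorted by (chrom, start); same-chromosome overlapping (or
    book-ended) intervals are merged when ``merge`` is true.  Raises
    :class:`BedParseError` naming the offending line for malformed input and
    :class:`BedValidationError` for empty/inverted intervals.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise BedValidationError(f"{path}:{lineno}: empty or inverted interval {start}-{end}")
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            regions.append(TargetRegion(fields[0], start, end, label))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return merge_regions(regions) if merge else regions


def merge_regions(regions: Sequence[TargetRegion]) -> list[TargetRegion]:
    """Merge overlapping/book-ended same-chromosome regions (idempotent)."""
    merged: list[TargetRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            if r.end > last.end:
                last.end = r.end
            if last.label is None:
                last.label = r.label
        else:
            merged.append(TargetRegion(r.chrom, r.start, r.end, r.label))
    return merged


def total_target_size(regions: Iterable[TargetRegion]) -> int:
    return sum(len(r) for r in regions)


def compute_gc(reference: Fasta, region: TargetRegion) -> Optional[float]:
    """GC fraction of a region: (#G+#C)/(#A+#C+#G+#T); ambiguous bases are
    excluded from the denominator.  Returns None (bin flagged missing) for an
    all-ambiguous region; raises for coordinates off the contig."""
    contig = reference[region.chrom]
    if region.start < 0 or region.end > len(contig):
        raise IndexError(
            f"region {region.chrom}:{region.start}-{region.end} outside contig (len {len(contig)})"
        )
    codes = encode_bases(str(contig[region.start : region.end]))
    n_valid = int((codes < 4).sum())
    if n_valid == 0:
        return None
    n_gc = int(((codes == 1) | (codes == 2)).sum())
    return n_gc / n_valid


@dataclasses.dataclass
class ReadRecord:
    """A single aligned read, decoupled from the underlying pysam object."""

    name: str
    chrom: str
    pos: int  # 0-based leftmost aligned reference bp
    mapq: int
    is_reverse: bool
    cigar: list[tuple[int, int]]  # (op, length) with pysam op codes
    codes: np.ndarray  # uint8 base codes, read (query) order as stored
    quals: np.ndarray  # uint8 Phred scores
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    is_paired: bool = False
    is_read2: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_is_reverse: bool = False

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.quals):
            raise ValueError(f"read {self.name}: bases/quals length mismatch")

    @property
    def query_length(self) -> int:
        return len(self.codes)

    def reference_end(self) -> int:
        end = self.pos
        for op, length in self.cigar:
            if op in (0, 2, 3, 7, 8):  # M, D, N, =, X consume reference
                end += length
        return end


def _from_pysam(a: pysam.AlignedSegment) -> ReadRecord:
    quals = a.query_qualities
    return ReadRecord(
        name=a.query_name or "",
        chrom=a.reference_name or "",
        pos=a.reference_start if a.reference_start is not None else -1,
        mapq=a.mapping_quality,
        is_reverse=a.is_reverse,
        cigar=list(a.cigartuples or []),
        codes=encode_bases(a.query_sequence or ""),
        quals=np.asarray(quals, dtype=np.uint8) if quals is not None else np.zeros(0, np.uint8),
        is_duplicate=a.is_duplicate,
        is_secondary=a.is_secondary,
        is_supplementary=a.is_supplementary,
        is_unmapped=a.is_unmapped,
        is_paired=a.is_paired,
        is_read2=a.is_paired and a.is_read2,
        mate_chrom=a.next_reference_name if a.is_paired and not a.mate_is_unmapped else None,
        mate_pos=a.next_reference_start if a.is_paired and not a.mate_is_unmapped else None,
        mate_is_reverse=a.mate_is_reverse if a.is_paired else False,
    )


def read_alignments(path: str) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a SAM or BAM file (auto-detected by pysam)."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            yield _from_pysam(a)


def prep_filter(
    reads: Iterable[ReadRecord],
    min_mapq: int = 20,
    min_baseq: int = 20,
    drop_duplicates: bool = True,
    mq0_spans: Optional[list] = None,
) -> Iterator[tuple[ReadRecord, np.ndarray]]:
    """Prep filters: gate reads on mapping quality and mask low-quality bases.

    Yields (read, baseq_mask) pairs where ``baseq_mask`` is True for bases
    whose quality passes ``min_baseq``.  Unmapped, secondary, supplementary
    and (optionally) duplicate records are dropped.  Reads with mapping
    quality 0 are excluded from counting but their (chrom, start, end) spans
    are appended to ``mq0_spans`` so the MQ0 filter can tally ambiguous
    coverage per site.  Reads with 0 < mapq < min_mapq are silently dropped.
    """
    if min_mapq < 0 or min_baseq < 0:
        raise ValueError("quality thresholds must be non-negative")
    for r in reads:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        if drop_duplicates and r.is_duplicate:
            continue
        if r.mapq == 0:
            if mq0_spans is not None:
                mq0_spans.append((r.chrom, r.pos, r.reference_end()))
            continue
        if r.mapq < min_mapq:
            continue
        yield r, r.quals >= min_baseq
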