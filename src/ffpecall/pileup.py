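"""Per-position pileups over capture targets.

Builds, for every target base, strand-split allele counts (A/C/G/T plus
``ins:<seq>`` / ``del:<len>`` keys anchored at the base preceding the event,
left-aligned), MQ0 coverage tallies, and the per-supporting-read context the
noise filters consume: distance of each call from the nearer read end, the
number of additional non-reference mismatches elsewhere on the read, the base
quality of the call and, for indels, mean base quality up/downstream of the
event.

Counting convention: a read whose alignment carries an indel keyed at a
column contributes only the indel allele there (not also its base call), so
the per-column allele-count sum never exceeds the number of overlapping
reads.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np
from pyfaidx import Fasta

from .core_io import BASES, ReadRecord, TargetRegion, encode_bases


class CallContext(NamedTuple):
    """Read-level context of one supporting (non-reference) call."""

    strand: int  # 0 forward, 1 reverse
    end_dist: int  # distance (bp) of the call from the nearer read end
    extra_mm: int  # non-reference mismatches elsewhere on the read
    baseq: int
    bq_up: float  # indels only: mean BQ upstream of the event (else nan)
    bq_down: float


@dataclasses.dataclass
class PileupColumn:
    """Allele/strand/quality/context tallies at one reference position."""

    chrom: str
    pos: int
    ref_base: str
    counts: dict  # allele key -> np.ndarray([fwd, rev])
    mq0_count: int = 0
    masked_count: int = 0
    end_depth: int = 0  # calls (any allele) within end_window of a read end
    trim_depth: int = 0  # calls within trim_window of a read end
    contexts: dict = dataclasses.field(default_factory=dict)

    @property
    def depth(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def count(self, allele: str) -> int:
        c = self.counts.get(allele)
        return int(c.sum()) if c is not None else 0

    def strand_counts(self, allele: str) -> tuple[int, int]:
        c = self.counts.get(allele)
        return (int(c[0]), int(c[1])) if c is not None else (0, 0)


class UnsortedInputError(ValueError):
    pass


def left_align_indel(ref_codes: np.ndarray, pos: int, kind: str, seq: np.ndarray) -> tuple[int, np.ndarray]:
    """Left-align an indel event within a reference code array.

    ``pos`` is the 0-based array index of the first deleted base (kind
    'del') or of the base after which the insertion occurs plus one, i.e. the
    insertion point (kind 'ins').  Returns the shifted (pos, seq).
    """
    seq = seq.copy()
    while pos > 0:
        if kind == "del":
            if ref_codes[pos - 1] == ref_codes[pos + len(seq) - 1]:
                pos -= 1
                seq = ref_codes[pos : pos + len(seq)].copy()
            else:
                break
        else:
            if ref_codes[pos - 1] == seq[-1]:
                seq = np.concatenate(([ref_codes[pos - 1]], seq[:-1]))
                pos -= 1
            else:
                break
    return pos, seq


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


class Pileup:
    """Dense per-target pileup matrices with sparse indel/context side tables."""

    def __init__(
        self,
        targets: list[TargetRegion],
        reference: Fasta,
        end_window: int = 5,
        trim_window: int = 5,
    ) -> None:
        self.targets = targets
        self.reference = reference
        self.end_window = end_window
        self.trim_window = trim_window
        self._chrom_regions: dict[str, list[tuple[int, int, int]]] = {}
        offset = 0
        self._region_offsets: list[int] = []
        for r in targets:
            self._chrom_regions.setdefault(r.chrom, []).append((r.start, r.end, offset))
            self._region_offsets.append(offset)
            offset += len(r)
        self.size = offset
        self.ref_codes = np.zeros(self.size, dtype=np.uint8)
        for r, off in zip(targets, self._region_offsets):
            self.ref_codes[off : off + len(r)] = encode_bases(str(reference[r.chrom][r.start : r.end]))
        # counts[i, base, strand]
        self.base_counts = np.zeros((self.size, 4, 2), dtype=np.uint32)
        self.mq0 = np.zeros(self.size, dtype=np.uint32)
        self.masked = np.zeros(self.size, dtype=np.uint32)
        self.end_depth = np.zeros(self.size, dtype=np.uint32)
        self.trim_depth = np.zeros(self.size, dtype=np.uint32)
        self.indel_counts: dict[int, dict[str, np.ndarray]] = {}
        self.contexts: dict[int, dict[str, list[CallContext]]] = {}
        self.n_reads = 0
        self.total_aligned_bases = 0
        self._last_pos: dict[str, int] = {}

    # -- coordinate helpers -------------------------------------------------
    def flat_index(self, chrom: str, pos: int) -> Optional[int]:
        regions = self._chrom_regions.get(chrom)
        if not regions:
            return None
        idx = bisect_right(regions, (pos, np.inf, np.inf)) - 1
        if idx < 0:
            return None
        start, end, off = regions[idx]
        if start <= pos < end:
            return off + pos - start
        return None

    def _overlaps(self, chrom: str, start: int, end: int) -> list[tuple[int, int, int]]:
        regions = self._chrom_regions.get(chrom, [])
        out = []
        for rs, re, off in regions:
            if rs < end and start < re:
                out.append((rs, re, off))
        return out

    @property
    def mean_read_length(self) -> float:
        return self.total_aligned_bases / self.n_reads if self.n_reads else 0.0

    # -- accumulation -------------------------------------------------------
    def add_mq0_spans(self, spans: Iterable[tuple[str, int, int]]) -> None:
        for chrom, start, end in spans:
            for rs, re, off in self._overlaps(chrom, start, end):
                lo, hi = max(start, rs), min(end, re)
                self.mq0[off + lo - rs : off + hi - rs] += 1

    def add_read(self, read: ReadRecord, baseq_mask: Optional[np.ndarray] = None) -> None:
        last = self._last_pos.get(read.chrom)
        if last is not None and read.pos < last:
            raise UnsortedInputError(
                f"input not coordinate-sorted at {read.chrom}:{read.pos}; sort the alignment first"
            )
        self._last_pos[read.chrom] = read.pos
        if baseq_mask is None:
            baseq_mask = np.ones(read.query_length, dtype=bool)
        L = read.query_length
        self.n_reads += 1

        # walk the CIGAR, collecting aligned (query, ref) blocks and indels
        blocks: list[tuple[int, int, int]] = []  # (qstart, rstart, length)
        indels: list[tuple[str, int, int, int]] = []  # (kind, qpos, rpos, length)
        q = r = 0
        rpos0 = read.pos
        for op, length in read.cigar:
            if op in (0, 7, 8):
                blocks.append((q, rpos0 + r, length))
                q += length
                r += length
            elif op == 1:
                indels.append(("ins", q, rpos0 + r, length))
                q += length
            elif op == 2:
                indels.append(("del", q, rpos0 + r, length))
                r += length
            elif op == 3:
                r += length
            elif op == 4:
                q += length

        strand = 1 if read.is_reverse else 0
        skip_base_at: set[int] = set()  # flat indices owned by an indel allele
        indel_records: list[tuple[int, str, int]] = []  # (flat, key, qpos)

        for kind, qpos, rpos, length in indels:
            if kind == "del":
                fi = self.flat_index(read.chrom, rpos)
                if fi is None:
                    continue
                seq = self.ref_codes[fi : fi + length]
                if len(seq) < length:
                    continue
                la_pos, seq = left_align_indel(self.ref_codes, fi, "del", seq)
                key = f"del:{length}"
                anchor = la_pos - 1
            else:
                fi = self.flat_index(read.chrom, rpos)
                if fi is None:
                    continue
                seq = read.codes[qpos : qpos + length]
                la_pos, seq = left_align_indel(self.ref_codes, fi, "ins", seq)
                key = f"ins:{_codes_to_str(seq)}"
                anchor = la_pos - 1
            if anchor < 0:
                continue
            skip_base_at.add(anchor)
            indel_records.append((anchor, key, qpos))

        mm_flats: list[int] = []
        mm_quals: list[int] = []
        mm_qidx: list[int] = []
        for qstart, rstart, length in blocks:
            for rs, re, off in self._overlaps(read.chrom, rstart, rstart + length):
                lo = max(rstart, rs)
                hi = min(rstart + length, re)
                qs = qstart + (lo - rstart)
                n = hi - lo
                codes = read.codes[qs : qs + n]
                quals_ok = baseq_mask[qs : qs + n]
                flat = off + lo - rs
                valid = quals_ok & (codes < 4)
                self.masked[flat : flat + n] += (~quals_ok).astype(np.uint32)
                if skip_base_at:
                    keep = np.ones(n, dtype=bool)
                    for a in skip_base_at:
                        if flat <= a < flat + n:
                            keep[a - flat] = False
                    valid = valid & keep
                idx = np.nonzero(valid)[0]
                if idx.size:
                    fpos = flat + idx
                    np.add.at(self.base_counts, (fpos, codes[idx], strand), 1)
                    qq = qs + idx
                    dist = np.minimum(qq, L - 1 - qq)
                    self.end_depth[fpos[dist < self.end_window]] += 1
                    self.trim_depth[fpos[dist < self.trim_window]] += 1
                    mism = codes[idx] != self.ref_codes[fpos]
                    if mism.any():
                        mm_flats.extend(fpos[mism].tolist())
                        mm_quals.extend(read.quals[qq[mism]].tolist())
                        mm_qidx.extend(qq[mism].tolist())
                self.total_aligned_bases += n

        n_mm = len(mm_flats)
        n_events = n_mm + len(indel_records)
        for fi_, bq, qi in zip(mm_flats, mm_quals, mm_qidx):
            key = BASES[int(read.codes[qi])]
            ctx = CallContext(
                strand=strand,
                end_dist=int(min(qi, L - 1 - qi)),
                extra_mm=n_mm - 1,
                baseq=int(bq),
                bq_up=float("nan"),
                bq_down=float("nan"),
            )
            self.contexts.setdefault(fi_, {}).setdefault(key, []).append(ctx)
        for anchor, key, qpos in indel_records:
            self.indel_counts.setdefault(anchor, {}).setdefault(key, np.zeros(2, dtype=np.int64))[strand] += 1
            up = read.quals[:qpos]
            down = read.quals[qpos:]
            ctx = CallContext(
                strand=strand,
                end_dist=int(min(qpos, L - 1 - qpos)),
                extra_mm=n_mm,
                baseq=int(read.quals[qpos]) if qpos < L else 0,
                bq_up=float(up.mean()) if up.size else float("nan"),
                bq_down=float(down.mean()) if down.size else float("nan"),
            )
            self.contexts.setdefault(anchor, {}).setdefault(key, []).append(ctx)

    def add_reads(self, stream: Iterable) -> None:
        """Consume a prep-filtered stream of (read, mask) pairs or bare reads."""
        for item in stream:
            if isinstance(item, ReadRecord):
                self.add_read(item)
            else:
                self.add_read(item[0], item[1])

    # -- access -------------------------------------------------------------
    def column_at(self, flat: int) -> PileupColumn:
        chrom, pos = self.locate(flat)
        counts: dict[str, np.ndarray] = {}
        for b in range(4):
            sc = self.base_counts[flat, b]
            if sc.sum():
                counts[BASES[b]] = sc.astype(np.int64)
        for key, sc in self.indel_counts.get(flat, {}).items():
            counts[key] = sc
        return PileupColumn(
            chrom=chrom,
            pos=pos,
            ref_base=BASES[self.ref_codes[flat]] if self.ref_codes[flat] < 4 else "N",
            counts=counts,
            mq0_count=int(self.mq0[flat]),
            masked_count=int(self.masked[flat]),
            end_depth=int(self.end_depth[flat]),
            trim_depth=int(self.trim_depth[flat]),
            contexts=self.contexts.get(flat, {}),
        )

    def column(self, chrom: str, pos: int) -> Optional[PileupColumn]:
        fi = self.flat_index(chrom, pos)
        return self.column_at(fi) if fi is not None else None

    def locate(self, flat: int) -> tuple[str, int]:
        idx = bisect_right(self._region_offsets, flat) - 1
        r = self.targets[idx]
        return r.chrom, r.start + (flat - self._region_offsets[idx])

    def columns(self, min_depth: int = 1) -> Iterator[PileupColumn]:
        depth = self.base_counts.sum(axis=(1, 2))
        for flat in np.nonzero(depth >= min_depth)[0]:
            yield self.column_at(int(flat))


def build_pileups(
    filtered_reads: Iterable,
    targets: list[TargetRegion],
    reference: Fasta,
    end_window: int = 5,
    trim_window: int = 5,
    mq0_spans: Optional[Iterable[tuple[str, int, int]]] = None,
) -> Pileup:
    """Build a :class:`Pileup` from a prep-filtered, coordinate-sorted stream."""
    pp = Pileup(targets, reference, end_window=end_window, trim_window=trim_window)
    pp.add_reads(filtered_reads)
    if mq0_spans is not None:
        pp.add_mq0_spans(mq0_spans)
    return pp
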