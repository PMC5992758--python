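"""Copy-number alteration calling from tumor-vs-control read depth.

Pipeline: bin per-base depth over capture targets, correct GC bias by LOWESS
regression of binned depth on GC content, form the per-bin
logR = log2(tumor corrected / control corrected) series (median-centred,
assuming a majority-neutral panel), segment each chromosome with circular
binary segmentation driven by a standardized Mann-Whitney rank statistic and
a permutation test (computed within fixed-size windows for speed, then
compiled to chromosome-scale segments), abort segments whose individual logR
values fluctuate excessively around the segment median, and classify the
surviving segments as AMP / DEL / NEUTRAL with a bootstrap interval of the
segment median.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import TargetRegion, compute_gc


@dataclasses.dataclass
class DepthBin:
    chrom: str
    start: int
    end: int
    gc: Optional[float]
    raw_depth: float
    corrected_depth: Optional[float] = None
    masked: bool = False
    gc_flagged: bool = False  # gc outside the central mass of the panel


@dataclasses.dataclass
class LogRSeries:
    """Per-bin log2 tumor/control depth ratios over unmasked bins."""

    bins: list  # DepthBin (tumor-side geometry)
    logr: np.ndarray
    center_offset: float = 0.0

    def chrom_indices(self) -> dict:
        out: dict[str, list[int]] = {}
        for i, b in enumerate(self.bins):
            out.setdefault(b.chrom, []).append(i)
        return out


@dataclasses.dataclass
class Segment:
    chrom: str
    start: int
    end: int
    bin_start: int  # index into the LogRSeries
    bin_end: int  # exclusive
    bin_count: int
    median_logr: float
    aborted: bool = False
    boot_low: Optional[float] = None
    boot_high: Optional[float] = None
    state: str = "NEUTRAL"


# ---------------------------------------------------------------------------
# binning and GC correction
# ---------------------------------------------------------------------------

def bin_depths(
    coverage: dict,
    targets: Sequence[TargetRegion],
    bin_size: int,
    reference=None,
) -> list[DepthBin]:
    """Split each target into bins of <= bin_size bp; ``coverage`` maps chrom
    to a per-base depth array indexed from position 0 (or per-region arrays
    via (chrom, start) keys)."""
    bins: list[DepthBin] = []
    for r in targets:
        cov = coverage.get(r.chrom)
        for s in range(r.start, r.end, bin_size):
            e = min(s + bin_size, r.end)
            raw = float(cov[s:e].mean()) if cov is not None else 0.0
            gc = compute_gc(reference, TargetRegion(r.chrom, s, e)) if reference is not None else None
            bins.append(DepthBin(r.chrom, s, e, gc, raw, masked=raw == 0.0 or gc is None))
    return bins


def coverage_from_reads(reads: Iterable, targets: Sequence[TargetRegion]) -> dict:
    """Per-base coverage arrays (one per chromosome, spanning its targets)."""
    spans: dict[str, int] = {}
    for r in targets:
        spans[r.chrom] = max(spans.get(r.chrom, 0), r.end)
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in spans.items()}
    for read in reads:
        arr = cov.get(read.chrom)
        if arr is None:
            continue
        s = max(read.pos, 0)
        e = min(read.reference_end(), len(arr))
        if e > s:
            arr[s] += 1
            if e < len(arr):
                arr[e] -= 1
    return {c: np.cumsum(a) for c, a in cov.items()}


class TooFewBinsError(ValueError):
    pass


def lowess_gc_correct(
    bins: Sequence[DepthBin],
    span: float = 0.5,
    min_bins: int = 50,
    gc_flag_quantiles: tuple[float, float] = (0.01, 0.99),
) -> list[DepthBin]:
    """LOWESS-correct depth for GC bias: corrected = raw * median / fitted(gc).

    Bins whose GC lies outside the central mass of the panel's GC
    distribution are flagged (correction there is poorly supported -- high-GC
    bins in particular are a known weak spot of depth-based CNA calling on
    small panels).  Raises TooFewBinsError below ``min_bins`` usable bins;
    disable correction rather than extrapolating from a handful of points.
    """
    usable = [b for b in bins if not b.masked and b.gc is not None]
    if len(usable) < min_bins:
        raise TooFewBinsError(
            f"{len(usable)} unmasked bins < {min_bins}; disable GC correction for this panel"
        )
    gc = np.array([b.gc for b in usable])
    raw = np.array([b.raw_depth for b in usable])
    fitted = lowess(raw, gc, frac=span, return_sorted=False)
    med = float(np.median(raw))
    qlo, qhi = np.quantile(gc, gc_flag_quantiles)
    for b, f in zip(usable, fitted):
        if f <= 0 or not np.isfinite(f):
            b.masked = True
            b.corrected_depth = None
        else:
            b.corrected_depth = b.raw_depth * med / f
        b.gc_flagged = not (qlo <= b.gc <= qhi)
    for b in bins:
        if b.masked and b.corrected_depth is None:
            b.corrected_depth = None
    return list(bins)


def compute_logr(tumor_bins: Sequence[DepthBin], control_bins: Sequence[DepthBin]) -> LogRSeries:
    """log2(tumor corrected / control corrected) per bin, median-centred.
    Bins masked in either sample (or with non-positive corrected depth) are
    excluded."""
    if len(tumor_bins) != len(control_bins):
        raise ValueError("tumor/control binning mismatch")
    kept = []
    values = []
    for t, c in zip(tumor_bins, control_bins):
        if (t.chrom, t.start, t.end) != (c.chrom, c.start, c.end):
            raise ValueError("tumor/control binning mismatch")
        td = t.corrected_depth if t.corrected_depth is not None else t.raw_depth
        cd = c.corrected_depth if c.corrected_depth is not None else c.raw_depth
        if t.masked or c.masked or td is None or cd is None or td <= 0 or cd <= 0:
            continue
        kept.append(t)
        values.append(np.log2(td / cd))
    logr = np.asarray(values)
    offset = float(np.median(logr)) if len(logr) else 0.0
    return LogRSeries(bins=kept, logr=logr - offset, center_offset=offset)


# ---------------------------------------------------------------------------
# CBS with a Mann-Whitney statistic
# ---------------------------------------------------------------------------

def _max_arc_stat(ranks: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal standardized Mann-Whitney rank statistic over all arcs (i, j]
    of the circularized sequence whose resulting pieces respect min_width.
    Returns (stat, i, j)."""
    n = len(ranks)
    S = np.concatenate(([0.0], np.cumsum(ranks)))
    best = (0.0, 0, n)
    for L in range(min_width, n - min_width + 1):
        rs = S[L:] - S[: n - L + 1]
        i = np.arange(n - L + 1)
        valid = ((i == 0) | (i >= min_width)) & ((i + L == n) | (n - (i + L) >= min_width))
        if not valid.any():
            continue
        mean = L * (n + 1) / 2.0
        var = L * (n - L) * (n + 1) / 12.0
        if var <= 0:
            continue
        z = (np.abs(rs - mean) - 0.5) / np.sqrt(var)
        z[~valid] = -np.inf
        k = int(np.argmax(z))
        if z[k] > best[0]:
            best = (float(z[k]), k, k + L)
    return best


def _perm_max_stats(
    ranks: np.ndarray, min_width: int, n_perm: int, rng: np.random.Generator, chunk: int = 250
) -> np.ndarray:
    n = len(ranks)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
        S = np.concatenate([np.zeros((m, 1)), np.cumsum(perm, axis=1)], axis=1)
        best = np.zeros(m)
        for L in range(min_width, n - min_width + 1):
            rs = S[:, L:] - S[:, : n - L + 1]
            i = np.arange(n - L + 1)
            valid = ((i == 0) | (i >= min_width)) & ((i + L == n) | (n - (i + L) >= min_width))
            if not valid.any():
                continue
            mean = L * (n + 1) / 2.0
            var = L * (n - L) * (n + 1) / 12.0
            z = (np.abs(rs[:, valid] - mean) - 0.5) / np.sqrt(var)
            best = np.maximum(best, z.max(axis=1))
        out[done : done + m] = best
        done += m
    return out


def _segment_recursive(
    x: np.ndarray,
    lo: int,
    hi: int,
    n_perm: int,
    alpha: float,
    min_width: int,
    rng: np.random.Generator,
    out: list,
) -> None:
    n = hi - lo
    if n < 2 * min_width:
        out.append((lo, hi))
        return
    seg = x[lo:hi]
    if np.allclose(seg, seg[0]):
        out.append((lo, hi))  # zero-variance: the U statistic is undefined, never split
        return
    ranks = rankdata(seg)
    stat, i, j = _max_arc_stat(ranks, min_width)
    if stat <= 0:
        out.append((lo, hi))
        return
    perm = _perm_max_stats(ranks, min_width, n_perm, rng)
    p = (1.0 + float((perm >= stat).sum())) / (1.0 + n_perm)
    if p > alpha:
        out.append((lo, hi))
        return
    cuts = [c for c in (i, j) if 0 < c < n]
    if not cuts:
        out.append((lo, hi))
        return
    bounds = [0] + cuts + [n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        _segment_recursive(x, lo + a, lo + b, n_perm, alpha, min_width, rng, out)


def cbs_segment(
    values: np.ndarray,
    window_size: int = 500,
    n_perm: int = 1000,
    alpha_seg: float = 0.01,
    min_width: int = 3,
    rng: Optional[np.random.Generator] = None,
    undo_sd: float = 1.5,
) -> list[tuple[int, int]]:
    """Segment one chromosome's logR values.  The sequence is cut into
    windows of ``window_size`` bins, CBS runs within each window, the
    per-window results are compiled back into chromosome-scale segments,
    splits whose level difference is below ``undo_sd`` noise standard
    deviations are undone, and the surviving boundaries are re-localized."""
    rng = rng or np.random.default_rng(0)
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if n < min_width:
        return [(0, n)]
    window_segs: list[list[tuple[int, int]]] = []
    for ws in range(0, n, window_size):
        we = min(ws + window_size, n)
        segs: list[tuple[int, int]] = []
        _segment_recursive(x, ws, we, n_perm, alpha_seg, min_width, rng, segs)
        window_segs.append(sorted(segs))
    compiled = compile_windows(window_segs, x, alpha_seg)
    refined = refine_boundaries(compiled, x, min_width)
    undone = undo_small_splits(refined, x, undo_sd)
    return refine_boundaries(undone, x, min_width)


def _noise_sd(x: np.ndarray) -> float:
    """Robust per-bin noise scale from median absolute first differences."""
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def undo_small_splits(
    segments: Sequence[tuple[int, int]], values: np.ndarray, undo_sd: float = 1.5
) -> list[tuple[int, int]]:
    """Merge adjacent segments whose medians differ by less than
    ``undo_sd`` times the robust noise SD -- permutation splitting alone
    over-segments long noisy stretches under recursion."""
    segs = sorted(segments)
    if undo_sd <= 0 or len(segs) < 2:
        return segs
    sigma = _noise_sd(values)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        diffs = [
            abs(
                float(np.median(values[a:b])) - float(np.median(values[b:c]))
            )
            for (a, b), (_, c) in zip(segs[:-1], segs[1:])
        ]
        k = int(np.argmin(diffs))
        if diffs[k] < undo_sd * sigma:
            segs[k] = (segs[k][0], segs[k + 1][1])
            del segs[k + 1]
            changed = True
    return segs


def refine_boundaries(
    segments: Sequence[tuple[int, int]], values: np.ndarray, min_width: int = 3
) -> list[tuple[int, int]]:
    """Relocate each internal boundary to the cut maximizing the two-sample
    Mann-Whitney statistic between the two flanking segments.  The global
    arc search localizes imprecisely when a window holds more than two
    levels; re-optimizing each boundary against only its two neighbours
    sharpens it."""
    segs = sorted(segments)
    for it in range(len(segs)):  # one sweep is enough in practice; bounded anyway
        moved = False
        for k in range(len(segs) - 1):
            lo = segs[k][0]
            hi = segs[k + 1][1]
            x = values[lo:hi]
            n = len(x)
            if n < 2 * min_width:
                continue
            ranks = rankdata(x)
            S = np.concatenate(([0.0], np.cumsum(ranks)))
            m = np.arange(min_width, n - min_width + 1)
            rs = S[m]
            mean = m * (n + 1) / 2.0
            var = m * (n - m) * (n + 1) / 12.0
            z = np.abs(rs - mean) / np.sqrt(var)
            best = int(m[np.argmax(z)])
            new_b = lo + best
            if new_b != segs[k][1]:
                segs[k] = (segs[k][0], new_b)
                segs[k + 1] = (new_b, segs[k + 1][1])
                moved = True
        if not moved:
            break
    return segs


def compile_windows(
    window_segs: Sequence[Sequence[tuple[int, int]]],
    values: np.ndarray,
    alpha_seg: float = 0.01,
) -> list[tuple[int, int]]:
    """Merge adjacent terminal segments of neighbouring windows when a
    Mann-Whitney test finds no evidence their levels differ."""
    merged: list[tuple[int, int]] = []
    for segs in window_segs:
        for s_idx, seg in enumerate(sorted(segs)):
            if (
                s_idx == 0
                and merged
                and merged[-1][1] == seg[0]
                and not _levels_differ(
                    values[merged[-1][0] : merged[-1][1]],
                    values[seg[0] : seg[1]],
                    alpha_seg,
                )
            ):
                merged[-1] = (merged[-1][0], seg[1])
            else:
                merged.append(seg)
    return merged


def _levels_differ(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    if len(a) == 0 or len(b) == 0:
        return False
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return False
    try:
        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    except ValueError:
        return False
    return p <= alpha


# ---------------------------------------------------------------------------
# abortion and bootstrap classification
# ---------------------------------------------------------------------------

def abort_segments(
    segments: Sequence[Segment],
    logr: np.ndarray,
    dev_delta: float = 0.5,
    dev_frac: float = 0.3,
) -> list[Segment]:
    """Abort segments whose individual logR values deviate from the segment
    median (|logr - median| > dev_delta) in more than a dev_frac fraction of
    bins.  Single-bin segments are never aborted (the fraction rule is
    vacuous there)."""
    for seg in segments:
        vals = logr[seg.bin_start : seg.bin_end]
        if len(vals) < 2:
            seg.aborted = False
            continue
        frac = float((np.abs(vals - np.median(vals)) > dev_delta).mean())
        seg.aborted = frac > dev_frac
        if seg.aborted:
            seg.state = "ABORTED"
    return list(segments)


def bootstrap_classify(
    seg: Segment,
    logr: np.ndarray,
    n_boot: int = 1000,
    amp_logr: float = 0.8,
    del_logr: float = -0.8,
    conf: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Bootstrap the segment median; AMP if the lower confidence bound clears
    amp_logr, DEL if the upper bound sits below del_logr, else NEUTRAL."""
    if seg.aborted:
        return "ABORTED"
    rng = rng or np.random.default_rng(0)
    vals = logr[seg.bin_start : seg.bin_end]
    if len(vals) < 3:
        seg.state = "NEUTRAL"
        seg.boot_low = seg.boot_high = None
        return seg.state
    meds = np.median(rng.choice(vals, size=(n_boot, len(vals)), replace=True), axis=1)
    lo = float(np.quantile(meds, (1 - conf) / 2))
    hi = float(np.quantile(meds, 1 - (1 - conf) / 2))
    seg.boot_low, seg.boot_high = lo, hi
    if lo > amp_logr:
        seg.state = "AMP"
    elif hi < del_logr:
        seg.state = "DEL"
    else:
        seg.state = "NEUTRAL"
    return seg.state


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CnaConfig:
    bin_size: int = 100
    lowess_span: float = 0.5
    lowess_min_bins: int = 50
    gc_correct: bool = True
    window_size: int = 500
    n_perm: int = 1000
    alpha_seg: float = 0.01
    min_width: int = 3
    undo_sd: float = 1.5
    dev_delta: float = 0.5
    dev_frac: float = 0.3
    n_boot: int = 1000
    amp_logr: float = 0.8
    del_logr: float = -0.8
    conf: float = 0.95
    seed: int = 0


def call_cnas(
    tumor_bins: Sequence[DepthBin],
    control_bins: Sequence[DepthBin],
    config: Optional[CnaConfig] = None,
) -> tuple[list[Segment], LogRSeries]:
    """GC-correct both samples, build the logR series and run segmentation,
    abortion and bootstrap classification."""
    cfg = config or CnaConfig()
    rng = np.random.default_rng(cfg.seed)
    if cfg.gc_correct:
        lowess_gc_correct(tumor_bins, cfg.lowess_span, cfg.lowess_min_bins)
        lowess_gc_correct(control_bins, cfg.lowess_span, cfg.lowess_min_bins)
    series = compute_logr(tumor_bins, control_bins)
    segments: list[Segment] = []
    for chrom, idxs in series.chrom_indices().items():
        idx0 = idxs[0]
        vals = series.logr[idx0 : idxs[-1] + 1]
        for s, e in cbs_segment(
            vals, cfg.window_size, cfg.n_perm, cfg.alpha_seg, cfg.min_width, rng,
            undo_sd=cfg.undo_sd,
        ):
            bs, be = idx0 + s, idx0 + e
            segments.append(
                Segment(
                    chrom=chrom,
                    start=series.bins[bs].start,
                    end=series.bins[be - 1].end,
                    bin_start=bs,
                    bin_end=be,
                    bin_count=be - bs,
                    median_logr=float(np.median(series.logr[bs:be])),
                )
            )
    abort_segments(segments, series.logr, cfg.dev_delta, cfg.dev_frac)
    for seg in segments:
        bootstrap_classify(
            seg, series.logr, cfg.n_boot, cfg.amp_logr, cfg.del_logr, cfg.conf, rng
        )
    return segments, series


def write_seg(segments: Sequence[Segment], path: str, sample: str = "tumor", seed: Optional[int] = None) -> None:
    """SEG-style tab table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        fh.write(
            "sample\tchrom\tstart\tend\tbin_count\tmedian_logr\tstate\tboot_low\tboot_high\taborted\n"
        )
        for s in segments:
            lo = "" if s.boot_low is None else f"{s.boot_low:.4f}"
            hi = "" if s.boot_high is None else f"{s.boot_high:.4f}"
            fh.write(
                f"{sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.bin_count}\t"
                f"{s.median_logr:.4f}\t{s.state}\t{lo}\t{hi}\t{int(s.aborted)}\n"
            )


def write_bins(series: LogRSeries, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgc\traw\tcorrected\tlogr\tgc_flagged\n")
        for b, lr in zip(series.bins, series.logr):
            gc = "" if b.gc is None else f"{b.gc:.4f}"
            cd = "" if b.corrected_depth is None else f"{b.corrected_depth:.2f}"
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{gc}\t{b.raw_depth:.2f}\t{cd}\t"
                f"{lr:.4f}\t{int(b.gc_flagged)}\n"
            )
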