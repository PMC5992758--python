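"""SNV/indel calling from tumor-vs-control pileups.

Candidates are extracted with a one-sided Fisher's exact test comparing
tumor against control allele counts at every target position (a
non-parametric choice: no assumptions on Phred calibration or error rates,
which differ between FFPE and frozen material).  Extracted candidates then
pass through a cascade of noise filters driven by statistical tests and
internal controls (error rates estimated from the data itself):

  set 1: misalignment, strand-bias, within-long-homopolymer, MQ0,
         read-end-call, surrounded-by-dust and, for Ion-platform indels
         only, abnormal-BQ-drop;
  set 2: a second Fisher test after removing mismatch-laden reads and
         trimming read ends;
  set 3: the VAF-lees beta-mixture/beta-binomial test (see
         :mod:`ffpecall.betamix`).

A germline VAF-band/SNP-database filter follows for the unmatched-control
setting.  There is no hard VAF cutoff anywhere in the cascade.  All set-1
verdicts are evaluated unconditionally (no short-circuiting), so a
candidate's PASS/FAIL state does not depend on the order of set-1 filters.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam
from pyfaidx import Fasta
from scipy.stats import binom, hypergeom, poisson

from .betamix import BetaMixtureModel, beta_binomial_sf, fit_beta_mixture
from .core_io import TargetRegion, prep_filter, read_alignments
from .pileup import Pileup, PileupColumn, build_pileups

SET1_FILTERS_ILLUMINA = ("misalignment", "strand_bias", "homopolymer", "mq0", "read_end", "dust")
SET1_FILTERS_ION = SET1_FILTERS_ILLUMINA + ("bq_drop",)


def noise_filter_names(platform: str = "illumina") -> tuple[str, ...]:
    """Ordered noise-filter cascade; 8 filters for Illumina, 9 for Ion."""
    set1 = SET1_FILTERS_ION if platform == "ion" else SET1_FILTERS_ILLUMINA
    return set1 + ("second_fisher", "vaf_lees")


@dataclasses.dataclass
class SnvConfig:
    platform: str = "illumina"
    min_mapq: int = 20
    min_baseq: int = 20
    drop_duplicates: bool = True
    alpha_extract: float = 1e-4
    min_alt: int = 3
    filter_alpha: float = 1e-4  # per-test cutoff of set-1 statistical filters
    homopolymer_min_run: int = 8
    mq0_max_frac: float = 0.1
    end_window: int = 5  # read-end-call filter window (bp from either end)
    dust_window: int = 10  # +/- bins around the candidate
    dust_min_count: int = 2
    dust_vaf_range: tuple[float, float] = (0.02, 0.25)
    trim: int = 5  # terminal bases removed in the second Fisher pass
    err_read_alpha: float = 1e-3  # Poisson tail defining an erroneous read
    err_read_min_mm: int = 2
    bq_drop_delta: float = 10.0
    max_indel_len: int = 10
    lees_k_max: int = 10
    lees_restarts: int = 5
    lees_min_obs: int = 20
    lees_band: tuple[float, float] = (0.01, 0.03)
    alpha_lees: float = 0.01
    germline_bands: tuple = ((0.40, 0.60), (0.96, 1.0))
    seed: int = 0


@dataclasses.dataclass
class FilterVerdict:
    filter_name: str
    passed: bool
    statistic: float
    threshold: float
    detail: str = ""


@dataclasses.dataclass
class VariantCandidate:
    chrom: str
    pos: int  # 0-based; for indels, the anchor base preceding the event
    ref: str
    alt: str  # SNV base, 'ins:<seq>' or 'del:<len>'
    tumor_alt: int
    tumor_ref: int
    control_alt: int
    control_ref: int
    vaf: float
    p_fisher: float
    p_fisher2: Optional[float] = None
    lees_p: Optional[float] = None
    verdicts: list = dataclasses.field(default_factory=list)
    status: str = "PASS"
    warn_no_control: bool = False

    @property
    def is_indel(self) -> bool:
        return self.alt.startswith(("ins:", "del:"))


def fisher_p_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p: P(alt count in tumor >= a) on the 2x2 table
    [[a, b], [c, d]] under the hypergeometric null."""
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def fisher_extract(
    tumor: PileupColumn,
    control: PileupColumn,
    alpha_extract: float = 1e-4,
    min_alt: int = 3,
) -> list[VariantCandidate]:
    """Extract candidate variants at one position (one-sided, enrichment in
    tumor).  A zero-depth control yields the degenerate-table p (1.0) with a
    warning flag and is emitted for downstream inspection regardless of the
    alpha cut."""
    if (tumor.chrom, tumor.pos) != (control.chrom, control.pos):
        raise ValueError("tumor/control pileup positions differ")
    out: list[VariantCandidate] = []
    ref = tumor.ref_base
    t_ref = tumor.count(ref)
    c_ref = control.count(ref)
    c_depth = control.depth
    for allele, cnt in tumor.counts.items():
        t_alt = int(cnt.sum())
        if allele == ref or t_alt < min_alt:
            continue
        c_alt = control.count(allele)
        p = fisher_p_greater(t_alt, t_ref, c_alt, c_ref)
        no_control = c_depth == 0
        if p <= alpha_extract or no_control:
            out.append(
                VariantCandidate(
                    chrom=tumor.chrom,
                    pos=tumor.pos,
                    ref=ref,
                    alt=allele,
                    tumor_alt=t_alt,
                    tumor_ref=t_ref,
                    control_alt=c_alt,
                    control_ref=c_ref,
                    vaf=t_alt / (t_alt + t_ref) if t_alt + t_ref else 0.0,
                    p_fisher=p,
                    warn_no_control=no_control,
                )
            )
    return out


# ---------------------------------------------------------------------------
# set-1 filters
# ---------------------------------------------------------------------------

def filter_strand_bias(cand: VariantCandidate, col: PileupColumn, alpha: float = 1e-4) -> FilterVerdict:
    """Fail when alt-supporting reads are significantly skewed to one strand
    relative to reference reads at the same site (one-sided Fisher, tested in
    the direction in which the alt strand ratio is more extreme)."""
    af, ar = col.strand_counts(cand.alt)
    rf, rr = col.strand_counts(cand.ref)
    n_alt, n_ref = af + ar, rf + rr
    if n_alt == 0:
        return FilterVerdict("strand_bias", True, 1.0, alpha, "no alt reads")
    alt_ratio = af / n_alt
    ref_ratio = rf / n_ref if n_ref else 0.5
    if alt_ratio >= ref_ratio:
        p = fisher_p_greater(af, ar, rf, rr)
    else:
        p = fisher_p_greater(ar, af, rr, rf)
    return FilterVerdict("strand_bias", p > alpha, p, alpha)


def filter_misalignment(
    cand: VariantCandidate,
    col: PileupColumn,
    window_cols: Sequence[PileupColumn],
    alpha: float = 1e-4,
    read_len: float = 150.0,
    fallback_rate: Optional[float] = None,
) -> FilterVerdict:
    """Fail when alt-supporting reads carry an excess of additional
    non-reference mismatches relative to the background per-base mismatch
    rate estimated from all reads in the surrounding window (an internal
    control), via a binomial tail on the total extra-mismatch count."""
    ctxs = col.contexts.get(cand.alt, [])
    n_sup = len(ctxs)
    if n_sup == 0:
        return FilterVerdict("misalignment", True, 0.0, alpha, "no context")
    m_total = int(sum(c.extra_mm for c in ctxs))
    calls = 0
    mismatches = 0
    for wc in window_cols:
        d = wc.depth
        calls += d
        nr = d - wc.count(wc.ref_base)
        if wc.pos == cand.pos and wc.chrom == cand.chrom:
            nr -= wc.count(cand.alt)
        mismatches += max(nr, 0)
    if calls == 0:
        if fallback_rate is None:
            return FilterVerdict("misalignment", True, float(m_total), alpha, "insufficient control")
        rate = fallback_rate
    else:
        rate = mismatches / calls
        if rate == 0 and fallback_rate:
            rate = fallback_rate
    rate = max(rate, 1.0 / (calls + read_len * n_sup + 1))
    trials = max(int(round(n_sup * read_len)), m_total, 1)
    p = float(binom.sf(m_total - 1, trials, rate)) if m_total > 0 else 1.0
    return FilterVerdict("misalignment", p > alpha, p, alpha, f"extra_mm={m_total} rate={rate:.3g}")


def filter_homopolymer(
    cand: VariantCandidate, reference: Fasta, min_run: int = 8
) -> FilterVerdict:
    """Fail variants lying within a single-base run of length >= min_run
    (threshold inclusive).  For indels the base after the anchor is also
    checked, since the event is keyed to the preceding base."""
    contig = reference[cand.chrom]
    lo = max(0, cand.pos - min_run - 1)
    hi = min(len(contig), cand.pos + min_run + 2)
    seq = str(contig[lo:hi]).upper()
    probe = {cand.pos - lo, cand.pos + 1 - lo} if cand.is_indel else {cand.pos - lo}
    run_len = 0
    run_start = 0
    longest = 0
    for i in range(len(seq) + 1):
        if i < len(seq) and run_len and seq[i] == seq[i - 1]:
            run_len += 1
        else:
            if run_len >= min_run and any(run_start <= p < run_start + run_len for p in probe):
                longest = max(longest, run_len)
            run_start = i
            run_len = 1
    passed = longest < min_run
    return FilterVerdict("homopolymer", passed, float(longest), float(min_run))


def filter_mq0(cand: VariantCandidate, col: PileupColumn, max_frac: float = 0.1) -> FilterVerdict:
    """Fail when the fraction of ambiguously mapped (MQ0) coverage exceeds
    max_frac (strict inequality)."""
    denom = col.mq0_count + col.depth
    frac = col.mq0_count / denom if denom else 0.0
    return FilterVerdict("mq0", frac <= max_frac, frac, max_frac)


def filter_read_end(
    cand: VariantCandidate, col: PileupColumn, end_window: int = 5, alpha: float = 1e-4
) -> FilterVerdict:
    """Fail when alt calls are concentrated within ``end_window`` bp of read
    ends compared with reference calls at the same site (one-sided Fisher).
    Vacuous (pass) below two alt observations."""
    ctxs = col.contexts.get(cand.alt, [])
    n_alt = len(ctxs)
    if n_alt < 2:
        return FilterVerdict("read_end", True, 1.0, alpha, "fewer than 2 alt reads")
    alt_within = sum(1 for c in ctxs if c.end_dist < end_window)
    nonref_within = sum(
        1 for lst in col.contexts.values() for c in lst if c.end_dist < end_window
    )
    ref_total = col.count(cand.ref)
    ref_within = max(col.end_depth - nonref_within, 0)
    ref_within = min(ref_within, ref_total)
    p = fisher_p_greater(alt_within, n_alt - alt_within, ref_within, ref_total - ref_within)
    return FilterVerdict("read_end", p > alpha, p, alpha, f"alt_within={alt_within}/{n_alt}")


def is_dusty(col: PileupColumn, min_count: int = 2, vaf_range: tuple[float, float] = (0.02, 0.25)) -> bool:
    """A 'dusty' position carries a sub-candidate non-reference allele at low
    but non-negligible VAF -- the halo of correlated FFPE/misalignment noise."""
    depth = col.depth
    if depth == 0:
        return False
    for allele, cnt in col.counts.items():
        if allele == col.ref_base:
            continue
        n = int(cnt.sum())
        if n >= min_count and vaf_range[0] <= n / depth < vaf_range[1]:
            return True
    return False


def filter_dust(
    cand: VariantCandidate,
    window_cols: Sequence[PileupColumn],
    background_rate: float,
    alpha: float = 1e-4,
    min_count: int = 2,
    vaf_range: tuple[float, float] = (0.02, 0.25),
) -> FilterVerdict:
    """Fail when the window around the candidate holds more low-VAF noise
    positions than the panel-wide background rate predicts (binomial tail)."""
    cols = [c for c in window_cols if not (c.chrom == cand.chrom and c.pos == cand.pos)]
    n = len(cols)
    if n == 0:
        return FilterVerdict("dust", True, 0.0, alpha, "empty window")
    k = sum(1 for c in cols if is_dusty(c, min_count, vaf_range))
    rate = max(background_rate, 1e-9)
    p = float(binom.sf(k - 1, n, rate)) if k > 0 else 1.0
    return FilterVerdict("dust", p > alpha, p, alpha, f"dusty={k}/{n} bg={rate:.3g}")


def filter_bq_drop(
    cand: VariantCandidate, col: PileupColumn, platform: str, delta: float = 10.0
) -> FilterVerdict:
    """Ion-platform indels only: fail when base quality downstream of the
    event drops by more than ``delta`` relative to upstream, averaged over
    supporting reads."""
    if platform != "ion" or not cand.is_indel:
        return FilterVerdict("bq_drop", True, 0.0, delta, "not applicable")
    ctxs = col.contexts.get(cand.alt, [])
    drops = [c.bq_up - c.bq_down for c in ctxs if np.isfinite(c.bq_up) and np.isfinite(c.bq_down)]
    if not drops:
        return FilterVerdict("bq_drop", True, 0.0, delta, "no BQ context")
    mean_drop = float(np.mean(drops))
    return FilterVerdict("bq_drop", mean_drop <= delta, mean_drop, delta)


# ---------------------------------------------------------------------------
# set-2: second Fisher pass
# ---------------------------------------------------------------------------

def _erroneous(ctx, bg_mm_per_read: float, alpha: float, min_mm: int) -> bool:
    if ctx.extra_mm < min_mm:
        return False
    return float(poisson.sf(ctx.extra_mm - 1, max(bg_mm_per_read, 1e-9))) < alpha


def second_fisher_pass(
    cand: VariantCandidate,
    tumor_col: PileupColumn,
    control_col: PileupColumn,
    bg_mm_per_read: float,
    trim: int = 5,
    err_read_alpha: float = 1e-3,
    err_read_min_mm: int = 2,
    alpha_extract: float = 1e-4,
) -> FilterVerdict:
    """Remove erroneous reads (extra-mismatch count beyond the internal
    control Poisson expectation), trim the terminal ``trim`` bp of every
    read from counting, and re-run the one-sided Fisher test on the cleaned
    tumor/control table."""

    def clean_alt(col: PileupColumn) -> int:
        return sum(
            1
            for c in col.contexts.get(cand.alt, [])
            if c.end_dist >= trim and not _erroneous(c, bg_mm_per_read, err_read_alpha, err_read_min_mm)
        )

    def trimmed_ref(col: PileupColumn, ref_count: int) -> int:
        nonref_trim = sum(1 for lst in col.contexts.values() for c in lst if c.end_dist < trim)
        ref_in_trim = max(col.trim_depth - nonref_trim, 0)
        return max(ref_count - min(ref_in_trim, ref_count), 0)

    t_alt2 = clean_alt(tumor_col)
    t_ref2 = trimmed_ref(tumor_col, cand.tumor_ref)
    c_alt2 = clean_alt(control_col)
    c_ref2 = trimmed_ref(control_col, cand.control_ref)
    if t_alt2 == 0:
        cand.p_fisher2 = 1.0
        return FilterVerdict("second_fisher", False, 1.0, alpha_extract, "no clean support")
    p2 = fisher_p_greater(t_alt2, t_ref2, c_alt2, c_ref2)
    cand.p_fisher2 = p2
    return FilterVerdict(
        "second_fisher", p2 <= alpha_extract, p2, alpha_extract,
        f"clean table {t_alt2}/{t_ref2} vs {c_alt2}/{c_ref2}",
    )


# ---------------------------------------------------------------------------
# set-3 and germline
# ---------------------------------------------------------------------------

def vaf_lees_filter(
    cands: Sequence[VariantCandidate],
    model: Optional[BetaMixtureModel],
    alpha_lees: float = 0.01,
) -> list[FilterVerdict]:
    """Beta-binomial test of each candidate's (alt | depth) against the
    fitted error component; candidates whose counts are consistent with the
    error distribution (upper-tail p > alpha) are removed."""
    verdicts = []
    if model is None or model.error_component is None:
        for _ in cands:
            verdicts.append(FilterVerdict("vaf_lees", True, 1.0, alpha_lees, "no error component"))
        return verdicts
    j = model.error_component
    a, b = float(model.alphas[j]), float(model.betas[j])
    for cand in cands:
        depth = cand.tumor_alt + cand.tumor_ref
        p = beta_binomial_sf(cand.tumor_alt, depth, a, b)
        cand.lees_p = p
        verdicts.append(FilterVerdict("vaf_lees", p <= alpha_lees, p, alpha_lees))
    return verdicts


def load_snp_sites(path: str) -> set:
    """Sites (chrom, 0-based pos, ref, alt) from a SNP-database VCF."""
    sites = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                sites.add((rec.chrom, rec.start, rec.ref, alt))
    return sites


def _vcf_alleles(cand: VariantCandidate, reference: Optional[Fasta]) -> tuple[str, str]:
    if cand.alt.startswith("del:"):
        n = int(cand.alt.split(":", 1)[1])
        if reference is not None:
            deleted = str(reference[cand.chrom][cand.pos + 1 : cand.pos + 1 + n]).upper()
        else:
            deleted = "N" * n
        return cand.ref + deleted, cand.ref
    if cand.alt.startswith("ins:"):
        return cand.ref, cand.ref + cand.alt.split(":", 1)[1]
    return cand.ref, cand.alt


def germline_filter(
    cands: Sequence[VariantCandidate],
    snp_sites: Optional[set] = None,
    bands: tuple = ((0.40, 0.60), (0.96, 1.0)),
    reference: Optional[Fasta] = None,
) -> list[FilterVerdict]:
    """Unmatched-control germline heuristic: remove candidates recorded in a
    SNP database and those whose VAF sits in the heterozygous band
    [0.40, 0.60] or the homozygous band (0.96, 1]."""
    verdicts = []
    (het_lo, het_hi), (hom_lo, hom_hi) = bands
    for cand in cands:
        in_band = (het_lo <= cand.vaf <= het_hi) or (hom_lo < cand.vaf <= hom_hi)
        in_db = False
        if snp_sites:
            ref, alt = _vcf_alleles(cand, reference)
            in_db = (cand.chrom, cand.pos, ref, alt) in snp_sites
        detail = "SNP database" if in_db else (f"VAF {cand.vaf:.3f} in germline band" if in_band else "")
        verdicts.append(FilterVerdict("germline", not (in_band or in_db), cand.vaf, het_lo, detail))
    return verdicts


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CallResult:
    candidates: list
    model: Optional[BetaMixtureModel]
    stats: dict


def _pileup_from_input(source, targets, reference, cfg: SnvConfig) -> Pileup:
    reads = read_alignments(source) if isinstance(source, str) else iter(source)
    mq0: list = []
    stream = prep_filter(
        reads, min_mapq=cfg.min_mapq, min_baseq=cfg.min_baseq,
        drop_duplicates=cfg.drop_duplicates, mq0_spans=mq0,
    )
    return build_pileups(
        stream, targets, reference,
        end_window=cfg.end_window, trim_window=cfg.trim, mq0_spans=mq0,
    )


def _candidate_flats(pp: Pileup, min_alt: int) -> list[int]:
    totals = pp.base_counts.sum(axis=2)
    masked = totals.copy()
    ok = pp.ref_codes < 4
    idx = np.arange(pp.size)[ok]
    masked[idx, pp.ref_codes[ok]] = 0
    flats = set(np.nonzero(masked.max(axis=1) >= min_alt)[0].tolist())
    for flat, alleles in pp.indel_counts.items():
        if any(int(c.sum()) >= min_alt for c in alleles.values()):
            flats.add(flat)
    return sorted(flats)


def _panel_noise_stats(pp: Pileup, cfg: SnvConfig) -> dict:
    totals = pp.base_counts.sum(axis=2)
    depth = totals.sum(axis=1)
    covered = depth > 0
    n_cov = int(covered.sum())
    ok = covered & (pp.ref_codes < 4)
    ref_counts = np.zeros(pp.size)
    idx = np.nonzero(ok)[0]
    ref_counts[idx] = totals[idx, pp.ref_codes[idx]]
    nonref = depth - ref_counts
    mm_rate = float(nonref[ok].sum() / max(depth[ok].sum(), 1))
    masked_nr = totals.copy()
    masked_nr[idx, pp.ref_codes[idx]] = 0
    mx = masked_nr.max(axis=1)
    lo, hi = cfg.dust_vaf_range
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, mx / np.maximum(depth, 1), 0.0)
    dusty = (mx >= cfg.dust_min_count) & (vaf >= lo) & (vaf < hi)
    dust_rate = float(dusty[ok].sum() / max(n_cov, 1))
    return {
        "mm_rate_per_base": mm_rate,
        "dust_rate": dust_rate,
        "covered_positions": n_cov,
        "mean_read_length": pp.mean_read_length,
    }


def _window_columns(pp: Pileup, chrom: str, pos: int, w: int) -> list[PileupColumn]:
    cols = []
    for p in range(pos - w, pos + w + 1):
        fi = pp.flat_index(chrom, p)
        if fi is not None:
            cols.append(pp.column_at(fi))
    return cols


def run_cascade(
    tumor_pp: Pileup,
    control_pp: Pileup,
    reference: Fasta,
    cfg: SnvConfig,
    snp_sites: Optional[set] = None,
) -> CallResult:
    """Run extraction and the full noise-filter cascade on built pileups."""
    stats = _panel_noise_stats(tumor_pp, cfg)
    read_len = stats["mean_read_length"] or 150.0
    bg_mm_per_read = stats["mm_rate_per_base"] * read_len

    candidates: list[VariantCandidate] = []
    for flat in _candidate_flats(tumor_pp, cfg.min_alt):
        chrom, pos = tumor_pp.locate(flat)
        t_col = tumor_pp.column_at(flat)
        c_fi = control_pp.flat_index(chrom, pos)
        c_col = control_pp.column_at(c_fi) if c_fi is not None else PileupColumn(chrom, pos, t_col.ref_base, {})
        for cand in fisher_extract(t_col, c_col, cfg.alpha_extract, cfg.min_alt):
            win = _window_columns(tumor_pp, chrom, pos, cfg.dust_window)
            set1 = [
                filter_misalignment(
                    cand, t_col, win, cfg.filter_alpha, read_len,
                    fallback_rate=stats["mm_rate_per_base"],
                ),
                filter_strand_bias(cand, t_col, cfg.filter_alpha),
                filter_homopolymer(cand, reference, cfg.homopolymer_min_run),
                filter_mq0(cand, t_col, cfg.mq0_max_frac),
                filter_read_end(cand, t_col, cfg.end_window, cfg.filter_alpha),
                filter_dust(cand, win, stats["dust_rate"], cfg.filter_alpha,
                            cfg.dust_min_count, cfg.dust_vaf_range),
            ]
            if cfg.platform == "ion":
                set1.append(filter_bq_drop(cand, t_col, cfg.platform, cfg.bq_drop_delta))
            v2 = second_fisher_pass(
                cand, t_col, c_col, bg_mm_per_read, cfg.trim,
                cfg.err_read_alpha, cfg.err_read_min_mm, cfg.alpha_extract,
            )
            cand.verdicts = set1 + [v2]
            candidates.append(cand)

    survivors = [c for c in candidates if all(v.passed for v in c.verdicts)]
    model = fit_beta_mixture(
        [c.vaf for c in survivors],
        k_max=cfg.lees_k_max, restarts=cfg.lees_restarts, seed=cfg.seed,
        min_obs=cfg.lees_min_obs, error_band=cfg.lees_band,
    )
    lees = vaf_lees_filter(candidates, model, cfg.alpha_lees)
    germ = germline_filter(candidates, snp_sites, cfg.germline_bands, reference)
    for cand, vl, vg in zip(candidates, lees, germ):
        cand.verdicts.extend([vl, vg])
        failing = next((v.filter_name for v in cand.verdicts if not v.passed), None)
        cand.status = failing or "PASS"
    stats["n_candidates"] = len(candidates)
    stats["n_pass"] = sum(1 for c in candidates if c.status == "PASS")
    return CallResult(candidates=candidates, model=model, stats=stats)


def call_variants(
    tumor: Union[str, Iterable],
    control: Union[str, Iterable],
    targets: list[TargetRegion],
    reference: Fasta,
    config: Optional[SnvConfig] = None,
    snp_sites: Optional[set] = None,
) -> CallResult:
    """End-to-end SNV/indel calling: prep filters, pileups, extraction and
    the full cascade, in the documented order."""
    cfg = config or SnvConfig()
    tumor_pp = _pileup_from_input(tumor, targets, reference, cfg)
    control_pp = _pileup_from_input(control, targets, reference, cfg)
    return run_cascade(tumor_pp, control_pp, reference, cfg, snp_sites)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(
    result: CallResult,
    path: str,
    reference: Fasta,
    cfg: Optional[SnvConfig] = None,
) -> None:
    cfg = cfg or SnvConfig()
    filters = noise_filter_names(cfg.platform) + ("germline",)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ffpecall",
        f"##ffpecall_platform={cfg.platform}",
    ]
    for name in reference.keys():
        lines.append(f"##contig=<ID={name},length={len(reference[name])}>")
    for f in filters:
        lines.append(f'##FILTER=<ID={f},Description="{f} noise filter">')
    lines += [
        '##INFO=<ID=TAC,Number=1,Type=Integer,Description="Tumor alt read count">',
        '##INFO=<ID=TRC,Number=1,Type=Integer,Description="Tumor ref read count">',
        '##INFO=<ID=CAC,Number=1,Type=Integer,Description="Control alt read count">',
        '##INFO=<ID=CRC,Number=1,Type=Integer,Description="Control ref read count">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Tumor variant allele frequency">',
        '##INFO=<ID=PF1,Number=1,Type=Float,Description="Extraction Fisher p">',
        '##INFO=<ID=PF2,Number=1,Type=Float,Description="Second-pass Fisher p">',
        '##INFO=<ID=LEES_P,Number=1,Type=Float,Description="Beta-binomial tail p vs error component">',
        '##INFO=<ID=VERDICTS,Number=1,Type=String,Description="filter:P/F pairs">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for cand in sorted(result.candidates, key=lambda c: (c.chrom, c.pos)):
        ref, alt = _vcf_alleles(cand, reference)
        info = (
            f"TAC={cand.tumor_alt};TRC={cand.tumor_ref};"
            f"CAC={cand.control_alt};CRC={cand.control_ref};"
            f"VAF={cand.vaf:.4f};PF1={cand.p_fisher:.3g}"
        )
        if cand.p_fisher2 is not None:
            info += f";PF2={cand.p_fisher2:.3g}"
        if cand.lees_p is not None:
            info += f";LEES_P={cand.lees_p:.3g}"
        info += ";VERDICTS=" + "|".join(
            f"{v.filter_name}:{'P' if v.passed else 'F'}" for v in cand.verdicts
        )
        lines.append(
            f"{cand.chrom}\t{cand.pos + 1}\t.\t{ref}\t{alt}\t.\t{cand.status}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
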