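"""Noise-filter cascade: each filter's rule checked on constructed pileup
columns, with independent tail-probability oracles where a test statistic is
involved."""

from math import comb

import numpy as np
import pytest
from pyfaidx import Fasta

from ffpecall.pileup import CallContext, PileupColumn
from ffpecall.snv import (
    FilterVerdict,
    SnvConfig,
    VariantCandidate,
    filter_bq_drop,
    filter_dust,
    filter_homopolymer,
    filter_misalignment,
    filter_mq0,
    filter_read_end,
    filter_strand_bias,
    germline_filter,
    noise_filter_names,
    second_fisher_pass,
)
from test_snv_stats import hypergeom_tail_exact


def make_col(pos=100, ref="A", counts=None, contexts=None, **kw):
    counts = {k: np.array(v) for k, v in (counts or {}).items()}
    return PileupColumn("chr1", pos, ref, counts, contexts=contexts or {}, **kw)


def make_cand(alt="C", tumor_alt=10, tumor_ref=90, pos=100, ref="A", **kw):
    return VariantCandidate(
        chrom="chr1", pos=pos, ref=ref, alt=alt, tumor_alt=tumor_alt,
        tumor_ref=tumor_ref, control_alt=0, control_ref=100,
        vaf=tumor_alt / (tumor_alt + tumor_ref), p_fisher=1e-6, **kw,
    )


def ctx(strand=0, end_dist=50, extra_mm=0, baseq=35, bq_up=float("nan"), bq_down=float("nan")):
    return CallContext(strand, end_dist, extra_mm, baseq, bq_up, bq_down)


class TestStrandBias:
    def test_extreme_bias_fails_with_oracle_p(self):
        col = make_col(counts={"C": [20, 0], "A": [50, 50]})
        v = filter_strand_bias(make_cand(tumor_alt=20), col, alpha=1e-4)
        assert not v.passed
        assert v.statistic == pytest.approx(hypergeom_tail_exact(20, 0, 50, 50), abs=1e-12)

    def test_balanced_alt_passes(self):
        col = make_col(counts={"C": [10, 10], "A": [50, 50]})
        assert filter_strand_bias(make_cand(tumor_alt=20), col).passed

    def test_single_read_no_power(self):
        col = make_col(counts={"C": [1, 0], "A": [5, 5]})
        v = filter_strand_bias(make_cand(tumor_alt=1), col, alpha=1e-4)
        assert v.passed
        assert v.statistic == pytest.approx(hypergeom_tail_exact(1, 0, 5, 5), abs=1e-12)

    def test_no_alt_reads_vacuous(self):
        col = make_col(counts={"A": [50, 50]})
        assert filter_strand_bias(make_cand(tumor_alt=0), col).passed


class TestMisalignment:
    def test_mismatch_laden_support_fails(self):
        # 10 supporting reads each carrying 4 extra mismatches against a
        # background of 0.2 mismatches per read
        contexts = {"C": [ctx(extra_mm=4) for _ in range(10)]}
        col = make_col(counts={"C": [5, 5], "A": [45, 45]}, contexts=contexts)
        window = [
            make_col(pos=100 + i, counts={"A": [50, 50], "G": [0, 0]}) for i in range(1, 11)
        ]
        # plant a window mismatch rate of ~0.2 per 150bp read (0.0015/base)
        noisy = make_col(pos=120, counts={"A": [497, 500], "G": [2, 1]})
        v = filter_misalignment(
            make_cand(), col, window + [noisy], alpha=1e-4, read_len=150.0
        )
        assert not v.passed

    def test_clean_support_passes(self):
        contexts = {"C": [ctx(extra_mm=0) for _ in range(10)]}
        col = make_col(counts={"C": [5, 5], "A": [45, 45]}, contexts=contexts)
        window = [make_col(pos=101, counts={"A": [500, 500], "G": [1, 0]})]
        assert filter_misalignment(make_cand(), col, window).passed

    def test_no_control_reads_passes_with_detail(self):
        contexts = {"C": [ctx(extra_mm=2)]}
        col = make_col(counts={"C": [1, 0]}, contexts=contexts)
        v = filter_misalignment(make_cand(tumor_alt=1), col, [])
        assert v.passed and "insufficient control" in v.detail


class TestHomopolymer:
    @pytest.fixture()
    def homopoly_ref(self, tmp_path):
        seq = "ACGTACGTAC" + "A" * 12 + "CGTACGTACG" + "G" * 8 + "TACGTACGTA"
        p = tmp_path / "hp.fa"
        p.write_text(f">chr1\n{seq}\n")
        return Fasta(str(p)), seq

    def test_deletion_inside_long_run_fails(self, homopoly_ref):
        fa, seq = homopoly_ref
        cand = make_cand(alt="del:1", pos=15, ref="A")
        assert not filter_homopolymer(cand, fa, min_run=8).passed

    def test_snv_in_mixed_context_passes(self, homopoly_ref):
        fa, _ = homopoly_ref
        assert filter_homopolymer(make_cand(pos=3, ref="T", alt="C"), fa, min_run=8).passed

    def test_run_exactly_at_threshold_fails(self, homopoly_ref):
        fa, seq = homopoly_ref
        run_start = seq.index("G" * 8)
        cand = make_cand(pos=run_start + 4, ref="G", alt="T")
        assert not filter_homopolymer(cand, fa, min_run=8).passed


class TestMq0:
    @pytest.mark.parametrize(
        "mq0,depth,passed", [(50, 50, False), (0, 100, True), (10, 90, True)]
    )
    def test_fraction_rule(self, mq0, depth, passed):
        col = make_col(counts={"A": [depth // 2, depth - depth // 2]}, mq0_count=mq0)
        v = filter_mq0(make_cand(), col, max_frac=0.1)
        assert v.passed is passed


class TestReadEnd:
    def test_end_concentrated_alt_fails(self):
        contexts = {"C": [ctx(end_dist=d) for d in [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]]}
        # ref calls uniform along 150bp reads: ~7% within 5bp of an end
        col = make_col(
            counts={"C": [5, 5], "A": [70, 70]}, contexts=contexts, end_depth=10 + 9
        )
        v = filter_read_end(make_cand(), col, end_window=5, alpha=1e-4)
        assert not v.passed

    def test_uniform_alt_passes(self):
        contexts = {"C": [ctx(end_dist=d) for d in [10, 30, 50, 70, 20, 40, 60, 15, 35, 55]]}
        col = make_col(counts={"C": [5, 5], "A": [70, 70]}, contexts=contexts, end_depth=9)
        assert filter_read_end(make_cand(), col).passed

    def test_single_alt_read_vacuous(self):
        contexts = {"C": [ctx(end_dist=0)]}
        col = make_col(counts={"C": [1, 0], "A": [70, 70]}, contexts=contexts, end_depth=6)
        v = filter_read_end(make_cand(tumor_alt=1), col)
        assert v.passed and "fewer than 2" in v.detail

    def test_type_one_error_near_nominal_under_null(self):
        # alt and ref end-distances drawn from the same uniform: the fail
        # rate over seeded replicates stays near the nominal alpha
        rng = np.random.default_rng(7)
        alpha = 0.05
        fails = 0
        n_rep = 200
        for _ in range(n_rep):
            dists = rng.integers(0, 75, size=12)
            contexts = {"C": [ctx(end_dist=int(d)) for d in dists]}
            ref_dists = rng.integers(0, 75, size=140)
            end_depth = int((dists < 5).sum() + (ref_dists < 5).sum())
            col = make_col(
                counts={"C": [6, 6], "A": [70, 70]}, contexts=contexts, end_depth=end_depth
            )
            v = filter_read_end(make_cand(tumor_alt=12, tumor_ref=140), col, alpha=alpha)
            fails += not v.passed
        assert fails / n_rep <= alpha + 0.03


class TestDust:
    def _window(self, n_dusty, n_total):
        cols = []
        for i in range(n_total):
            if i < n_dusty:
                cols.append(make_col(pos=200 + i, counts={"A": [49, 49], "G": [1, 1]}))
            else:
                cols.append(make_col(pos=200 + i, counts={"A": [50, 50]}))
        return cols

    def test_noisy_window_fails(self):
        v = filter_dust(make_cand(), self._window(8, 20), background_rate=0.01, alpha=1e-4)
        assert not v.passed
        # oracle: binomial tail P(X >= 8 | n=20, p=0.01)
        p = sum(comb(20, k) * 0.01**k * 0.99 ** (20 - k) for k in range(8, 21))
        assert v.statistic == pytest.approx(p, rel=1e-9)

    def test_clean_window_passes(self):
        assert filter_dust(make_cand(), self._window(0, 20), 0.01).passed

    def test_empty_window_passes_with_detail(self):
        v = filter_dust(make_cand(), [], 0.01)
        assert v.passed and "empty window" in v.detail


class TestBqDrop:
    def test_illumina_snv_not_applicable(self):
        v = filter_bq_drop(make_cand(), make_col(), platform="illumina")
        assert v.passed and v.detail == "not applicable"

    def test_ion_indel_with_drop_fails(self):
        contexts = {"del:1": [ctx(bq_up=30.0, bq_down=12.0) for _ in range(5)]}
        col = make_col(counts={"del:1": [3, 2]}, contexts=contexts)
        v = filter_bq_drop(make_cand(alt="del:1"), col, platform="ion", delta=10.0)
        assert not v.passed and v.statistic == pytest.approx(18.0)

    def test_ion_indel_flat_profile_passes(self):
        contexts = {"del:1": [ctx(bq_up=30.0, bq_down=29.0)]}
        col = make_col(counts={"del:1": [1, 0]}, contexts=contexts)
        assert filter_bq_drop(make_cand(alt="del:1"), col, platform="ion").passed


class TestSecondFisher:
    def test_unchanged_counts_reproduce_first_p(self):
        cand = make_cand(tumor_alt=10, tumor_ref=90)
        contexts = {"C": [ctx(end_dist=40, extra_mm=0) for _ in range(10)]}
        t_col = make_col(counts={"C": [5, 5], "A": [45, 45]}, contexts=contexts, trim_depth=0)
        c_col = make_col(counts={"A": [50, 50]}, trim_depth=0)
        v = second_fisher_pass(cand, t_col, c_col, bg_mm_per_read=0.2, alpha_extract=1e-3)
        assert v.passed
        assert cand.p_fisher2 == pytest.approx(hypergeom_tail_exact(10, 90, 0, 100), abs=1e-12)

    def test_erroneous_read_removal_weakens_table(self):
        cand = make_cand(tumor_alt=10, tumor_ref=90)
        contexts = {"C": [ctx(extra_mm=8, end_dist=40)] * 8 + [ctx(extra_mm=0, end_dist=40)] * 2}
        t_col = make_col(counts={"C": [5, 5], "A": [45, 45]}, contexts=contexts)
        c_col = make_col(counts={"A": [50, 50]})
        v = second_fisher_pass(cand, t_col, c_col, bg_mm_per_read=0.2, alpha_extract=1e-4)
        assert not v.passed
        assert cand.p_fisher2 == pytest.approx(hypergeom_tail_exact(2, 90, 0, 100), abs=1e-12)

    def test_all_support_in_trimmed_ends_fails(self):
        cand = make_cand(tumor_alt=10, tumor_ref=90)
        contexts = {"C": [ctx(end_dist=2, extra_mm=0)] * 10}
        t_col = make_col(counts={"C": [5, 5], "A": [45, 45]}, contexts=contexts, trim_depth=10)
        c_col = make_col(counts={"A": [50, 50]})
        v = second_fisher_pass(cand, t_col, c_col, bg_mm_per_read=0.2)
        assert not v.passed and v.detail == "no clean support"


class TestGermline:
    def test_snp_database_hit_fails(self):
        cand = make_cand(tumor_alt=25, tumor_ref=75)  # VAF 0.25, outside bands
        sites = {("chr1", 100, "A", "C")}
        (v,) = germline_filter([cand], snp_sites=sites)
        assert not v.passed and "SNP database" in v.detail

    def test_off_band_without_snp_file_passes(self):
        (v,) = germline_filter([make_cand(tumor_alt=25, tumor_ref=75)], snp_sites=None)
        assert v.passed

    @pytest.mark.parametrize(
        "vaf,passed",
        [(0.39, True), (0.40, False), (0.50, False), (0.60, False), (0.61, True),
         (0.96, True), (0.961, False), (0.97, False), (1.0, False)],
    )
    def test_band_boundaries(self, vaf, passed):
        cand = make_cand(tumor_alt=int(round(vaf * 1000)), tumor_ref=1000 - int(round(vaf * 1000)))
        cand.vaf = vaf
        (v,) = germline_filter([cand])
        assert v.passed is passed


class TestCascadeStructure:
    def test_platform_filter_counts(self):
        assert len(noise_filter_names("illumina")) == 8
        assert len(noise_filter_names("ion")) == 9
        assert "bq_drop" in noise_filter_names("ion")
        assert "bq_drop" not in noise_filter_names("illumina")

    def test_verdicts_are_pure_and_order_stable(self):
        # every set-1 verdict is a pure function of its inputs, so the
        # overall PASS/FAIL state cannot depend on evaluation order
        col = make_col(counts={"C": [20, 0], "A": [50, 50]})
        cand = make_cand(tumor_alt=20)
        filters = [
            lambda: filter_strand_bias(make_cand(tumor_alt=20), col),
            lambda: filter_mq0(make_cand(tumor_alt=20), col),
            lambda: filter_dust(make_cand(tumor_alt=20), [], 0.01),
        ]
        first = [f() for f in filters]
        second = [f() for f in reversed(filters)][::-1]
        assert [(v.filter_name, v.passed) for v in first] == [
            (v.filter_name, v.passed) for v in second
        ]
        assert all(v.passed == (v2.passed) for v, v2 in zip(first, [f() for f in filters]))
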