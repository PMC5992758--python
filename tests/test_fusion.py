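"""Fusion calling: 2map split detection, virtual-fusion rescue, paired-end
corroboration and S/N ranking, on synthetic junction fixtures."""

import numpy as np
import pytest
from pyfaidx import Fasta

from ffpecall.fusion import (
    AlignerNotFoundError,
    Breakpoint,
    FusionCandidate,
    FusionConfig,
    LocalAlignment,
    align_local,
    build_virtual_fusion,
    call_fusions,
    paired_end_step,
    rank_candidates,
    revcomp,
    twomap_step,
)
from ffpecall.simulate import clean_junction, simulate_fusion_reads, simulate_reference


@pytest.fixture(scope="module")
def fusion_world(tmp_path_factory):
    """A 4-gene reference, a microhomology-free junction and its FASTA/BED."""
    outdir = tmp_path_factory.mktemp("fusion")
    ref = simulate_reference(n_genes=4, lengths=4000, seed=31)
    fa_path, bed_path = ref.write(str(outdir))
    bp_a, bp_b = clean_junction(ref, "GENE1", "GENE2", seed=7)
    return ref, fa_path, bed_path, bp_a, bp_b, outdir


def _simulate_and_call(fusion_world, tmp_path, n_support=20, noise=0, jitter=0, seed=32, **cfg_kw):
    ref, fa, bed, bp_a, bp_b, _ = fusion_world
    fq = str(tmp_path / "reads.fastq")
    simulate_fusion_reads(
        ref, "GENE1", "GENE2", bp_a, bp_b, fq, n_support=n_support,
        junction_jitter=jitter, noise_chimeras=noise, n_background=400, seed=seed,
    )
    return call_fusions(fq, fa, bed, ["GENE1"], config=FusionConfig(**cfg_kw))


class TestEndToEnd:
    def test_clean_fixture_exact_breakpoints_and_full_support(self, fusion_world, tmp_path):
        ref, fa, bed, bp_a, bp_b, _ = fusion_world
        res = _simulate_and_call(fusion_world, tmp_path, n_support=20)
        top = res.candidates[0]
        assert (top.gene_a, top.gene_b) == ("GENE1", "GENE2")
        assert (top.bp_a.pos, top.bp_b.pos) == (bp_a, bp_b)
        assert top.split_support + top.vf_support == 20
        assert top.sn_ratio == float("inf")

    def test_jittered_junctions_stay_within_merge_tolerance(self, fusion_world, tmp_path):
        ref, fa, bed, bp_a, bp_b, _ = fusion_world
        res = _simulate_and_call(fusion_world, tmp_path, n_support=20, jitter=2, seed=33)
        top = res.candidates[0]
        assert abs(top.bp_a.pos - bp_a) <= 2 and abs(top.bp_b.pos - bp_b) <= 2

    def test_no_support_reads_no_candidate(self, fusion_world, tmp_path):
        res = _simulate_and_call(fusion_world, tmp_path, n_support=0, seed=34)
        assert res.candidates == []

    def test_true_fusion_outranks_scattered_noise(self, fusion_world, tmp_path):
        res = _simulate_and_call(fusion_world, tmp_path, n_support=20, noise=15, seed=35)
        top = res.candidates[0]
        assert (top.gene_a, top.gene_b) == ("GENE1", "GENE2")
        assert top.sn_ratio > 1.0

    def test_support_reads_counted_once(self, fusion_world, tmp_path):
        res = _simulate_and_call(fusion_world, tmp_path, n_support=20, noise=10, seed=36)
        names = [c.support_read_names for c in res.candidates]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert not (names[i] & names[j])


class TestVirtualFusion:
    def test_sequence_equals_reference_slices(self, fusion_world):
        ref, fa_path, _, bp_a, bp_b, _ = fusion_world
        cand = FusionCandidate(
            "GENE1", "GENE2",
            Breakpoint(ref.contig, bp_a, "+"), Breakpoint(ref.contig, bp_b, "-"),
            split_support=1,
        )
        fa = Fasta(fa_path)
        vref = build_virtual_fusion(cand, fa, flank=100)
        want = ref.sequence[bp_a - 99 : bp_a + 1] + ref.sequence[bp_b : bp_b + 100]
        assert vref == want and cand.junction_index == 100

    def test_requires_split_read(self, fusion_world):
        ref, fa_path, _, bp_a, bp_b, _ = fusion_world
        cand = FusionCandidate(
            "GENE1", "GENE2",
            Breakpoint(ref.contig, bp_a, "+"), Breakpoint(ref.contig, bp_b, "-"),
            split_support=0,
        )
        with pytest.raises(ValueError):
            build_virtual_fusion(cand, Fasta(fa_path))

    def test_short_arm_read_rescued_by_vf_not_2map(self, fusion_world, tmp_path):
        # a chimera with a 5 bp arm cannot split-map (min_seg 20) but aligns
        # contiguously across the virtual junction
        ref, fa, bed, bp_a, bp_b, _ = fusion_world
        fq = tmp_path / "short.fastq"
        long_arm = ref.sequence[bp_a - 144 : bp_a + 1]
        short_arm = ref.sequence[bp_b : bp_b + 5]
        reads = [(f"anchor.{i}", ref.sequence[bp_a - 120 + i : bp_a + 1] + ref.sequence[bp_b : bp_b + 29 + 120 - i]) for i in range(3)]
        reads.append(("shorty", long_arm + short_arm))
        with open(fq, "w") as fh:
            for name, s in reads:
                fh.write(f"@{name}\n{s}\n+\n{'I' * len(s)}\n")
        res = call_fusions(str(fq), fa, bed, ["GENE1"], config=FusionConfig())
        top = res.candidates[0]
        assert top.split_support == 3
        assert top.vf_support >= 1
        assert "shorty" in top.support_read_names


class TestTwoMap:
    def _aln(self, name, chrom, rs, re_, qs, qe, strand="+", L=150):
        return LocalAlignment(name, chrom, rs, re_, strand, qs, qe, L)

    def test_same_gene_split_ignored(self, fusion_world):
        ref = fusion_world[0]
        g = ref.genes[0]
        alns = {
            "r": [
                self._aln("r", ref.contig, g.start + 100, g.start + 175, 0, 75),
                self._aln("r", ref.contig, g.start + 500, g.start + 575, 75, 150),
            ]
        }
        assert twomap_step(alns, ref.genes, ["GENE1"]) == []

    def test_three_locus_split_dropped(self, fusion_world):
        ref = fusion_world[0]
        g1, g2, g3 = ref.genes[:3]
        alns = {
            "r": [
                self._aln("r", ref.contig, g1.start + 100, g1.start + 150, 0, 50),
                self._aln("r", ref.contig, g2.start + 100, g2.start + 150, 50, 100),
                self._aln("r", ref.contig, g3.start + 100, g3.start + 150, 100, 150),
            ]
        }
        assert twomap_step(alns, ref.genes, ["GENE1"]) == []

    def test_candidates_must_touch_user_gene(self, fusion_world):
        ref = fusion_world[0]
        g3, g4 = ref.genes[2], ref.genes[3]
        alns = {
            "r": [
                self._aln("r", ref.contig, g3.start + 100, g3.start + 175, 0, 75),
                self._aln("r", ref.contig, g4.start + 200, g4.start + 275, 75, 150),
            ]
        }
        assert twomap_step(alns, ref.genes, ["GENE1"]) == []
        assert len(twomap_step(alns, ref.genes, ["GENE3"])) == 1

    def test_requires_user_gene_list(self, fusion_world):
        with pytest.raises(ValueError):
            twomap_step({}, fusion_world[0].genes, [])


class TestPairedEnd:
    def _world_alns(self, fusion_world):
        ref, _, _, bp_a, bp_b, _ = fusion_world
        cand = FusionCandidate(
            "GENE1", "GENE2",
            Breakpoint(ref.contig, bp_a, "+"), Breakpoint(ref.contig, bp_b, "-"),
            split_support=1,
        )
        return ref, bp_a, bp_b, cand

    def test_straddling_pair_counted(self, fusion_world):
        ref, bp_a, bp_b, cand = self._world_alns(fusion_world)
        alns = {
            "p/1": [LocalAlignment("p/1", ref.contig, bp_a - 200, bp_a - 50, "+", 0, 150, 150)],
            "p/2": [LocalAlignment("p/2", ref.contig, bp_b + 50, bp_b + 200, "-", 0, 150, 150)],
        }
        paired_end_step(alns, [cand], ref.genes)
        assert cand.pair_support == 1

    def test_same_gene_pair_not_counted(self, fusion_world):
        ref, bp_a, bp_b, cand = self._world_alns(fusion_world)
        alns = {
            "p/1": [LocalAlignment("p/1", ref.contig, bp_a - 200, bp_a - 50, "+", 0, 150, 150)],
            "p/2": [LocalAlignment("p/2", ref.contig, bp_a - 400, bp_a - 250, "-", 0, 150, 150)],
        }
        paired_end_step(alns, [cand], ref.genes)
        assert cand.pair_support == 0

    def test_unmapped_mate_not_counted(self, fusion_world):
        ref, bp_a, bp_b, cand = self._world_alns(fusion_world)
        alns = {"p/1": [LocalAlignment("p/1", ref.contig, bp_a - 200, bp_a - 50, "+", 0, 150, 150)]}
        paired_end_step(alns, [cand], ref.genes)
        assert cand.pair_support == 0


class TestRanking:
    def _cand(self, ga, gb, split):
        return FusionCandidate(
            ga, gb, Breakpoint("c", 0, "+"), Breakpoint("c", 1, "-"), split_support=split
        )

    def test_sn_ratio_arithmetic(self):
        ranked = rank_candidates([self._cand("A", "B", 20), self._cand("A", "C", 4)], 1000)
        assert ranked[0].gene_b == "B" and ranked[0].sn_ratio == pytest.approx(5.0)
        assert ranked[1].sn_ratio == pytest.approx(0.2)

    def test_single_candidate_infinite_sn(self):
        (c,) = rank_candidates([self._cand("A", "B", 7)], 1000)
        assert c.sn_ratio == float("inf")

    def test_norm_support_scale(self):
        (c,) = rank_candidates([self._cand("A", "B", 20)], 1_000_000)
        assert c.norm_support == pytest.approx(2e-5)

    def test_empty_input_empty_output(self):
        assert rank_candidates([], 100) == []

    def test_zero_mapped_total_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates([], 0)


class TestAligner:
    def test_missing_binary_is_actionable(self, fusion_world, tmp_path):
        _, fa, _, _, _, _ = fusion_world
        fq = tmp_path / "x.fastq"
        fq.write_text("@r\nACGT\n+\nIIII\n")
        with pytest.raises(AlignerNotFoundError, match="definitely-absent-aligner"):
            align_local(str(fq), fa, FusionConfig(bwa="definitely-absent-aligner"))

    def test_all_n_read_yields_no_alignment(self, fusion_world, tmp_path):
        _, fa, _, _, _, _ = fusion_world
        fq = tmp_path / "n.fastq"
        fq.write_text("@r\n" + "N" * 150 + "\n+\n" + "I" * 150 + "\n")
        alns, seqs = align_local(str(fq), fa, FusionConfig())
        assert alns == {}


def test_revcomp_involution():
    s = "ACGTTGCAN"
    assert revcomp(revcomp(s)) == s
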