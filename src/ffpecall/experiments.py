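"""Benchmark experiments run end-to-end through the public interfaces.

These reproduce, at desk scale, the headline evaluations the callers are
designed around: the dilution-series sensitivity of the SNV caller at low
tumor fraction and deep coverage, and the fusion signal-to-noise ranking on
a fixture with scattered chimeric noise.
"""

from __future__ import annotations

import os
import tempfile
from typing import Optional

from pyfaidx import Fasta

from .core_io import load_targets
from .fusion import FusionConfig, call_fusions
from .simulate import (
    clean_junction,
    plant_variants,
    simulate_fusion_reads,
    simulate_reference,
    simulate_snv_reads,
)
from .snv import SnvConfig, call_variants


def dilution_sensitivity(
    seed: int,
    panel_kb: int = 50,
    depth: float = 970.0,
    n_variants: int = 50,
    purity: float = 0.1,
    workdir: Optional[str] = None,
) -> dict:
    """Sensitivity of the SNV caller on a fully synthetic dilution series.

    Plants ``n_variants`` heterozygous somatic variants on a ``panel_kb`` kb
    panel, dilutes them to expected VAF = purity/2 at mean depth ``depth``
    with FFPE-like noise in the foreground sample only, runs the full
    cascade with defaults, and scores called PASS variants against the
    plant.  Returns sensitivity as a percentage plus the raw counts.
    """
    own_tmp = workdir is None
    wd = workdir or tempfile.mkdtemp(prefix="ffpecall_dilution_")
    n_genes = max(panel_kb // 5, 1)
    ref = simulate_reference(n_genes=n_genes, lengths=5000, seed=seed)
    variants = plant_variants(ref, n_variants, seed=seed + 1)
    paths = simulate_snv_reads(
        ref, ref.genes, variants, purity=purity, depth=depth, outdir=wd, seed=seed + 2
    )
    fa, bed = ref.write(wd)
    result = call_variants(
        paths["tumor_sam"], paths["control_sam"], load_targets(bed), Fasta(fa),
        SnvConfig(seed=seed),
    )
    called = {(c.pos, c.alt) for c in result.candidates if c.status == "PASS"}
    planted = {(p, a) for p, _, a, _ in variants}
    recovered = len(called & planted)
    out = {
        "sensitivity_pct": 100.0 * recovered / len(planted),
        "n_planted": len(planted),
        "n_recovered": recovered,
        "n_false_pass": len(called - planted),
        "depth": depth,
        "purity": purity,
    }
    if own_tmp:
        import shutil

        shutil.rmtree(wd, ignore_errors=True)
    return out


def fusion_signal_to_noise(
    seed: int,
    n_support: int = 20,
    noise_chimeras: int = 15,
    n_background: int = 500,
    workdir: Optional[str] = None,
) -> dict:
    """S/N of the true fusion on a fixture with scattered chimeric noise."""
    own_tmp = workdir is None
    wd = workdir or tempfile.mkdtemp(prefix="ffpecall_fusion_")
    ref = simulate_reference(n_genes=4, lengths=4000, seed=seed)
    fa, bed = ref.write(wd)
    bp_a, bp_b = clean_junction(ref, "GENE1", "GENE2", seed=seed + 1)
    fq = os.path.join(wd, "reads.fastq")
    simulate_fusion_reads(
        ref, "GENE1", "GENE2", bp_a, bp_b, fq, n_support=n_support,
        noise_chimeras=noise_chimeras, n_background=n_background, seed=seed + 2,
    )
    res = call_fusions(fq, fa, bed, ["GENE1"], config=FusionConfig(), workdir=wd)
    top = res.candidates[0] if res.candidates else None
    out = {
        "top_is_planted": bool(
            top and {top.gene_a, top.gene_b} == {"GENE1", "GENE2"}
            and (top.bp_a.pos, top.bp_b.pos) == (bp_a, bp_b)
        ),
        "sn_ratio": top.sn_ratio if top else 0.0,
        "total_support": top.total_support() if top else 0,
        "mapped_reads": res.mapped_read_total,
    }
    if own_tmp:
        import shutil

        shutil.rmtree(wd, ignore_errors=True)
    return out
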