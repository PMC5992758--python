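"""Shared fixtures: small synthetic references, hand-built reads and helpers.

Everything is generated programmatically at test time; nothing binary is
stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest
from pyfaidx import Fasta

from ffpecall.core_io import ReadRecord, TargetRegion, encode_bases


def make_read(
    name: str,
    chrom: str,
    pos: int,
    seq: str,
    mapq: int = 60,
    quals: int | list = 35,
    cigar=None,
    is_reverse: bool = False,
    **kw,
) -> ReadRecord:
    q = np.full(len(seq), quals, dtype=np.uint8) if isinstance(quals, int) else np.asarray(quals, dtype=np.uint8)
    return ReadRecord(
        name=name,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        is_reverse=is_reverse,
        cigar=cigar or [(0, len(seq))],
        codes=encode_bases(seq),
        quals=q,
        **kw,
    )


@pytest.fixture()
def tiny_reference(tmp_path):
    """A 400 bp single-contig FASTA with a known sequence."""
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 400))
    path = tmp_path / "ref.fa"
    path.write_text(f">chr1\n{seq}\n")
    return Fasta(str(path)), seq


@pytest.fixture()
def tiny_targets():
    return [TargetRegion("chr1", 0, 400)]
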