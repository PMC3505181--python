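"""Shared fixtures: all test data is forged programmatically at run time."""

from __future__ import annotations

import numpy as np
import pytest

import indelscope as ix


@pytest.fixture(scope="session")
def demo_run() -> ix.PipelineResult:
    """One medium-size end-to-end run with planted editing and sensitivity,
    shared by the pipeline-level tests."""
    cfg = ix.RunConfig(seed=101, outdir=None, run_sensitivity=True, write_artifacts=False)
    cfg.forge.n_reads = 60_000
    cfg.forge.n_editing_sites = 10
    return ix.run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_genome() -> ix.GenomeSet:
    return ix.build_reference(1, 20_000, 0.45, seed=3)


def make_record(
    read_id: str,
    contig: str,
    pos: int,
    cigar: list[tuple[str, int]],
    seq: str,
    quals=37,
    mapq: int = 60,
    nm: int = 0,
    strand: str = "+",
    score: int = 30,
) -> "ix.AlignmentRecord":
    """Fabricate an alignment record for pileup fixtures."""
    q = np.full(len(seq), quals) if isinstance(quals, int) else np.asarray(quals)
    return ix.AlignmentRecord(
        read_id=read_id,
        contig=contig,
        pos=pos,
        strand=strand,
        cigar=cigar,
        mapq=mapq,
        score=score,
        n_mismatches=nm,
        seq=seq,
        base_qualities=q,
    )
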