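"""Generator tests: determinism, composition, round-trips, planted structures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import indelscope as ix
from indelscope.dna import gc_fraction, revcomp
from indelscope.synthetic_data import Liftover, apply_truth_variants, normalize_indel


# ---------------------------------------------------------------------------
# reference construction


def test_build_reference_deterministic():
    a = ix.build_reference(1, 10_000, 0.5, seed=7)
    b = ix.build_reference(1, 10_000, 0.5, seed=7)
    assert a.reference == b.reference


def test_build_reference_degenerate_gc():
    gs = ix.build_reference(1, 10_000, 1.0 - 1e-12, seed=1)
    seq = gs.reference["chr1"]
    assert set(seq) <= {"G", "C"}


def test_build_reference_gc_within_bounds():
    gs = ix.build_reference(2, 50_000, 0.41, seed=1)
    for seq in gs.reference.values():
        assert 0.38 <= gc_fraction(seq) <= 0.44


def test_build_reference_rejects_bad_sizes():
    with pytest.raises(ValueError):
        ix.build_reference(0, 10_000, 0.5)
    with pytest.raises(ValueError):
        ix.build_reference(1, 10, 0.5)
    with pytest.raises(ValueError):
        ix.build_reference(1, 10_000, 0.0)


# ---------------------------------------------------------------------------
# diploid derivation and liftover


def test_null_variation_gives_identical_haplotypes():
    gs = ix.build_reference(1, 5_000, 0.5, seed=2)
    gs2, variants = ix.derive_diploid(gs, snp_rate=0.0, indel_rate=0.0, seed=3)
    assert variants == []
    assert gs2.maternal == gs2.reference == gs2.paternal


def test_variant_round_trip_reproduces_haplotypes():
    gs = ix.build_reference(2, 30_000, 0.41, seed=4)
    gs2, variants = ix.derive_diploid(gs, snp_rate=1e-3, indel_rate=2e-4, seed=5)
    for hap in ("maternal", "paternal"):
        for contig in gs2.reference:
            vs = [v for v in variants if v.haplotype == hap and v.contig == contig]
            seq, lift = apply_truth_variants(gs2.reference[contig], vs)
            assert seq == gs2.haplotype(hap)[contig]
            assert lift.hap_len == len(seq)


def test_indel_count_is_poisson_distributed():
    """Mean indel count over many seeds matches rate*length within 3 s.e."""
    rate, length, n_seeds = 1e-4, 100_000, 100
    gs = ix.build_reference(1, length, 0.41, seed=0)
    counts = []
    for s in range(n_seeds):
        _, variants = ix.derive_diploid(gs, snp_rate=0.0, indel_rate=rate, seed=s)
        counts.append(sum(1 for v in variants if v.haplotype == "maternal" and v.kind != "snp"))
    mean = np.mean(counts)
    expect = rate * length
    se = np.sqrt(expect / n_seeds)
    assert abs(mean - expect) <= 3 * se


def test_planted_insertion_lengthens_haplotype_by_one():
    gs = ix.build_reference(1, 5_000, 0.5, seed=2)
    v = ix.TruthVariant("chr1", 1000, "insertion", gs.reference["chr1"][1000],
                        gs.reference["chr1"][1000] + "A", "maternal")
    seq, lift = apply_truth_variants(gs.reference["chr1"], [v])
    assert len(seq) == 5_001
    assert lift.to_ref(1000) == (1000, True)
    # the inserted base maps inexactly back to the anchor
    npos, exact = lift.to_ref(1001)
    assert not exact and npos == 1000
    assert lift.to_ref(1002) == (1001, True)


def test_liftover_round_trip_identity_outside_indels():
    gs = ix.build_reference(1, 20_000, 0.41, seed=9)
    gs2, variants = ix.derive_diploid(gs, snp_rate=0.0, indel_rate=3e-4, seed=10)
    lift = gs2.liftover["maternal"]["chr1"]
    for pos in range(0, lift.hap_len, 137):
        rp, exact = lift.to_ref(pos)
        if exact:
            back, exact2 = lift.from_ref(rp)
            assert exact2 and back == pos


def test_rates_out_of_range_rejected():
    gs = ix.build_reference(1, 5_000, 0.5, seed=2)
    with pytest.raises(ValueError):
        ix.derive_diploid(gs, snp_rate=-0.1, indel_rate=0.0)
    with pytest.raises(ValueError):
        ix.derive_diploid(gs, snp_rate=0.0, indel_rate=0.5)


# ---------------------------------------------------------------------------
# indel normalization


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=20, max_size=40), st.data())
def test_normalize_indel_preserves_edited_sequence(seq, data):
    pos = data.draw(st.integers(min_value=1, max_value=len(seq) - 3))
    kind = data.draw(st.sampled_from(["insertion", "deletion"]))
    base = data.draw(st.sampled_from("ACGT")) if kind == "insertion" else seq[pos + 1]
    npos, nallele = normalize_indel(seq, pos, kind, base)
    if kind == "insertion":
        original = seq[: pos + 1] + base + seq[pos + 1 :]
        shifted = seq[: npos + 1] + nallele + seq[npos + 1 :]
    else:
        original = seq[: pos + 1] + seq[pos + 2 :]
        shifted = seq[: npos + 1] + seq[npos + 1 + len(nallele) :]
    assert original == shifted
    # idempotence
    assert normalize_indel(seq, npos, kind, nallele) == (npos, nallele)


# ---------------------------------------------------------------------------
# gene models, traps, paralogs


@pytest.fixture(scope="module")
def genome_with_genes():
    gs = ix.build_reference(2, 100_000, 0.41, seed=11)
    genes = ix.build_gene_models(gs, 20, seed=12)
    return gs, genes


def test_gene_models_have_canonical_splice_signals(genome_with_genes):
    gs, genes = genome_with_genes
    for g in genes:
        seq = gs.reference[g.contig]
        for s, e in g.introns:
            if g.strand == "+":
                assert seq[s : s + 2] == "GT" and seq[e - 2 : e] == "AG"
            else:  # coding-strand GT..AG appears reverse-complemented
                assert seq[s : s + 2] == "CT" and seq[e - 2 : e] == "AC"


def test_gene_exons_pairwise_disjoint(genome_with_genes):
    _, genes = genome_with_genes
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).extend(g.exons)
    for intervals in by_contig.values():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2


def test_single_exon_gene_has_no_introns():
    gs = ix.build_reference(1, 50_000, 0.41, seed=13)
    before = gs.reference["chr1"]
    genes = ix.build_gene_models(gs, 3, exon_count_range=(1, 1), seed=14)
    assert all(len(g.exons) == 1 and not g.introns for g in genes)
    assert gs.reference["chr1"] == before  # no GT/AG edits needed


def test_gene_models_error_when_genome_too_small():
    gs = ix.build_reference(1, 1_000, 0.41, seed=15)
    with pytest.raises(ValueError):
        ix.build_gene_models(gs, 50, seed=16)


def test_splice_trap_writes_exon_tail_copy(genome_with_genes):
    gs = ix.build_reference(2, 100_000, 0.41, seed=17)
    genes = ix.build_gene_models(gs, 20, seed=18)
    traps = ix.plant_splice_traps(gs, genes, 4, seed=19, trap_len=20)
    assert len(traps) == 4
    for t in traps:
        seq = gs.reference[t.contig]
        s, e = t.copy_interval
        assert e == t.acceptor_pos
        assert seq[e - 2 : e] == "AG"  # the copy supplies the acceptor signal
        gene = next(g for g in genes if g.gene_id == t.gene_id)
        donor_end = next(x[1] for x, i in zip(gene.exons, gene.introns) if i[1] == t.acceptor_pos)
        tail = seq[donor_end - 20 : donor_end]
        copy = seq[s:e]
        assert abs(len(copy) - 20) == 1  # exactly one 1 bp indel
        assert sum(a != b for a, b in zip(tail, copy)) <= len(tail) // 2


def test_paralog_identity_and_single_indel():
    import edlib

    gs = ix.build_reference(1, 80_000, 0.41, seed=20)
    pairs = ix.plant_paralogs(gs, 1, 500, 0.02, seed=21)
    p = pairs[0]
    src = gs.reference[p.source_contig][slice(*p.source_interval)]
    cpy = gs.reference[p.copy_contig][slice(*p.copy_interval)]
    aln = edlib.align(src, cpy, mode="NW", task="path")
    identity = 1 - aln["editDistance"] / len(src)
    assert 0.97 <= identity <= 0.99
    n_indels = sum(1 for c in aln["cigar"] if c in "ID")
    assert abs(len(cpy) - len(src)) == 1


def test_paralog_zero_divergence_identical_copy():
    gs = ix.build_reference(1, 80_000, 0.41, seed=22)
    pairs = ix.plant_paralogs(gs, 1, 300, 0.0, seed=23)
    p = pairs[0]
    src = gs.reference[p.source_contig][slice(*p.source_interval)]
    cpy = gs.reference[p.copy_contig][slice(*p.copy_interval)]
    assert src == cpy and p.indel_kind is None


def test_paralog_zero_pairs_leaves_genome_unchanged():
    gs = ix.build_reference(1, 80_000, 0.41, seed=24)
    before = dict(gs.reference)
    assert ix.plant_paralogs(gs, 0, 300, 0.01, seed=25) == []
    assert gs.reference == before


# ---------------------------------------------------------------------------
# transcription


def test_single_exon_transcript_equals_genomic_substring(genome_with_genes):
    gs = ix.build_reference(1, 50_000, 0.41, seed=26)
    genes = [ix.GeneModel("g1", "chr1", "+", [(1000, 1250)])]
    db = ix.transcribe(gs, genes, "reference")
    assert db.transcripts["g1"].seq == gs.reference["chr1"][1000:1250]


def test_two_exon_transcript_length():
    gs = ix.build_reference(1, 50_000, 0.41, seed=27)
    genes = [ix.GeneModel("g1", "chr1", "+", [(1000, 1100), (1300, 1450)])]
    db = ix.transcribe(gs, genes, "reference")
    assert len(db.transcripts["g1"].seq) == 250
    assert db.transcripts["g1"].junctions == [100]


def test_minus_strand_transcript_is_reverse_complement():
    gs = ix.build_reference(1, 50_000, 0.41, seed=28)
    genes = [ix.GeneModel("g1", "chr1", "-", [(1000, 1100), (1300, 1450)])]
    db = ix.transcribe(gs, genes, "reference")
    expect = revcomp(gs.reference["chr1"][1000:1100] + gs.reference["chr1"][1300:1450])
    assert db.transcripts["g1"].seq == expect
    tx = db.transcripts["g1"]
    # coordinate maps invert each other
    for tpos in (0, 10, 160, 249):
        assert tx.genome_to_tx(tx.tx_to_genome(tpos)) == tpos


def test_transcribe_rejects_exon_outside_contig():
    gs = ix.build_reference(1, 5_000, 0.41, seed=29)
    genes = [ix.GeneModel("g1", "chr1", "+", [(4_900, 5_200)])]
    with pytest.raises(ValueError):
        ix.transcribe(gs, genes, "reference")


# ---------------------------------------------------------------------------
# editing injection and read simulation


@pytest.fixture(scope="module")
def transcribed():
    gs = ix.build_reference(1, 80_000, 0.41, seed=30)
    genes = ix.build_gene_models(gs, 8, seed=31)
    gs2, _ = ix.derive_diploid(gs, snp_rate=0.0, indel_rate=0.0, seed=32)
    db = ix.transcribe(gs2, genes, "maternal")
    return gs2, genes, db


def test_inject_editing_zero_sites_is_noop(transcribed):
    _, _, db = transcribed
    before = len(db.editing_sites)
    db2, truths = ix.inject_editing(db, 0, 0.5, seed=33)
    assert truths == [] and len(db2.editing_sites) == before


def test_inject_editing_respects_placement_rules(transcribed):
    gs2, _, db = transcribed
    db, truths = ix.inject_editing(db, 8, 0.5, seed=34)
    assert len(truths) == 8
    for t in truths:
        tx = db.transcripts[t.transcript_id]
        assert 40 <= t.transcript_pos < len(tx.seq) - 40
        assert all(abs(t.transcript_pos - j) >= 40 for j in tx.junctions)
    # cleanup for other tests sharing the fixture
    db.editing_sites.clear()


def test_full_fraction_editing_carried_by_every_covering_read(transcribed):
    gs2, _, db = transcribed
    db, truths = ix.inject_editing(db, 1, 1.0, seed=35)
    t = truths[0]
    reads = ix.simulate_reads(db, None, 4000, 33, 0.0, seed=36)
    covering = [
        r
        for r in reads
        if r.truth_transcript == t.transcript_id
        and r.truth_offset <= t.transcript_pos < r.truth_offset + 32
    ]
    assert covering and all(r.carried_events for r in covering)
    db.editing_sites.clear()


def test_editing_support_is_binomial(transcribed):
    """Carrier fraction at a 0.5-fraction site matches Binomial expectation."""
    gs2, _, db = transcribed
    db, truths = ix.inject_editing(db, 1, 0.5, seed=37)
    t = truths[0]
    carriers = total = 0
    for s in range(25):
        reads = ix.simulate_reads(db, None, 2000, 33, 0.0, seed=100 + s)
        for r in reads:
            if (
                r.truth_transcript == t.transcript_id
                and r.truth_offset <= t.transcript_pos < r.truth_offset + 32
            ):
                total += 1
                carriers += bool(r.carried_events)
    assert total > 200
    se = np.sqrt(0.25 * total)
    assert abs(carriers - 0.5 * total) <= 3 * se
    db.editing_sites.clear()


def test_error_free_reads_are_exact_transcript_substrings(transcribed):
    _, _, db = transcribed
    reads = ix.simulate_reads(db, None, 500, 33, 0.0, seed=38)
    for r in reads:
        tx = db.transcripts[r.truth_transcript]
        fwd = r.sequence if r.truth_strand == "+" else revcomp(r.sequence)
        assert fwd == tx.seq[r.truth_offset : r.truth_offset + 33]


def test_observed_error_rate_matches_requested(transcribed):
    _, _, db = transcribed
    reads = ix.simulate_reads(db, None, 10_000, 33, 0.01, seed=39)
    mism = 0
    for r in reads:
        tx = db.transcripts[r.truth_transcript]
        fwd = r.sequence if r.truth_strand == "+" else revcomp(r.sequence)
        truth = tx.seq[r.truth_offset : r.truth_offset + 33]
        mism += sum(a != b for a, b in zip(fwd, truth))
    rate = mism / (len(reads) * 33)
    assert 0.008 <= rate <= 0.012


def test_simulation_deterministic_for_fixed_seed(transcribed):
    _, _, db = transcribed
    a = ix.simulate_reads(db, None, 300, 33, 0.01, seed=40)
    b = ix.simulate_reads(db, None, 300, 33, 0.01, seed=40)
    assert [(r.read_id, r.sequence, list(r.phred_qualities)) for r in a] == [
        (r.read_id, r.sequence, list(r.phred_qualities)) for r in b
    ]


def test_error_bases_usually_low_quality(transcribed):
    _, _, db = transcribed
    reads = ix.simulate_reads(db, None, 3_000, 33, 0.02, seed=41)
    low_at_error = n_error = 0
    for r in reads:
        tx = db.transcripts[r.truth_transcript]
        truth = tx.seq[r.truth_offset : r.truth_offset + 33]
        fwd = r.sequence if r.truth_strand == "+" else revcomp(r.sequence)
        quals = r.phred_qualities if r.truth_strand == "+" else r.phred_qualities[::-1]
        for i, (a, b) in enumerate(zip(fwd, truth)):
            if a != b:
                n_error += 1
                low_at_error += quals[i] < 20
    assert n_error > 100
    assert low_at_error / n_error >= 0.5


def test_simulate_rejects_bad_inputs(transcribed):
    _, _, db = transcribed
    with pytest.raises(ValueError):
        ix.simulate_reads(db, None, 10, 33, 0.2, seed=1)
    empty = ix.JunctionDB(haplotype="maternal", transcripts={}, genes=[])
    with pytest.raises(ValueError):
        ix.simulate_reads(empty, None, 10, 33, 0.01, seed=1)
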