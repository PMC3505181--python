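"""False-positive cascade tests: each filter on constructed fixtures, plus
label correctness on the shared end-to-end run."""

from __future__ import annotations

import numpy as np
import pytest

import indelscope as ix
from indelscope.fp_classify import (
    ClassifyResources,
    check_known_variant,
    check_paralog,
    check_paternal_allele,
    check_splice_junction,
    classify_cascade,
    extract_flanks,
)
from indelscope.pileup_call import IndelCandidate
from indelscope.synthetic_data import GenomeSet, Liftover

from conftest import make_record


def identity_genomeset(reference: dict[str, str]) -> GenomeSet:
    """A haploid stand-in: maternal == paternal == reference."""
    lift = {c: Liftover.identity(len(s)) for c, s in reference.items()}
    return GenomeSet(
        reference=dict(reference),
        maternal=dict(reference),
        paternal=dict(reference),
        liftover={"maternal": dict(lift), "paternal": dict(lift)},
    )


def cand(contig, pos, kind, seq, **kw) -> IndelCandidate:
    base = dict(
        n_support=5,
        n_total=20,
        variant_qual=150.0,
        allele_set=((kind, seq),),
        homopolymer_run=1,
    )
    base.update(kw)
    return IndelCandidate(contig=contig, pos=pos, kind=kind, seq=seq, **base)


@pytest.fixture(scope="module")
def plain_resources():
    gs = ix.build_reference(1, 30_000, 0.45, seed=60)
    genomeset = identity_genomeset(gs.reference)
    genes = [ix.GeneModel("g1", "chr1", "+", [(2_000, 2_200), (2_400, 2_650)])]
    db = ix.transcribe(genomeset, genes, "reference")
    return ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[])


# ---------------------------------------------------------------------------
# flank extraction


def test_flank_window_lengths(plain_resources):
    res = plain_resources
    c = cand("chr1", 10_000, "insertion", "G")
    f = extract_flanks(c, res.mapping_genome)
    assert len(f.genomic_window) == 65
    assert len(f.edited_window) == 66
    assert f.anchor_offset == 32
    d = cand("chr1", 10_000, "deletion", res.mapping_genome["chr1"][10_001])
    fd = extract_flanks(d, res.mapping_genome)
    assert len(fd.genomic_window) == 65
    assert len(fd.edited_window) == 64 + 1  # rebalanced by one downstream base


def test_flank_truncated_at_contig_start(plain_resources):
    res = plain_resources
    c = cand("chr1", 10, "insertion", "G")
    f = extract_flanks(c, res.mapping_genome)
    assert f.window_start == 0 and f.anchor_offset == 10


# ---------------------------------------------------------------------------
# paternal-allele filter


@pytest.fixture(scope="module")
def diploid_site():
    """A pinned exonic paternal indel with reads from both haplotypes."""
    gs = ix.build_reference(1, 40_000, 0.45, seed=61)
    genes = ix.build_gene_models(gs, 4, exon_count_range=(2, 3), seed=62)
    g = genes[0]
    xs, xe = max(g.exons, key=lambda x: x[1] - x[0])
    site = (g.contig, (xs + xe) // 2)
    gs2, variants = ix.derive_diploid(gs, snp_rate=0.0, indel_rate=0.0, seed=63, indel_sites=[site])
    dbm = ix.transcribe(gs2, genes, "maternal")
    dbp = ix.transcribe(gs2, genes, "paternal")
    reads = ix.simulate_reads(dbm, None, 6_000, 33, 0.0, seed=64, id_prefix="m")
    reads += ix.simulate_reads(dbp, None, 6_000, 33, 0.0, seed=65, id_prefix="p")
    from indelscope.align import SeedIndex, map_reads

    idx = SeedIndex(gs2.maternal, seed_length=14)
    recs = [r for r in map_reads(reads, idx) if r]
    recs.sort(key=lambda r: (r.contig, r.pos))
    cands, _, _ = ix.call_indels_from_alignments(recs, gs2.maternal)
    db_ref = ix.transcribe(gs2, genes, "reference")
    res = ClassifyResources(genomeset=gs2, junction_db=db_ref, known_variants=[])
    support = ix.gather_supporting_reads(cands, recs, gs2.maternal)
    return gs2, variants, cands, support, res


def test_paternal_variant_site_matches(diploid_site):
    gs2, variants, cands, support, res = diploid_site
    v = next(v for v in variants if v.kind != "snp")
    hits = [
        (c, s)
        for c, s in zip(cands, support)
        if abs(res.candidate_ref_coords(c)[0] - v.ref_pos) <= 5
    ]
    assert hits, "the haplotype indel must be called"
    for c, s in hits:
        matched, ev = check_paternal_allele(c, s, res)
        assert matched is True
        assert ev["n_reads_matched"] == len(s) > 0


def test_reads_requiring_indel_against_paternal_do_not_match(plain_resources):
    """Supporting reads that still need the indel on the paternal genome
    leave the candidate to the next filter."""
    res = plain_resources
    seq = res.genomeset.maternal["chr1"]
    anchor = 15_000
    base = "G" if seq[anchor] != "G" else "C"
    read_seq = seq[anchor - 15 : anchor + 1] + base + seq[anchor + 1 : anchor + 17]
    rec = make_record(
        "r1", "chr1", anchor - 15, [("M", 16), ("I", 1), ("M", 16)], read_seq, score=26
    )
    c = cand("chr1", anchor, "insertion", base)
    matched, _ = check_paternal_allele(c, [rec], res)
    assert matched is False


def test_unresolvable_paternal_locus_passes_through():
    gs = ix.build_reference(1, 20_000, 0.45, seed=66)
    genomeset = identity_genomeset(gs.reference)
    del genomeset.liftover["paternal"]["chr1"]  # no paternal map for this contig
    db = ix.transcribe(genomeset, [], "reference")
    res = ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[])
    c = cand("chr1", 5_000, "insertion", "A")
    matched, ev = check_paternal_allele(c, [], res)
    assert matched is None and "warning" in ev


# ---------------------------------------------------------------------------
# splice-junction filter


def test_single_exon_region_fails_partial_criterion(plain_resources):
    """A candidate deep inside an exon fully aligns to the transcript, so the
    only-part-aligns criterion rejects the splice explanation."""
    res = plain_resources
    c = cand("chr1", 2_100, "insertion", "G")  # mid-exon1 of g1
    f = extract_flanks(c, res.mapping_genome)
    ok, _ = check_splice_junction(c, f, [], res)
    assert not ok


def test_intronic_candidate_without_transcript_fit_fails(plain_resources):
    """Partial genomic alignment alone is not enough: the indel-including
    evidence must fit the transcript gaplessly."""
    res = plain_resources
    seq = res.mapping_genome["chr1"]
    anchor = 2_210  # 10 bp into the intron of g1
    base = "G" if seq[anchor] != "G" else "C"
    c = cand("chr1", anchor, "insertion", base)
    f = extract_flanks(c, res.mapping_genome)
    # supporting reads are genomic (unspliced) sequence carrying the indel
    read_seq = seq[anchor - 15 : anchor + 1] + base + seq[anchor + 1 : anchor + 17]
    rec = make_record("r1", "chr1", anchor - 15, [("M", 16), ("I", 1), ("M", 16)], read_seq)
    ok, _ = check_splice_junction(c, f, [rec], res)
    assert not ok


def test_empty_junction_db_vacuously_fails():
    gs = ix.build_reference(1, 20_000, 0.45, seed=67)
    genomeset = identity_genomeset(gs.reference)
    db = ix.transcribe(genomeset, [], "reference")
    res = ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[])
    c = cand("chr1", 5_000, "insertion", "A")
    ok, _ = check_splice_junction(c, extract_flanks(c, res.mapping_genome), [], res)
    assert not ok


# ---------------------------------------------------------------------------
# paralog filter


def test_planted_paralog_copy_matches():
    gs = ix.build_reference(1, 40_000, 0.45, seed=68)
    genomeset = identity_genomeset(gs.reference)
    seq = genomeset.reference["chr1"]
    anchor = 20_000
    base = "T" if seq[anchor] != "T" else "A"
    # the decoy carries the edited sequence as plain genomic DNA
    edited = seq[anchor - 200 : anchor + 1] + base + seq[anchor + 1 : anchor + 200]
    genomeset.reference["decoy"] = edited
    db = ix.transcribe(genomeset, [], "reference")
    res = ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[])
    c = cand("chr1", anchor, "insertion", base)
    ok, ev = check_paralog(c, extract_flanks(c, res.mapping_genome), res)
    assert ok and ev["paralog_contig"] == "decoy"


def test_unique_region_has_no_paralog(plain_resources):
    res = plain_resources
    c = cand("chr1", 12_000, "insertion", "A")
    ok, _ = check_paralog(c, extract_flanks(c, res.mapping_genome), res)
    assert not ok


def test_gapped_secondary_alignment_not_a_paralog():
    """An identical copy without the indel would itself need a gap: no match."""
    gs = ix.build_reference(1, 40_000, 0.45, seed=69)
    genomeset = identity_genomeset(gs.reference)
    seq = genomeset.reference["chr1"]
    anchor = 20_000
    # exact copy of the unedited region elsewhere
    genomeset.reference["decoy"] = seq[anchor - 200 : anchor + 200]
    db = ix.transcribe(genomeset, [], "reference")
    res = ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[])
    base = "T" if seq[anchor] != "T" and seq[anchor + 1] != "T" else "G"
    c = cand("chr1", anchor, "insertion", base)
    ok, _ = check_paralog(c, extract_flanks(c, res.mapping_genome), res)
    assert not ok


# ---------------------------------------------------------------------------
# known-variant filter


def test_known_variant_exact_and_shifted_match():
    gs = ix.build_reference(1, 20_000, 0.45, seed=70)
    genomeset = identity_genomeset(gs.reference)
    seq = genomeset.reference["chr1"]
    # put the database entry at an unnormalized position inside a 2-base run
    pos = next(i for i in range(6_000, 7_000) if seq[i] == seq[i + 1])
    rec = dict(contig="chr1", pos=pos + 1, kind="deletion", ref=seq[pos + 1] + seq[pos + 2], alt=seq[pos + 1], id="rs1")
    db = ix.transcribe(genomeset, [], "reference")
    res = ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[rec])
    npos, nallele = ix.normalize_indel(seq, pos + 1, "deletion", seq[pos + 2])
    c = cand("chr1", npos, "deletion", nallele)
    ok, ev = check_known_variant(c, res)
    assert ok and ev["database_id"] == "rs1"


def test_snp_in_database_does_not_match_indel():
    gs = ix.build_reference(1, 20_000, 0.45, seed=71)
    genomeset = identity_genomeset(gs.reference)
    seq = genomeset.reference["chr1"]
    rec = dict(contig="chr1", pos=6_000, kind="snp", ref=seq[6_000], alt="A" if seq[6_000] != "A" else "C", id="rs2")
    db = ix.transcribe(genomeset, [], "reference")
    res = ClassifyResources(genomeset=genomeset, junction_db=db, known_variants=[rec])
    c = cand("chr1", 6_000, "insertion", "G")
    ok, _ = check_known_variant(c, res)
    assert not ok


# ---------------------------------------------------------------------------
# the cascade


def test_cascade_partition_and_order(plain_resources):
    """Sum of category counts equals the input count; first match wins."""
    res = plain_resources
    gs = res.genomeset
    seq = gs.reference["chr1"]
    anchor = 12_000
    base = "T" if seq[anchor] != "T" and seq[anchor + 1] != "T" else "G"
    c1 = cand("chr1", anchor, "insertion", base)  # residual: matches nothing
    c2 = cand("chr1", 6_000, "insertion", "A")  # known variant
    res.known_variants.append(
        dict(contig="chr1", pos=6_000, kind="insertion", ref=seq[6_000], alt=seq[6_000] + "A", id="rs9")
    )
    res2 = ClassifyResources(
        genomeset=gs, junction_db=res.junction_db, known_variants=res.known_variants
    )
    results, counts = classify_cascade([c1, c2], [[], []], res2)
    assert counts["initial_candidates"] == 2
    total = sum(counts[k] for k in ix.CATEGORIES)
    assert total == 2
    assert results[0].label == "residual" and results[0].evidence == {}
    assert results[1].label == "known_variant"


def test_cascade_prefers_splice_over_paralog(demo_run):
    """A candidate matching both the splice and the paralog fixture takes the
    earlier (splice) label — verified against an engineered double match."""
    fr = demo_run.forge
    res = ClassifyResources(
        genomeset=fr.genomeset, junction_db=fr.db_reference, known_variants=fr.known_records
    )
    splice_hits = [
        (c, s)
        for (c, s, ev) in zip(
            demo_run.candidates,
            ix.gather_supporting_reads(
                demo_run.candidates, demo_run.alignments, fr.genomeset.maternal
            ),
            demo_run.truth_eval["per_candidate"],
        )
        if ev["label"] == "splice_junction"
    ]
    assert splice_hits
    c, s = splice_hits[0]
    # engineer a paralog copy of the edited window onto a decoy contig
    flanks = extract_flanks(c, res.mapping_genome)
    gs2 = fr.genomeset
    gs2.reference["engineered_decoy"] = "ACGT" * 10 + flanks.edited_window + "TGCA" * 10
    res2 = ClassifyResources(
        genomeset=gs2, junction_db=fr.db_reference, known_variants=fr.known_records
    )
    ok, _ = check_paralog(c, flanks, res2)
    assert ok, "the engineered decoy must satisfy the paralog filter"
    results, _ = classify_cascade([c], [s], res2)
    assert results[0].label == "splice_junction"
    del gs2.reference["engineered_decoy"]


# ---------------------------------------------------------------------------
# labels on the shared end-to-end run


def test_all_mechanism_labels_correct_on_demo_run(demo_run):
    ev = demo_run.truth_eval
    assert ev["n_mechanism_derived"] >= 25
    assert ev["label_accuracy"] >= 0.9
    assert ev["editing_retention"] >= 0.9


def test_every_candidate_gets_exactly_one_label(demo_run):
    assert len(demo_run.classifications) == len(demo_run.candidates)
    for r in demo_run.classifications:
        assert r.label in ix.CATEGORIES
        if r.label != "residual":
            assert r.evidence


def test_summary_partition_enforced(demo_run):
    demo_run.summary.check_partition()
    broken = ix.SummaryReport(initial_candidates=5, residual=1)
    with pytest.raises(ValueError):
        broken.check_partition()
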