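"""Synthetic diploid genomes, gene models and RNA-seq reads with truth labels.

This module forges every genomic structure the downstream filters target:

* a random reference genome plus maternal/paternal haplotypes carrying
  independent SNP and single-base indel draws (with liftover tables),
* multi-exon gene models with canonical GT-AG introns,
* "splice traps" — near-copies of an exon tail written into the adjacent
  intron 3' end, the structure that makes a non-splice-aware aligner place
  junction-spanning reads on the genome with a spurious 1 bp indel,
* near-identical paralog copies on reference-only decoy contigs, emulating
  loci present in the individual's true genome but missing from the
  assembled haplotypes,
* transcript-level indel injections: hypothetical RNA editing events at a
  configurable molecule fraction, and database-annotated "misassembly"
  indels carried by every molecule of both haplotypes,
* short single-end reads with Phred-scored substitution errors.

Coordinates are 0-based half-open throughout; indels are left-aligned and
anchored on the base before the event (the emitted VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dna import BASES, decode, encode, gc_fraction, random_sequence, revcomp, run_length_at

__all__ = [
    "GenomeSet",
    "TruthVariant",
    "GeneModel",
    "ParalogPair",
    "SpliceTrap",
    "EditingTruth",
    "SimulatedRead",
    "Liftover",
    "Transcript",
    "JunctionDB",
    "QualityProfile",
    "build_reference",
    "derive_diploid",
    "apply_truth_variants",
    "build_gene_models",
    "plant_splice_traps",
    "plant_paralogs",
    "transcribe",
    "inject_editing",
    "mirror_editing",
    "editing_genome_event",
    "resolve_reference_coords",
    "simulate_reads",
    "normalize_indel",
]


# ---------------------------------------------------------------------------
# liftover


@dataclass
class Liftover:
    """Block-wise coordinate map between one haplotype contig and the reference.

    Blocks are maximal co-linear segments between indel breakpoints; SNPs do
    not break blocks. Arrays are parallel: block i maps haplotype interval
    [hap_starts[i], hap_starts[i]+lengths[i]) onto the reference interval
    starting at ref_starts[i].
    """

    hap_starts: np.ndarray
    ref_starts: np.ndarray
    lengths: np.ndarray
    hap_len: int
    ref_len: int

    def to_ref(self, pos: int) -> tuple[int, bool]:
        """Map a haplotype position to the reference; bool flags an exact hit."""
        if not 0 <= pos < self.hap_len:
            raise IndexError(f"haplotype position {pos} outside [0, {self.hap_len})")
        i = int(np.searchsorted(self.hap_starts, pos, side="right")) - 1
        off = pos - int(self.hap_starts[i])
        if off < int(self.lengths[i]):
            return int(self.ref_starts[i]) + off, True
        # inside inserted material: anchor on the last mapped base of the block
        return int(self.ref_starts[i]) + int(self.lengths[i]) - 1, False

    def from_ref(self, pos: int) -> tuple[int, bool]:
        """Map a reference position to the haplotype; bool flags an exact hit."""
        if not 0 <= pos < self.ref_len:
            raise IndexError(f"reference position {pos} outside [0, {self.ref_len})")
        i = int(np.searchsorted(self.ref_starts, pos, side="right")) - 1
        off = pos - int(self.ref_starts[i])
        if off < int(self.lengths[i]):
            return int(self.hap_starts[i]) + off, True
        # inside deleted material: anchor on the last haplotype base of the block
        return int(self.hap_starts[i]) + int(self.lengths[i]) - 1, False

    def map_interval_from_ref(self, start: int, end: int) -> tuple[int, int]:
        s, _ = self.from_ref(start)
        e, _ = self.from_ref(end - 1)
        return s, e + 1

    @classmethod
    def identity(cls, length: int) -> "Liftover":
        one = np.array([0])
        return cls(one, one.copy(), np.array([length]), length, length)


@dataclass
class GenomeSet:
    """Reference plus assembled maternal/paternal haplotypes and liftovers.

    ``liftover[haplotype][contig]`` maps that haplotype contig to the
    reference. Decoy contigs (paralog copies) exist in ``reference`` only.
    """

    reference: dict[str, str]
    maternal: dict[str, str] = field(default_factory=dict)
    paternal: dict[str, str] = field(default_factory=dict)
    liftover: dict[str, dict[str, Liftover]] = field(default_factory=dict)

    def haplotype(self, name: str) -> dict[str, str]:
        if name == "reference":
            return self.reference
        if name == "maternal":
            return self.maternal
        if name == "paternal":
            return self.paternal
        raise KeyError(name)


@dataclass
class TruthVariant:
    contig: str
    ref_pos: int  # 0-based anchor base before the event (SNP: the base itself)
    kind: str  # snp | insertion | deletion
    ref_allele: str
    alt_allele: str
    haplotype: str  # maternal | paternal | both
    in_database: bool = False

    def __post_init__(self) -> None:
        if self.kind == "snp":
            assert len(self.ref_allele) == len(self.alt_allele) == 1
        elif self.kind == "insertion":
            assert len(self.ref_allele) == 1 and len(self.alt_allele) >= 2
        elif self.kind == "deletion":
            assert len(self.alt_allele) == 1 and len(self.ref_allele) >= 2
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping, reference coords

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


@dataclass
class ParalogPair:
    source_contig: str
    source_interval: tuple[int, int]
    copy_contig: str
    copy_interval: tuple[int, int]
    percent_identity: float
    indel_kind: str | None  # kind of the copy's indel relative to the source
    indel_source_pos: int | None  # anchor in source (reference) coordinates
    indel_base: str | None


@dataclass
class SpliceTrap:
    gene_id: str
    contig: str
    acceptor_pos: int  # reference position of the downstream exon start
    kind: str  # indel of the intronic copy relative to the exon tail
    copy_interval: tuple[int, int]
    indel_anchor: int  # reference anchor where the spurious indel is expected


@dataclass
class EditingTruth:
    """A planted transcript-level single-base indel.

    ``db_id`` set ⇒ the event models a misassembled genomic indel annotated
    in the known-variant database (carried by every molecule) rather than a
    hypothetical editing event.
    """

    transcript_id: str
    transcript_pos: int  # anchor base before the event, transcript coords
    kind: str  # insertion | deletion
    base: str
    editing_fraction: float
    genome_contig: str | None = None
    genome_pos: int | None = None  # transcribing-haplotype coords
    ref_pos: int | None = None
    db_id: str | None = None

    def __post_init__(self) -> None:
        assert self.kind in ("insertion", "deletion")
        assert len(self.base) == 1
        assert 0 < self.editing_fraction <= 1


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    phred_qualities: np.ndarray
    truth_transcript: str
    truth_offset: int
    truth_haplotype: str
    truth_strand: str = "+"
    carried_events: tuple[int, ...] = ()  # indices into the db's editing sites


# ---------------------------------------------------------------------------
# indel normalization (left alignment, VCF-style anchoring)


def normalize_indel(seq: str, pos: int, kind: str, allele: str) -> tuple[int, str]:
    """Left-align an indel against ``seq``.

    ``pos`` is the anchor (base before the event); ``allele`` the inserted
    sequence (insertion) or deleted sequence (deletion). Returns the
    normalized (anchor, allele).
    """
    allele = allele.upper()
    while pos > 0:
        if kind == "insertion":
            # inserting `allele` after pos == inserting rotated allele after pos-1
            # iff the base at pos equals the allele's last base
            if seq[pos] == allele[-1]:
                allele = seq[pos] + allele[:-1]
                pos -= 1
                continue
        else:
            # deletion of seq[pos+1 : pos+1+k]
            if seq[pos] == allele[-1]:
                allele = seq[pos] + allele[:-1]
                pos -= 1
                continue
        break
    return pos, allele


# ---------------------------------------------------------------------------
# reference and diploid construction


def build_reference(
    n_contigs: int, contig_length: int, gc: float = 0.41, seed: int = 0
) -> GenomeSet:
    """Forge a random haploid reference genome."""
    if n_contigs <= 0 or contig_length < 1000:
        raise ValueError("need n_contigs >= 1 and contig_length >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    reference = {
        f"chr{i + 1}": random_sequence(contig_length, gc, rng) for i in range(n_contigs)
    }
    return GenomeSet(reference=reference)


def _draw_haplotype_variants(
    contig: str,
    seq: str,
    snp_rate: float,
    indel_rate: float,
    haplotype: str,
    rng: np.random.Generator,
    indel_positions: Sequence[int] | None,
) -> list[TruthVariant]:
    n = len(seq)
    variants: list[TruthVariant] = []
    taken: list[int] = []

    if indel_positions is None:
        raw = np.flatnonzero(rng.random(n) < indel_rate)
        raw = raw[(raw >= 1) & (raw < n - 10)]
    else:
        raw = np.asarray(sorted(indel_positions), dtype=int)
    last = -(10**9)
    for pos in raw.tolist():
        if pos - last < 10:
            continue
        last = pos
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        if kind == "insertion":
            base = BASES[rng.integers(4)]
            npos, allele = normalize_indel(seq, pos, "insertion", base)
            v = TruthVariant(contig, npos, kind, seq[npos], seq[npos] + allele, haplotype)
        else:
            npos, allele = normalize_indel(seq, pos, "deletion", seq[pos + 1])
            v = TruthVariant(contig, npos, kind, seq[npos] + allele, seq[npos], haplotype)
        variants.append(v)
        taken.append(npos)

    if snp_rate > 0:
        blocked = set()
        for p in taken:
            blocked.update(range(p, p + 3))
        for pos in np.flatnonzero(rng.random(n) < snp_rate).tolist():
            if pos in blocked:
                continue
            ref_base = seq[pos]
            if ref_base not in BASES:
                continue
            alt = BASES[(BASES.index(ref_base) + 1 + int(rng.integers(3))) % 4]
            variants.append(TruthVariant(contig, pos, "snp", ref_base, alt, haplotype))
    variants.sort(key=lambda v: v.ref_pos)
    return variants


def apply_truth_variants(reference: str, variants: Iterable[TruthVariant]) -> tuple[str, Liftover]:
    """Apply one haplotype's sorted variants to a reference contig.

    Returns the haplotype sequence and its liftover to the reference.
    """
    parts: list[str] = []
    hap_starts, ref_starts, lengths = [0], [0], []
    cursor = 0
    hap_pos = 0
    block_ref = 0
    block_hap = 0
    for v in variants:
        if v.kind == "snp":
            parts.append(reference[cursor : v.ref_pos])
            parts.append(v.alt_allele)
            hap_pos += v.ref_pos + 1 - cursor
            cursor = v.ref_pos + 1
            continue
        parts.append(reference[cursor : v.ref_pos + 1])
        hap_pos += v.ref_pos + 1 - cursor
        cursor = v.ref_pos + 1
        lengths.append(cursor - block_ref)
        if v.kind == "insertion":
            ins = v.alt_allele[1:]
            parts.append(ins)
            hap_pos += len(ins)
        else:
            cursor += len(v.ref_allele) - 1  # skip deleted bases
        block_ref = cursor
        block_hap = hap_pos
        hap_starts.append(block_hap)
        ref_starts.append(block_ref)
    parts.append(reference[cursor:])
    hap_pos += len(reference) - cursor
    lengths.append(len(reference) - block_ref)
    hap = "".join(parts)
    assert len(hap) == hap_pos
    lift = Liftover(
        np.asarray(hap_starts),
        np.asarray(ref_starts),
        np.asarray(lengths),
        hap_len=len(hap),
        ref_len=len(reference),
    )
    return hap, lift


def derive_diploid(
    genomeset: GenomeSet,
    snp_rate: float,
    indel_rate: float,
    database_fraction: float = 0.0,
    seed: int = 0,
    indel_sites: Sequence[tuple[str, int]] | None = None,
) -> tuple[GenomeSet, list[TruthVariant]]:
    """Derive maternal and paternal haplotypes with independent variant draws.

    ``indel_sites`` optionally pins indel loci (each randomly assigned to one
    haplotype) instead of the per-base rate draw; SNPs always follow the rate.
    Decoy contigs are left reference-only.
    """
    for r in (snp_rate, indel_rate, database_fraction):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if snp_rate > 0.01 or indel_rate > 0.01:
        raise ValueError("per-base variant rates above 0.01 are not supported")
    rng = np.random.default_rng(seed)
    main_contigs = [c for c in genomeset.reference if not c.startswith("paralog")]

    pinned: dict[str, dict[str, list[int]]] = {h: {c: [] for c in main_contigs} for h in ("maternal", "paternal")}
    if indel_sites is not None:
        for contig, pos in indel_sites:
            hap = "maternal" if rng.random() < 0.5 else "paternal"
            pinned[hap][contig].append(pos)

    all_variants: list[TruthVariant] = []
    maternal: dict[str, str] = {}
    paternal: dict[str, str] = {}
    liftover: dict[str, dict[str, Liftover]] = {"maternal": {}, "paternal": {}}
    for hap_name, store in (("maternal", maternal), ("paternal", paternal)):
        for contig in main_contigs:
            seq = genomeset.reference[contig]
            variants = _draw_haplotype_variants(
                contig,
                seq,
                snp_rate,
                indel_rate,
                hap_name,
                rng,
                pinned[hap_name][contig] if indel_sites is not None else None,
            )
            store[contig], liftover[hap_name][contig] = apply_truth_variants(seq, variants)
            all_variants.extend(variants)

    indel_idx = [i for i, v in enumerate(all_variants) if v.kind != "snp"]
    for i in indel_idx:
        if rng.random() < database_fraction:
            all_variants[i].in_database = True

    return (
        GenomeSet(genomeset.reference, maternal, paternal, liftover),
        sorted(all_variants, key=lambda v: (v.contig, v.ref_pos)),
    )


# ---------------------------------------------------------------------------
# gene models, splice traps, paralogs


def _edit(seq: str, pos: int, repl: str) -> str:
    return seq[:pos] + repl + seq[pos + len(repl) :]


def build_gene_models(
    genomeset: GenomeSet,
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 5),
    exon_len_range: tuple[int, int] = (120, 300),
    intron_len_range: tuple[int, int] = (120, 400),
    seed: int = 0,
    min_gap: int = 300,
) -> list[GeneModel]:
    """Place non-overlapping genes and write GT-AG dinucleotides at intron ends.

    Splice signals are written in coding orientation, so minus-strand genes
    carry CT..AC on the plus strand of the reference.
    """
    if intron_len_range[0] < 60:
        raise ValueError("introns shorter than 60 bp are not supported")
    rng = np.random.default_rng(seed)
    contigs = [c for c in genomeset.reference if not c.startswith("paralog")]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, n_exons)
        intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1, max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        placed = False
        for _ in range(200):
            contig = contigs[int(rng.integers(len(contigs)))]
            limit = len(genomeset.reference[contig]) - span - min_gap
            if limit <= min_gap:
                continue
            start = int(rng.integers(min_gap, limit))
            if any(start < e + min_gap and start + span + min_gap > s for s, e in occupied[contig]):
                continue
            occupied[contig].append((start, start + span))
            strand = "+" if gi % 2 == 0 else "-"
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gene = GeneModel(f"g{gi + 1:03d}", contig, strand, exons)
            seq = genomeset.reference[contig]
            donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
            for istart, iend in gene.introns:
                seq = _edit(seq, istart, donor)
                seq = _edit(seq, iend - 2, acceptor)
            genomeset.reference[contig] = seq
            genes.append(gene)
            placed = True
            break
        if not placed:
            raise ValueError("genome too small to place all requested genes")
    return genes


def plant_splice_traps(
    genomeset: GenomeSet,
    genes: Sequence[GeneModel],
    n_traps: int,
    seed: int = 0,
    trap_len: int = 20,
    indel_depth_range: tuple[int, int] = (6, 10),
) -> list[SpliceTrap]:
    """Copy an exon tail (with one 1 bp indel) into the adjacent intron 3' end.

    Junction-spanning reads then admit a full-length gapped genomic alignment
    ending at the downstream exon, planting a spurious indel candidate in the
    intron — the splice-junction false-positive structure. Only plus-strand
    multi-exon genes are used; the donor exon's last two bases are set to AG
    so the copied tail supplies the canonical acceptor signal.
    """
    rng = np.random.default_rng(seed)
    eligible = [
        g
        for g in genes
        if g.strand == "+"
        and len(g.exons) >= 2
        and min(e - s for s, e in g.introns) >= trap_len + 30
    ]
    if len(eligible) < n_traps:
        raise ValueError(f"only {len(eligible)} genes eligible for {n_traps} splice traps")
    traps: list[SpliceTrap] = []
    for g in [eligible[i] for i in rng.permutation(len(eligible))[:n_traps]]:
        intron_i = int(rng.integers(len(g.introns)))
        donor_exon = g.exons[intron_i]
        acceptor = g.introns[intron_i][1]  # == start of the downstream exon
        seq = genomeset.reference[g.contig]
        seq = _edit(seq, donor_exon[1] - 2, "AG")
        tail = seq[donor_exon[1] - trap_len : donor_exon[1]]
        depth = int(rng.integers(indel_depth_range[0], indel_depth_range[1] + 1))
        if rng.random() < 0.5:
            kind = "deletion"  # the copy lacks one base the reads will re-insert
            copy = tail[: trap_len - depth - 1] + tail[trap_len - depth :]
        else:
            kind = "insertion"
            extra = BASES[int(rng.integers(4))]
            copy = tail[: trap_len - depth] + extra + tail[trap_len - depth :]
        start = acceptor - len(copy)
        seq = _edit(seq, start, copy)
        genomeset.reference[g.contig] = seq
        traps.append(
            SpliceTrap(
                gene_id=g.gene_id,
                contig=g.contig,
                acceptor_pos=acceptor,
                kind=kind,
                copy_interval=(start, acceptor),
                indel_anchor=acceptor - depth - 1,
            )
        )
    return traps


def plant_paralogs(
    genomeset: GenomeSet,
    n_pairs: int,
    length: int = 500,
    divergence: float = 0.01,
    seed: int = 0,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    flank: int = 60,
) -> list[ParalogPair]:
    """Create diverged paralog copies of intergenic source intervals.

    Each copy differs from its source by substitutions at the requested
    divergence plus exactly one 1 bp indel (when divergence > 0) and lives on
    a reference-only decoy contig, emulating a locus present in the true
    genome but absent from the assembled haplotypes. Decoy contigs keep the
    copy well separated from the source.
    """
    if length < 200:
        raise ValueError("paralog length must be >= 200")
    if not 0.0 <= divergence <= 0.05:
        raise ValueError("divergence must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    contigs = [c for c in genomeset.reference if not c.startswith("paralog")]
    occupied = {c: list(occupied.get(c, [])) if occupied else [] for c in contigs}
    pairs: list[ParalogPair] = []
    for pi in range(n_pairs):
        placed = False
        for _ in range(300):
            contig = contigs[int(rng.integers(len(contigs)))]
            limit = len(genomeset.reference[contig]) - length - 100
            if limit <= 100:
                continue
            start = int(rng.integers(100, limit))
            if any(start < e + 100 and start + length + 100 > s for s, e in occupied[contig]):
                continue
            occupied[contig].append((start, start + length))
            placed = True
            break
        if not placed:
            raise ValueError("insufficient intergenic space for paralog sources")
        source = genomeset.reference[contig][start : start + length]
        codes = encode(source)
        n_subs = 0
        if divergence > 0:
            # exact substitution count so the planted identity is deterministic
            n_subs = max(1, round(length * divergence)) - 1
            sub_pos = rng.choice(length, size=n_subs, replace=False) if n_subs else np.empty(0, int)
            codes[sub_pos] = (codes[sub_pos] + 1 + rng.integers(0, 3, n_subs)) % 4
        copy = decode(codes)
        indel_kind = indel_base = None
        indel_src = None
        if divergence > 0:
            ipos = int(rng.integers(length // 3, 2 * length // 3))
            if rng.random() < 0.5:
                indel_kind = "insertion"  # copy gains a base relative to source
                indel_base = BASES[int(rng.integers(4))]
                copy = copy[: ipos + 1] + indel_base + copy[ipos + 1 :]
            else:
                indel_kind = "deletion"
                indel_base = copy[ipos + 1]
                copy = copy[: ipos + 1] + copy[ipos + 2 :]
            indel_src = start + ipos
        decoy = f"paralog{pi + 1}"
        left = random_sequence(flank, 0.5, rng)
        right = random_sequence(flank, 0.5, rng)
        genomeset.reference[decoy] = left + copy + right
        identity = (length - n_subs - (1 if indel_kind else 0)) / length
        pairs.append(
            ParalogPair(
                source_contig=contig,
                source_interval=(start, start + length),
                copy_contig=decoy,
                copy_interval=(flank, flank + len(copy)),
                percent_identity=identity,
                indel_kind=indel_kind,
                indel_source_pos=indel_src,
                indel_base=indel_base,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# transcription


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    seq: str
    # per exon, in transcript order: (tx_start, tx_end, g_start, g_end)
    exon_map: list[tuple[int, int, int, int]]
    source_haplotype: str

    @property
    def junctions(self) -> list[int]:
        """Transcript positions of exon-exon boundaries (start of next exon)."""
        return [te for _, te, _, _ in self.exon_map[:-1]]

    def tx_to_genome(self, pos: int) -> int:
        for ts, te, gs, ge in self.exon_map:
            if ts <= pos < te:
                if self.strand == "+":
                    return gs + (pos - ts)
                return ge - 1 - (pos - ts)
        raise IndexError(f"transcript position {pos} outside {self.transcript_id}")

    def genome_to_tx(self, gpos: int) -> int:
        for ts, te, gs, ge in self.exon_map:
            if gs <= gpos < ge:
                if self.strand == "+":
                    return ts + (gpos - gs)
                return ts + (ge - 1 - gpos)
        raise IndexError(f"genome position {gpos} outside exons of {self.transcript_id}")


@dataclass
class JunctionDB:
    """Spliced transcript sequences plus their exon maps for one haplotype."""

    haplotype: str
    transcripts: dict[str, Transcript]
    genes: list[GeneModel]
    editing_sites: list[EditingTruth] = field(default_factory=list)


def transcribe(genomeset: GenomeSet, gene_models: Sequence[GeneModel], haplotype: str) -> JunctionDB:
    """Concatenate exon sequences into transcripts on the chosen haplotype.

    Exon intervals (reference coordinates) are lifted onto the haplotype.
    Genes on contigs absent from an assembled haplotype (paralog decoys) are
    transcribed from the reference — the locus exists in the individual's
    true genome even though the assembly missed it.
    """
    genome = genomeset.haplotype(haplotype)
    transcripts: dict[str, Transcript] = {}
    for gene in gene_models:
        if gene.contig in genome:
            seq = genome[gene.contig]
            source = haplotype
            lift = None if haplotype == "reference" else genomeset.liftover[haplotype][gene.contig]
        else:
            seq = genomeset.reference[gene.contig]
            source = "reference"
            lift = None
        pieces: list[str] = []
        g_intervals: list[tuple[int, int]] = []
        for s, e in gene.exons:
            if lift is not None:
                s, e = lift.map_interval_from_ref(s, e)
            if not (0 <= s < e <= len(seq)):
                raise ValueError(f"exon ({s}, {e}) outside contig {gene.contig}")
            pieces.append(seq[s:e])
            g_intervals.append((s, e))
        if gene.strand == "-":
            tx_seq = revcomp("".join(pieces))
            g_intervals = g_intervals[::-1]
            lens = [e - s for s, e in g_intervals]
        else:
            tx_seq = "".join(pieces)
            lens = [e - s for s, e in g_intervals]
        exon_map = []
        off = 0
        for (s, e), L in zip(g_intervals, lens):
            exon_map.append((off, off + L, s, e))
            off += L
        transcripts[gene.gene_id] = Transcript(
            transcript_id=gene.gene_id,
            gene_id=gene.gene_id,
            contig=gene.contig,
            strand=gene.strand,
            seq=tx_seq,
            exon_map=exon_map,
            source_haplotype=source,
        )
    return JunctionDB(haplotype=haplotype, transcripts=transcripts, genes=list(gene_models))


# ---------------------------------------------------------------------------
# editing injection


def _eligible_editing_position(
    tx: Transcript, pos: int, kind: str, base: str, min_distance: int, max_run: int = 5
) -> bool:
    L = len(tx.seq)
    if not min_distance <= pos < L - min_distance:
        return False
    for j in tx.junctions:
        if abs(pos - j) < min_distance:
            return False
    if kind == "insertion":
        run = 1
        i = pos
        while i >= 0 and tx.seq[i] == base:
            run += 1
            i -= 1
        i = pos + 1
        while i < L and tx.seq[i] == base:
            run += 1
            i += 1
        return run <= max_run
    return run_length_at(tx.seq, pos + 1) <= max_run


def inject_editing(
    junctiondb: JunctionDB,
    n_sites: int,
    editing_fraction: float,
    seed: int = 0,
    min_distance: int = 40,
    min_separation: int = 120,
    kinds: tuple[str, ...] = ("insertion", "deletion"),
    base: str | None = None,
    transcript_ids: Sequence[str] | None = None,
    avoid: dict[str, Sequence[int]] | None = None,
) -> tuple[JunctionDB, list[EditingTruth]]:
    """Plant single-base transcript indels carried by a fraction of molecules.

    Sites stay >= ``min_distance`` bp from transcript ends and junctions and
    outside homopolymer runs longer than 5, so the planted signal is not
    removed by the initial filters. The insert base is configurable rather
    than uridine-only. Sites are attached to the JunctionDB; reads simulated
    from it carry each event with probability ``editing_fraction``.
    """
    if n_sites == 0:
        return junctiondb, []
    rng = np.random.default_rng(seed)
    tx_ids = sorted(transcript_ids) if transcript_ids is not None else sorted(junctiondb.transcripts)
    occupied: dict[str, list[int]] = {}
    for site in junctiondb.editing_sites:
        occupied.setdefault(site.transcript_id, []).append(site.transcript_pos)
    if avoid:
        for tx_id, positions in avoid.items():
            occupied.setdefault(tx_id, []).extend(positions)
    truths: list[EditingTruth] = []
    attempts = 0
    while len(truths) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise ValueError("could not place the requested number of editing sites")
        tx = junctiondb.transcripts[tx_ids[int(rng.integers(len(tx_ids)))]]
        pos = int(rng.integers(0, len(tx.seq)))
        kind = kinds[int(rng.integers(len(kinds)))]
        b = base if base is not None else (BASES[int(rng.integers(4))] if kind == "insertion" else tx.seq[min(pos + 1, len(tx.seq) - 1)])
        if kind == "deletion":
            b = tx.seq[pos + 1] if pos + 1 < len(tx.seq) else tx.seq[pos]
        if not _eligible_editing_position(tx, pos, kind, b, min_distance):
            continue
        if any(abs(pos - p) < min_separation for p in occupied.get(tx.transcript_id, [])):
            continue
        occupied.setdefault(tx.transcript_id, []).append(pos)
        gpos = tx.tx_to_genome(pos)
        truths.append(
            EditingTruth(
                transcript_id=tx.transcript_id,
                transcript_pos=pos,
                kind=kind,
                base=b,
                editing_fraction=editing_fraction,
                genome_contig=tx.contig,
                genome_pos=gpos,
            )
        )
    junctiondb.editing_sites.extend(truths)
    return junctiondb, truths


def editing_genome_event(
    truth: EditingTruth, tx: Transcript, genome_seq: str
) -> tuple[int, str, str]:
    """Project a transcript-level indel onto the genome of its transcribing
    haplotype: returns the left-normalized (anchor, kind, allele).

    For minus-strand transcripts the anchor shifts and the allele is
    complemented, since the event sits between/after different genome bases
    than in transcript orientation.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    g = truth.genome_pos
    if tx.strand == "+":
        anchor, allele = g, truth.base
    else:
        if truth.kind == "insertion":
            anchor, allele = g - 1, comp[truth.base]
        else:
            anchor, allele = g - 2, comp[truth.base]
    pos, allele = normalize_indel(genome_seq, anchor, truth.kind, allele)
    return pos, truth.kind, allele


def resolve_reference_coords(
    truths: Iterable[EditingTruth], junctiondb: JunctionDB, genomeset: GenomeSet
) -> None:
    """Fill in each truth's reference coordinate via the liftover tables."""
    for t in truths:
        tx = junctiondb.transcripts[t.transcript_id]
        if tx.source_haplotype == "reference":
            t.ref_pos = t.genome_pos
        else:
            lift = genomeset.liftover[tx.source_haplotype][tx.contig]
            t.ref_pos, _ = lift.to_ref(t.genome_pos)


def mirror_editing(
    truths: Sequence[EditingTruth], target_db: JunctionDB, genomeset: GenomeSet
) -> list[EditingTruth]:
    """Project editing truths onto the homologous transcripts of another haplotype."""
    mirrored: list[EditingTruth] = []
    for t in truths:
        tx = target_db.transcripts[t.transcript_id]
        if t.ref_pos is None:
            raise ValueError("resolve_reference_coords must run before mirroring")
        if tx.source_haplotype == "reference":
            gpos = t.ref_pos
        else:
            lift = genomeset.liftover[tx.source_haplotype][tx.contig]
            gpos, _ = lift.from_ref(t.ref_pos)
        pos = tx.genome_to_tx(gpos)
        m = replace(t, transcript_pos=pos, genome_pos=gpos)
        mirrored.append(m)
    target_db.editing_sites.extend(mirrored)
    return mirrored


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class QualityProfile:
    """Two-state per-base quality model (high/low Phred scores)."""

    high: int = 37
    low: int = 10
    low_given_error: float = 0.9
    low_given_correct: float = 0.02


def _edited_fragment(tx_seq: str, start: int, length: int, events: list[EditingTruth]) -> str:
    """Extract ``length`` bases starting at unedited position ``start`` after
    applying the carried events (anchors within the visible range)."""
    slack = sum(1 for e in events if e.kind == "deletion") + 2
    window = tx_seq[start : start + length + slack]
    for e in sorted(events, key=lambda e: -e.transcript_pos):
        off = e.transcript_pos - start
        if e.kind == "insertion":
            window = window[: off + 1] + e.base + window[off + 1 :]
        else:
            window = window[: off + 1] + window[off + 2 :]
    return window[:length]


def simulate_reads(
    junctiondb: JunctionDB,
    expression_weights: dict[str, float] | None,
    n_reads: int,
    read_length: int = 33,
    error_rate: float = 0.01,
    quality_profile: QualityProfile | None = None,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[SimulatedRead]:
    """Simulate single-end reads with uniform starts and substitution errors.

    Expression weights default to transcript length (uniform coverage per
    transcript base). Reads from molecules carrying a planted transcript
    indel are built from the edited sequence. Error bases receive the low
    quality state with probability ``low_given_error``.
    """
    if not junctiondb.transcripts:
        raise ValueError("cannot simulate reads from an empty transcript set")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("per-base error rate must lie in [0, 0.05]")
    qp = quality_profile or QualityProfile()
    rng = np.random.default_rng(seed)
    tx_ids = sorted(junctiondb.transcripts)
    txs = [junctiondb.transcripts[t] for t in tx_ids]
    shortest = min(len(t.seq) for t in txs)
    if read_length > shortest:
        raise ValueError(f"read_length {read_length} exceeds shortest transcript ({shortest})")
    if expression_weights is None:
        w = np.array([len(t.seq) for t in txs], dtype=float)
    else:
        w = np.array([expression_weights.get(t, 0.0) for t in tx_ids], dtype=float)
    w = w / w.sum()
    counts = rng.multinomial(n_reads, w)

    sites_by_tx: dict[str, list[tuple[int, EditingTruth]]] = {}
    for gi, site in enumerate(junctiondb.editing_sites):
        sites_by_tx.setdefault(site.transcript_id, []).append((gi, site))

    prefix = id_prefix if id_prefix is not None else junctiondb.haplotype[:3]
    seq_mat = np.empty((n_reads, read_length), dtype=np.uint8)
    meta: list[tuple[str, int, str, tuple[int, ...]]] = []  # tx_id, start, source_hap, events
    row = 0
    for tx, cnt in zip(txs, counts):
        if cnt == 0:
            continue
        L = len(tx.seq)
        starts = rng.integers(0, L - read_length + 1, int(cnt))
        codes = encode(tx.seq)
        site_list = sites_by_tx.get(tx.transcript_id, [])
        for s in starts.tolist():
            carried: list[EditingTruth] = []
            carried_ids: list[int] = []
            for gi, site in site_list:
                if s <= site.transcript_pos < s + read_length - 1 and (
                    site.editing_fraction >= 1.0 or rng.random() < site.editing_fraction
                ):
                    carried.append(site)
                    carried_ids.append(gi)
            if carried:
                frag = _edited_fragment(tx.seq, s, read_length, carried)
                seq_mat[row] = encode(frag)
            else:
                seq_mat[row] = codes[s : s + read_length]
            meta.append((tx.transcript_id, s, tx.source_haplotype, tuple(carried_ids)))
            row += 1
    assert row == n_reads

    # strand of origin
    rev = rng.random(n_reads) < 0.5
    flipped = seq_mat[rev][:, ::-1]
    acgt = flipped < 4
    flipped[acgt] = 3 - flipped[acgt]
    seq_mat[rev] = flipped

    # substitution errors + two-state qualities
    err = rng.random((n_reads, read_length)) < error_rate
    n_err = int(err.sum())
    if n_err:
        seq_mat[err] = (seq_mat[err] + 1 + rng.integers(0, 3, n_err).astype(np.uint8)) % 4
    low = np.where(
        err,
        rng.random((n_reads, read_length)) < qp.low_given_error,
        rng.random((n_reads, read_length)) < qp.low_given_correct,
    )
    quals = np.where(low, qp.low, qp.high).astype(np.int16)

    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        tx_id, s, source_hap, carried_ids = meta[i]
        reads.append(
            SimulatedRead(
                read_id=f"{prefix}_{i:07d}",
                sequence=decode(seq_mat[i]),
                phred_qualities=quals[i].copy(),
                truth_transcript=tx_id,
                truth_offset=int(s),
                truth_haplotype=source_hap if source_hap == "reference" else junctiondb.haplotype,
                truth_strand="-" if rev[i] else "+",
                carried_events=carried_ids,
            )
        )
    return reads
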