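"""Readers and writers for the standard text formats the pipeline exchanges.

Writers emit plain uncompressed FASTA / FASTQ (Phred+33) / GFF3 / VCF / SAM;
readers go through the established parsers (Biopython, gffutils, pysam) so
externally produced files are ingested the same way. All emitted coordinates
are 1-based per format convention; in-memory objects stay 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .align import AlignmentRecord
from .synthetic_data import GeneModel, SimulatedRead, TruthVariant

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_gff3",
    "read_gff3",
    "write_vcf",
    "read_vcf",
    "write_sam",
    "read_sam",
]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.phred_qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            SimulatedRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                phred_qualities=np.asarray(rec.letter_annotations["phred_quality"]),
                truth_transcript="",
                truth_offset=-1,
                truth_haplotype="",
            )
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "indelscope") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.contig}\t{source}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i + 1};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(g, featuretype="exon")
        )
        genes.append(GeneModel(gene_id=g.id, contig=g.seqid, strand=g.strand, exons=exons))
    return genes


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contigs: dict[str, int], extra_info: Sequence[str] = ()) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=indelscope"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind">')
    lines.append('##INFO=<ID=HAP,Number=1,Type=String,Description="Haplotype carrying the variant">')
    lines.extend(extra_info)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_vcf(
    variants: Sequence[TruthVariant],
    contigs: dict[str, int],
    path: str | Path,
    ids: Sequence[str] | None = None,
) -> None:
    """Write truth variants (anchored-base convention, 1-based POS)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs))
        for i, v in enumerate(sorted(variants, key=lambda v: (v.contig, v.ref_pos))):
            vid = ids[i] if ids is not None else "."
            info = f"KIND={v.kind};HAP={v.haplotype}"
            if v.in_database:
                info += ";DB"
            fh.write(
                f"{v.contig}\t{v.ref_pos + 1}\t{vid}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[dict]:
    """Parse a VCF into simple records with 0-based anchored coordinates."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                ref = rec.ref
                if len(alt) > len(ref):
                    kind = "insertion"
                elif len(alt) < len(ref):
                    kind = "deletion"
                else:
                    kind = "snp"
                out.append(
                    dict(
                        contig=rec.contig,
                        pos=rec.pos - 1,
                        id=rec.id,
                        ref=ref,
                        alt=alt,
                        kind=kind,
                        info=dict(rec.info),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# SAM


def sam_header(contigs: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append("@PG\tID:indelscope\tPN:indelscope")
    return "\n".join(lines) + "\n"


def write_sam(
    records: Iterable[AlignmentRecord], contigs: dict[str, int], path: str | Path
) -> None:
    """Write alignment records as SAM 1.x with NM and AS tags."""
    with open(path, "w") as fh:
        fh.write(sam_header(contigs))
        for r in records:
            flag = 16 if r.strand == "-" else 0
            qual = (
                "".join(chr(int(q) + 33) for q in r.base_qualities)
                if r.base_qualities is not None
                else "*"
            )
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig}\t{r.pos + 1}\t{r.mapq}\t"
                f"{r.cigar_string()}\t*\t0\t0\t{r.seq}\t{qual}\t"
                f"NM:i:{r.n_mismatches}\tAS:i:{r.score}\n"
            )


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a SAM file (ours or an external aligner's) into alignment records.

    Soft clips are preserved in the cigar; unmapped records are skipped.
    Malformed records surface as parse errors naming the offending line.
    """
    out = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=True) as sf:
            for ln, rec in enumerate(sf, start=1):
                if rec.is_unmapped:
                    continue
                cigar = [( "MIDNSHP=XB"[op], n) for op, n in rec.cigartuples or []]
                read_len = sum(n for op, n in cigar if op in "MIS=X")
                if rec.query_sequence is not None and read_len != len(rec.query_sequence):
                    raise ValueError(
                        f"{path}: record {ln} ({rec.query_name}): CIGAR length sum "
                        f"{read_len} != sequence length {len(rec.query_sequence)}"
                    )
                cigar = [("M" if op in "=X" else op, n) for op, n in cigar]
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                score = rec.get_tag("AS") if rec.has_tag("AS") else 0
                quals = (
                    np.asarray(rec.query_qualities)
                    if rec.query_qualities is not None
                    else None
                )
                out.append(
                    AlignmentRecord(
                        read_id=rec.query_name,
                        contig=rec.reference_name,
                        pos=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        cigar=cigar,
                        mapq=rec.mapping_quality,
                        score=int(score),
                        n_mismatches=int(nm),
                        seq=(rec.query_sequence or "").upper(),
                        base_qualities=quals,
                    )
                )
    except ValueError:
        raise
    except Exception as exc:  # pysam raises varied exception types on bad input
        raise ValueError(f"malformed SAM file {path}: {exc}") from exc
    return out
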