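"""End-to-end orchestration: forge → align → call → classify → sensitivity.

A run is fully determined by its RunConfig (one master seed; per-stage
sub-seeds derived through numpy SeedSequence spawning, so stages are
individually reproducible). Planted mechanisms are kept spatially separated
— haplotype indels inside exon interiors well away from junctions,
transcript-level injections away from each other and from haplotype indels —
so each candidate's expected label is unambiguous in the truth tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import synthetic_data as sd
from .align import AlignmentRecord, ScoringScheme, SeedIndex, map_reads
from .fp_classify import (
    CATEGORIES,
    ClassificationResult,
    ClassifyParams,
    ClassifyResources,
    classify_cascade,
    gather_supporting_reads,
)
from .pileup_call import CallThresholds, FilterDecision, IndelCandidate, call_indels_from_alignments
from .sensitivity import locate_haplotype_indels, rank_and_select, recovery_fraction

__all__ = [
    "ForgeConfig",
    "RunConfig",
    "ForgeResult",
    "SummaryReport",
    "PipelineResult",
    "forge",
    "run_pipeline",
    "write_report",
    "evaluate_against_truth",
]

REPORT_ROWS = (
    ("initial_candidates", "Initial candidates"),
    ("paternal_alleles", "Paternal alleles"),
    ("splice_junctions", "Splice junctions"),
    ("paralog_sequences", "Paralog sequences"),
    ("known_genomic_variations", "Known genomic variations"),
    ("residual", "Residual"),
)


@dataclass
class ForgeConfig:
    """Study conditions for the synthetic dataset."""

    n_contigs: int = 2
    contig_length: int = 100_000
    gc: float = 0.41
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (2, 5)
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (120, 400)
    n_splice_traps: int = 5
    n_paralog_pairs: int = 5
    paralog_length: int = 500
    paralog_divergence: float = 0.02
    snp_rate: float = 5e-4
    n_haplotype_indels: int = 10
    database_fraction: float = 0.3
    n_database_indels: int = 10
    n_editing_sites: int = 0
    editing_fraction: float = 0.5
    n_reads: int = 200_000
    read_length: int = 33
    error_rate: float = 0.01


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    forge: ForgeConfig = field(default_factory=ForgeConfig)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    seed_length: int = 14
    run_sensitivity: bool = False
    sensitivity_top_n: int = 100
    sensitivity_min_coverage: int = 5
    sensitivity_max_homopolymer: int = 5
    write_artifacts: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "forge" in kwargs:
            fc = dict(kwargs["forge"])
            for key in ("exon_count_range", "exon_len_range", "intron_len_range"):
                if key in fc:
                    fc[key] = tuple(fc[key])
            kwargs["forge"] = ForgeConfig(**fc)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = CallThresholds(**kwargs["thresholds"])
        if "classify" in kwargs:
            kwargs["classify"] = ClassifyParams(**kwargs["classify"])
        if "scoring" in kwargs:
            kwargs["scoring"] = ScoringScheme(**kwargs["scoring"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ForgeResult:
    genomeset: sd.GenomeSet
    genes: list[sd.GeneModel]  # all genes including paralog-copy genes
    main_genes: list[sd.GeneModel]
    traps: list[sd.SpliceTrap]
    paralogs: list[sd.ParalogPair]
    variants: list[sd.TruthVariant]
    misassemblies: list[sd.EditingTruth]
    editing: list[sd.EditingTruth]
    db_maternal: sd.JunctionDB
    db_paternal: sd.JunctionDB
    db_reference: sd.JunctionDB
    reads: list[sd.SimulatedRead]
    known_records: list[dict]

    def reference_event(self, truth: sd.EditingTruth) -> tuple[str, int, str, str]:
        """Reference-level (contig, anchor, kind, allele) of a transcript event."""
        tx = self.db_maternal.transcripts[truth.transcript_id]
        gs = self.genomeset
        if tx.source_haplotype == "reference":
            seq = gs.reference[tx.contig]
            anchor, kind, allele = sd.editing_genome_event(truth, tx, seq)
            return tx.contig, anchor, kind, allele
        anchor_m, kind, allele = sd.editing_genome_event(truth, tx, gs.maternal[tx.contig])
        ra, _ = gs.liftover["maternal"][tx.contig].to_ref(anchor_m)
        ra, allele = sd.normalize_indel(gs.reference[tx.contig], ra, kind, allele)
        return tx.contig, ra, kind, allele


@dataclass
class SummaryReport:
    initial_candidates: int = 0
    paternal_alleles: int = 0
    splice_junctions: int = 0
    paralog_sequences: int = 0
    known_genomic_variations: int = 0
    residual: int = 0
    n_reads: int = 0
    n_mapped: int = 0
    raw_candidate_sites: int = 0

    def check_partition(self) -> None:
        total = (
            self.paternal_alleles
            + self.splice_junctions
            + self.paralog_sequences
            + self.known_genomic_variations
            + self.residual
        )
        if total != self.initial_candidates:
            raise ValueError(
                f"category counts sum to {total} but initial_candidates is "
                f"{self.initial_candidates}"
            )


@dataclass
class PipelineResult:
    config: RunConfig
    forge: ForgeResult
    alignments: list[AlignmentRecord]
    candidates: list[IndelCandidate]
    decisions: list[FilterDecision]
    depth: dict[str, np.ndarray]
    classifications: list[ClassificationResult]
    summary: SummaryReport
    truth_eval: dict
    sensitivity: dict | None = None


# ---------------------------------------------------------------------------
# forging


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(master).spawn(n)]


def forge(config: ForgeConfig, seed: int) -> ForgeResult:
    """Build the complete synthetic study: genome, structures, truth, reads."""
    seeds = _spawn_seeds(seed, 12)
    gs = sd.build_reference(config.n_contigs, config.contig_length, config.gc, seed=seeds[0])
    genes = sd.build_gene_models(
        gs,
        config.n_genes,
        config.exon_count_range,
        config.exon_len_range,
        config.intron_len_range,
        seed=seeds[1],
    )
    traps = sd.plant_splice_traps(gs, genes, config.n_splice_traps, seed=seeds[2])
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in gs.reference}
    for g in genes:
        occupied[g.contig].append(g.span)
    pairs = sd.plant_paralogs(
        gs,
        config.n_paralog_pairs,
        config.paralog_length,
        config.paralog_divergence,
        seed=seeds[3],
        occupied=occupied,
    )

    # haplotype indels: exon interiors, clear of junctions and of each other
    rng = np.random.default_rng(seeds[4])
    sites: list[tuple[str, int]] = []
    if config.n_haplotype_indels:
        order = rng.permutation(len(genes))
        for gi in order:
            if len(sites) >= config.n_haplotype_indels:
                break
            g = genes[int(gi)]
            xs, xe = max(g.exons, key=lambda x: x[1] - x[0])
            if xe - xs < 100:
                continue
            sites.append((g.contig, int(rng.integers(xs + 45, xe - 45))))
        if len(sites) < config.n_haplotype_indels:
            raise ValueError("not enough genes with roomy exons for haplotype indels")
    gs, variants = sd.derive_diploid(
        gs,
        config.snp_rate,
        indel_rate=0.0,
        database_fraction=config.database_fraction,
        seed=seeds[5],
        indel_sites=sites if sites else None,
    )

    copy_genes = [
        sd.GeneModel(f"pg{i + 1:02d}", p.copy_contig, "+", [p.copy_interval])
        for i, p in enumerate(pairs)
    ]
    all_genes = genes + copy_genes
    db_m = sd.transcribe(gs, all_genes, "maternal")
    db_p = sd.transcribe(gs, all_genes, "paternal")
    db_ref = sd.transcribe(gs, all_genes, "reference")

    main_ids = [g.gene_id for g in genes]
    avoid: dict[str, list[int]] = {}
    for v in variants:
        if v.kind == "snp":
            continue
        for g in genes:
            if g.contig == v.contig and any(s <= v.ref_pos < e for s, e in g.exons):
                tx = db_m.transcripts[g.gene_id]
                try:
                    am, _ = gs.liftover["maternal"][g.contig].from_ref(v.ref_pos)
                    avoid.setdefault(g.gene_id, []).append(tx.genome_to_tx(am))
                except IndexError:
                    pass

    db_m, mis = sd.inject_editing(
        db_m,
        config.n_database_indels,
        editing_fraction=1.0,
        seed=seeds[6],
        transcript_ids=main_ids,
        avoid=avoid,
    )
    sd.resolve_reference_coords(mis, db_m, gs)
    for i, m in enumerate(mis):
        m.db_id = f"rs9{i:05d}"
    sd.mirror_editing(mis, db_p, gs)

    editing: list[sd.EditingTruth] = []
    if config.n_editing_sites:
        db_m, editing = sd.inject_editing(
            db_m,
            config.n_editing_sites,
            config.editing_fraction,
            seed=seeds[7],
            transcript_ids=main_ids,
            avoid=avoid,
        )
        sd.resolve_reference_coords(editing, db_m, gs)
        sd.mirror_editing(editing, db_p, gs)

    half = config.n_reads // 2
    reads_m = sd.simulate_reads(
        db_m, None, half, config.read_length, config.error_rate, seed=seeds[8], id_prefix="m"
    )
    reads_p = sd.simulate_reads(
        db_p,
        None,
        config.n_reads - half,
        config.read_length,
        config.error_rate,
        seed=seeds[9],
        id_prefix="p",
    )

    result = ForgeResult(
        genomeset=gs,
        genes=all_genes,
        main_genes=genes,
        traps=traps,
        paralogs=pairs,
        variants=variants,
        misassemblies=mis,
        editing=editing,
        db_maternal=db_m,
        db_paternal=db_p,
        db_reference=db_ref,
        reads=reads_m + reads_p,
        known_records=[],
    )
    known: list[dict] = []
    for m in mis:
        contig, anchor, kind, allele = result.reference_event(m)
        a = gs.reference[contig][anchor]
        known.append(
            dict(
                contig=contig,
                pos=anchor,
                kind=kind,
                ref=a + (allele if kind == "deletion" else ""),
                alt=a + (allele if kind == "insertion" else ""),
                id=m.db_id,
            )
        )
    for v in variants:
        if v.kind != "snp" and v.in_database:
            known.append(
                dict(
                    contig=v.contig,
                    pos=v.ref_pos,
                    kind=v.kind,
                    ref=v.ref_allele,
                    alt=v.alt_allele,
                    id=None,
                )
            )
    result.known_records = known
    return result


# ---------------------------------------------------------------------------
# truth evaluation


def evaluate_against_truth(
    candidates: Sequence[IndelCandidate],
    classifications: Sequence[ClassificationResult],
    fr: ForgeResult,
    res: ClassifyResources,
    window: int = 5,
) -> dict:
    """Compare labels with the planted mechanisms.

    Mechanism-derived candidates are those near a planted structure; chance
    junction artifacts are tallied separately (any splice-junction label is
    correct for them, but they do not enter the accuracy numerator or
    denominator).
    """
    hap_sites = {(v.contig, v.ref_pos) for v in fr.variants if v.kind != "snp"}
    trap_iv = [(t.contig, t.copy_interval[0] - 4, t.acceptor_pos + 4) for t in fr.traps]
    par_sites = {
        (p.source_contig, p.indel_source_pos) for p in fr.paralogs if p.indel_source_pos is not None
    }
    mis_sites = {fr.reference_event(m)[:2] for m in fr.misassemblies}
    edit_sites = {fr.reference_event(e)[:2] for e in fr.editing}

    def expected(cand: IndelCandidate) -> str:
        rp, _ = res.candidate_ref_coords(cand)
        if any(cand.contig == c and abs(rp - p) <= window for c, p in hap_sites):
            return "paternal_allele"
        if any(cand.contig == c and s <= rp < e for c, s, e in trap_iv):
            return "splice_junction"
        if any(cand.contig == c and abs(rp - p) <= window for c, p in par_sites):
            return "paralog"
        if any(cand.contig == c and abs(rp - p) <= window for c, p in mis_sites):
            return "known_variant"
        if any(cand.contig == c and abs(rp - p) <= window for c, p in edit_sites):
            return "residual"
        return "unattributed"

    per_candidate = []
    n_mech = n_mech_correct = 0
    for cand, cls in zip(candidates, classifications):
        exp = expected(cand)
        correct = cls.label == exp if exp != "unattributed" else None
        if exp != "unattributed":
            n_mech += 1
            n_mech_correct += int(bool(correct))
        per_candidate.append({"expected": exp, "label": cls.label, "correct": correct})

    # editing retention: fraction of planted sites recovered as residual
    residual_positions = [
        res.candidate_ref_coords(c.candidate) for c in classifications if c.label == "residual"
    ]
    retained = 0
    for contig, pos in edit_sites:
        if any(abs(rp - pos) <= window for rp, _ in residual_positions):
            retained += 1
    return {
        "per_candidate": per_candidate,
        "n_mechanism_derived": n_mech,
        "n_mechanism_correct": n_mech_correct,
        "label_accuracy": (n_mech_correct / n_mech) if n_mech else 1.0,
        "n_editing_planted": len(edit_sites),
        "n_editing_retained": retained,
        "editing_retention": (retained / len(edit_sites)) if edit_sites else 1.0,
    }


# ---------------------------------------------------------------------------
# the run


def run_pipeline(config: RunConfig) -> PipelineResult:
    t_start = time.time()
    manifest: list[dict] = []

    def log(stage: str, **counts) -> None:
        manifest.append({"stage": stage, "elapsed_s": round(time.time() - t_start, 2), **counts})

    fr = forge(config.forge, seed=config.seed)
    log("forge", n_reads=len(fr.reads), n_genes=len(fr.genes), n_variants=len(fr.variants))

    index = SeedIndex(fr.genomeset.maternal, seed_length=config.seed_length)
    mapped = [r for r in map_reads(fr.reads, index, config.scoring) if r is not None]
    mapped.sort(key=lambda r: (r.contig, r.pos))
    log("align", n_mapped=len(mapped))

    candidates, decisions, depth = call_indels_from_alignments(
        mapped, fr.genomeset.maternal, config.thresholds
    )
    log("call", raw_sites=len(decisions), passing=len(candidates))

    res = ClassifyResources(
        genomeset=fr.genomeset,
        junction_db=fr.db_reference,
        known_variants=fr.known_records,
        scoring=config.scoring,
        params=config.classify,
    )
    support = gather_supporting_reads(candidates, mapped, fr.genomeset.maternal, config.thresholds)
    classifications, counts = classify_cascade(candidates, support, res)
    log("classify", **{k: v for k, v in counts.items()})

    summary = SummaryReport(
        initial_candidates=counts["initial_candidates"],
        paternal_alleles=counts["paternal_allele"],
        splice_junctions=counts["splice_junction"],
        paralog_sequences=counts["paralog"],
        known_genomic_variations=counts["known_variant"],
        residual=counts["residual"],
        n_reads=len(fr.reads),
        n_mapped=len(mapped),
        raw_candidate_sites=len(decisions),
    )
    summary.check_partition()
    truth_eval = evaluate_against_truth(candidates, classifications, fr, res)

    sens = None
    if config.run_sensitivity:
        index_p = SeedIndex(fr.genomeset.paternal, seed_length=config.seed_length)
        mapped_p = [r for r in map_reads(fr.reads, index_p, config.scoring) if r is not None]
        mapped_p.sort(key=lambda r: (r.contig, r.pos))
        cands_p, _, _ = call_indels_from_alignments(
            mapped_p, fr.genomeset.paternal, config.thresholds
        )
        sites = locate_haplotype_indels(fr.genomeset, fr.variants)
        selected = rank_and_select(
            sites,
            depth,
            top_n=config.sensitivity_top_n,
            min_coverage=config.sensitivity_min_coverage,
            max_homopolymer=config.sensitivity_max_homopolymer,
        )
        sens = recovery_fraction(selected, candidates, cands_p)
        log(
            "sensitivity",
            n_sites=sens["n_sites"],
            maternal_only=round(sens["maternal_only"], 4),
            combined=round(sens["combined"], 4),
        )

    result = PipelineResult(
        config=config,
        forge=fr,
        alignments=mapped,
        candidates=candidates,
        decisions=decisions,
        depth=depth,
        classifications=classifications,
        summary=summary,
        truth_eval=truth_eval,
        sensitivity=sens,
    )
    if config.outdir and config.write_artifacts:
        _write_artifacts(result, manifest)
    return result


# ---------------------------------------------------------------------------
# reporting and artifacts


def render_report(summary: SummaryReport, fmt: str = "tsv") -> str:
    """Render the category table (Table-1 layout plus a Residual row)."""
    summary.check_partition()
    rows = [(label, getattr(summary, key)) for key, label in REPORT_ROWS]
    if fmt == "tsv":
        return "".join(f"{label}\t{value}\n" for label, value in rows)
    if fmt == "markdown":
        out = ["| Category | Count |", "| --- | --- |"]
        out += [f"| {label} | {value} |" for label, value in rows]
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def write_report(summary: SummaryReport, path: str | Path, fmt: str = "tsv") -> None:
    text = render_report(summary, fmt)
    with open(path, "w") as fh:
        fh.write(text)


def _write_artifacts(result: PipelineResult, manifest: list[dict]) -> None:
    from . import io as iomod

    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fr = result.forge
    gs = fr.genomeset

    iomod.write_fasta(gs.reference, outdir / "reference.fa")
    iomod.write_fasta(gs.maternal, outdir / "maternal.fa")
    iomod.write_fasta(gs.paternal, outdir / "paternal.fa")
    iomod.write_gff3(fr.genes, outdir / "genes.gff3")
    iomod.write_fasta(
        {t.transcript_id: t.seq for t in fr.db_reference.transcripts.values()},
        outdir / "transcripts.fa",
    )
    iomod.write_fastq(fr.reads, outdir / "reads.fastq")
    contigs = {c: len(s) for c, s in gs.reference.items()}
    iomod.write_vcf(fr.variants, contigs, outdir / "truth_variants.vcf")
    _write_known_vcf(fr.known_records, contigs, outdir / "known_variants.vcf")
    iomod.write_sam(result.alignments, {c: len(s) for c, s in gs.maternal.items()}, outdir / "alignments.sam")
    _write_candidates_vcf(result, outdir / "candidates.vcf")
    _write_audit_tsv(result.decisions, outdir / "filter_audit.tsv")
    _write_classification_tsv(result, outdir / "classification.tsv")
    write_report(result.summary, outdir / "summary.tsv", "tsv")
    write_report(result.summary, outdir / "summary.md", "markdown")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(asdict(result.summary), fh, indent=2)
    result.config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(outdir / "truth_eval.json", "w") as fh:
        json.dump(
            {k: v for k, v in result.truth_eval.items() if k != "per_candidate"}, fh, indent=2
        )
    if result.sensitivity is not None:
        with open(outdir / "sensitivity.json", "w") as fh:
            json.dump(
                {k: v for k, v in result.sensitivity.items() if k != "flags"}, fh, indent=2
            )


def _write_known_vcf(records: Sequence[dict], contigs: dict[str, int], path: Path) -> None:
    from .io import _vcf_header

    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs))
        for r in sorted(records, key=lambda r: (r["contig"], r["pos"])):
            vid = r.get("id") or "."
            fh.write(
                f"{r['contig']}\t{r['pos'] + 1}\t{vid}\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
                f"KIND={r['kind']};DB\n"
            )


def _write_candidates_vcf(result: PipelineResult, path: Path) -> None:
    from .io import _vcf_header

    gs = result.forge.genomeset
    contigs = {c: len(s) for c, s in gs.maternal.items()}
    extra = [
        '##INFO=<ID=NSUP,Number=1,Type=Integer,Description="Indel-supporting reads">',
        '##INFO=<ID=NTOT,Number=1,Type=Integer,Description="Covering reads">',
        '##INFO=<ID=HRUN,Number=1,Type=Integer,Description="Homopolymer run">',
        "##reference=maternal haplotype coordinates",
    ]
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, extra))
        for c in result.candidates:
            seq = gs.maternal[c.contig]
            a = seq[c.pos]
            if c.kind == "insertion":
                ref, alt = a, a + c.seq
            else:
                ref, alt = a + c.seq, a
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{ref}\t{alt}\t{c.variant_qual:.0f}\tPASS\t"
                f"KIND={c.kind};NSUP={c.n_support};NTOT={c.n_total};HRUN={c.homopolymer_run}\n"
            )


def _write_audit_tsv(decisions: Sequence[FilterDecision], path: Path) -> None:
    import pandas as pd

    rows = []
    for d in decisions:
        c = d.candidate
        rows.append(
            dict(
                contig=c.contig,
                pos=c.pos,
                kind=c.kind,
                seq=c.seq,
                n_support=c.n_support,
                n_total=c.n_total,
                support_fraction=round(c.support_fraction, 4),
                variant_qual=c.variant_qual,
                homopolymer_run=c.homopolymer_run,
                n_alleles=len(c.allele_set),
                passed=d.passed,
                failed_rules=",".join(d.failed_rules),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_classification_tsv(result: PipelineResult, path: Path) -> None:
    import pandas as pd

    rows = []
    for cls, ev in zip(result.classifications, result.truth_eval["per_candidate"]):
        c = cls.candidate
        rows.append(
            dict(
                contig=c.contig,
                pos=c.pos,
                kind=c.kind,
                seq=c.seq,
                n_support=c.n_support,
                n_total=c.n_total,
                label=cls.label,
                expected=ev["expected"],
                evidence=json.dumps(cls.evidence, default=str),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
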