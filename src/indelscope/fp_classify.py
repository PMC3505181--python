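"""False-positive elimination cascade for indel RNA-DNA difference candidates.

Every candidate that survives the initial filters is assigned exactly one
label, applying the filters in a fixed order and stopping at the first match:

1. paternal_allele — the apparent indel is a genuine maternal-paternal
   difference: every indel-supporting read aligns full-length and gaplessly
   to the homologous paternal locus (both the all-paternal and the mixed
   maternal/paternal read patterns satisfy this).
2. splice_junction — the candidate is a misaligned junction-spanning read
   artifact, recognized by three joint criteria against a single transcript
   overlapping the candidate locus: (1) the genomic surrounding sequence
   (32 bp either side, without the indel) aligns gaplessly at the expected
   reference position; (2) only part of that genomic window aligns gaplessly
   to the transcript; (3) the indel-including sequence — the edited window,
   or failing that the supporting reads themselves — aligns to the same
   transcript gaplessly over its full length.
3. paralog — the edited window aligns gaplessly (few mismatches) at some
   other reference locus: the "indel" is genomic sequence of a diverged
   duplicate missing from the assembled haplotypes.
4. known_variant — the indel matches a database-annotated genomic indel
   after left-alignment normalization, most plausibly a misassembly.

Candidates matching no filter are residual: putative indel RNA-DNA
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import AlignmentRecord, ScoringScheme, SeedIndex
from .dna import encode, revcomp
from .pileup_call import IndelCandidate
from .synthetic_data import GenomeSet, JunctionDB, Liftover, normalize_indel

__all__ = [
    "ClassifyParams",
    "ClassifyResources",
    "FlankPair",
    "ClassificationResult",
    "extract_flanks",
    "check_paternal_allele",
    "check_splice_junction",
    "check_paralog",
    "check_known_variant",
    "classify_cascade",
    "CATEGORIES",
]

CATEGORIES = (
    "paternal_allele",
    "splice_junction",
    "paralog",
    "known_variant",
    "residual",
)


@dataclass
class ClassifyParams:
    flank: int = 32  # window half-width around the anchor
    partial_max: float = 0.9  # criterion 2: aligned fraction must stay below this
    min_anchor: int = 15  # criterion 2: and cover at least this many bases
    mm_max: int = 3  # gapless alignments may carry up to this many mismatches
    paralog_mm_max: int = 6  # divergence allowance (~90% identity over the window)
    full_min: float = 0.95  # paralog: minimum aligned fraction of the window
    read_match_min_fraction: float = 0.9  # criterion 3 via supporting reads
    paternal_mm_max: int = 3
    own_locus_margin: int = 200  # paralog hits closer than this are the site itself
    known_window: int = 5  # positional tolerance for database matches of the same kind/size


@dataclass
class FlankPair:
    """Genomic surrounding sequence of a candidate, without and with the indel."""

    contig: str
    anchor: int  # mapping-haplotype coordinates
    window_start: int
    genomic_window: str
    edited_window: str
    anchor_offset: int  # anchor position within genomic_window


@dataclass
class ClassificationResult:
    candidate: IndelCandidate
    label: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.label in CATEGORIES
        assert self.evidence or self.label == "residual"


@dataclass
class ClassifyResources:
    """Everything the cascade consults besides the candidates themselves."""

    genomeset: GenomeSet
    junction_db: JunctionDB  # reference-derived, unedited transcripts
    known_variants: list[dict]  # normalized known indels (read_vcf records)
    ref_index: SeedIndex | None = None
    scoring: ScoringScheme = ScoringScheme()
    params: ClassifyParams = field(default_factory=ClassifyParams)
    mapping_haplotype: str = "maternal"

    def __post_init__(self) -> None:
        if self.ref_index is None:
            self.ref_index = SeedIndex(self.genomeset.reference, seed_length=14)
        self._tx_kmers: dict[int, list[tuple[str, int]]] = {}
        k = self._tx_k = 12
        for tx_id, tx in self.junction_db.transcripts.items():
            codes = encode(tx.seq)
            for i in range(len(tx.seq) - k + 1):
                window = codes[i : i + k]
                if (window >= 4).any():
                    continue
                code = 0
                for c in window.tolist():
                    code = code * 4 + c
                self._tx_kmers.setdefault(code, []).append((tx_id, i))
        self._gene_span = {}
        for g in self.junction_db.genes:
            self._gene_span[g.gene_id] = (g.contig, g.span[0], g.span[1])
        self._known_normalized = set()
        self._known_ids: dict[tuple, str] = {}
        for rec in self.known_variants:
            if rec["kind"] == "snp":
                continue
            if rec["kind"] == "insertion":
                allele = rec["alt"][1:]
            else:
                allele = rec["ref"][1:]
            ref_seq = self.genomeset.reference.get(rec["contig"])
            pos = rec["pos"]
            if ref_seq is not None:
                pos, allele = normalize_indel(ref_seq, pos, rec["kind"], allele)
            key = (rec["contig"], pos, rec["kind"], allele)
            self._known_normalized.add(key)
            if rec.get("id"):
                self._known_ids[key] = rec["id"]

    @property
    def mapping_genome(self) -> dict[str, str]:
        return self.genomeset.haplotype(self.mapping_haplotype)

    def liftover(self, contig: str) -> Liftover:
        return self.genomeset.liftover[self.mapping_haplotype][contig]

    def candidate_ref_coords(self, cand: IndelCandidate) -> tuple[int, str]:
        """Reference anchor of a candidate, re-normalized against the reference."""
        ref_pos, _ = self.liftover(cand.contig).to_ref(cand.pos)
        return normalize_indel(self.genomeset.reference[cand.contig], ref_pos, cand.kind, cand.seq)


# ---------------------------------------------------------------------------
# gapless alignment helpers


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(((a != b) | (a >= 4) | (b >= 4)).sum())


def _best_segment(matches: np.ndarray, mismatch_penalty: int = 3) -> tuple[int, int]:
    """Best-scoring contiguous run (match +1 / mismatch −penalty); returns
    (start, end) of the maximal segment."""
    score = np.where(matches, 1, -mismatch_penalty)
    best = cur = 0
    best_s = best_e = cur_s = 0
    for i, s in enumerate(score.tolist()):
        if cur <= 0:
            cur = s
            cur_s = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_s, best_e = cur_s, i + 1
    return best_s, best_e


def _window_vs_transcript(
    window: np.ndarray, tx_seq: str, tx_codes: np.ndarray, diagonals: set[int], mm_max: int
) -> tuple[int, bool, int]:
    """(best ungapped span, full-length gapless hit, mismatches of that hit)."""
    L = window.size
    T = tx_codes.size
    best_span = 0
    full = False
    full_mm = -1
    for d in sorted(diagonals):
        lo = max(0, -d)
        hi = min(L, T - d)
        if hi - lo <= 0:
            continue
        seg = tx_codes[lo + d : hi + d]
        w = window[lo:hi]
        matches = (w == seg) & (w < 4) & (seg < 4)
        if lo == 0 and hi == L:
            mm = int((~matches).sum())
            if mm <= mm_max:
                full = True
                full_mm = mm if full_mm < 0 else min(full_mm, mm)
        s, e = _best_segment(matches)
        best_span = max(best_span, e - s)
    return best_span, full, full_mm


def _transcript_diagonals(res: ClassifyResources, window: np.ndarray) -> dict[tuple[str, int], set[int]]:
    """Seed-vote diagonals per (transcript, orientation 0/1)."""
    k = res._tx_k
    out: dict[tuple[str, int], set[int]] = {}
    for orient, w in ((0, window), (1, _revcomp_codes(window))):
        n = w.size
        for i in range(n - k + 1):
            sub = w[i : i + k]
            if (sub >= 4).any():
                continue
            code = 0
            for c in sub.tolist():
                code = code * 4 + c
            for tx_id, tpos in res._tx_kmers.get(code, ()):
                out.setdefault((tx_id, orient), set()).add(tpos - i)
    return out


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


# ---------------------------------------------------------------------------
# flank extraction


def extract_flanks(
    cand: IndelCandidate, genome: dict[str, str], flank: int = 32
) -> FlankPair:
    """Surrounding sequence from ``flank`` bp upstream through ``flank`` bp
    downstream of the anchor, without and with the candidate indel applied.

    Windows are truncated at contig ends, with the anchor offset recorded.
    """
    seq = genome[cand.contig]
    ws = max(0, cand.pos - flank)
    we = min(len(seq), cand.pos + flank + 1)
    genomic = seq[ws:we]
    off = cand.pos - ws
    if cand.kind == "insertion":
        edited = genomic[: off + 1] + cand.seq + genomic[off + 1 :]
    else:
        edited = genomic[: off + 1] + genomic[off + 1 + len(cand.seq) :]
        # keep the window length balanced by extending downstream
        ext = seq[we : we + len(cand.seq)]
        edited += ext
    return FlankPair(
        contig=cand.contig,
        anchor=cand.pos,
        window_start=ws,
        genomic_window=genomic,
        edited_window=edited,
        anchor_offset=off,
    )


# ---------------------------------------------------------------------------
# individual filters


def check_paternal_allele(
    cand: IndelCandidate,
    supporting_reads: Sequence[AlignmentRecord],
    res: ClassifyResources,
) -> tuple[bool | None, dict]:
    """Do all indel-supporting reads fit the homologous paternal locus gaplessly?

    Returns (matched, evidence); matched None signals an unresolvable
    paternal locus (the candidate passes to the next filter with a warning).
    """
    p = res.params
    try:
        ref_pos, _ = res.liftover(cand.contig).to_ref(cand.pos)
        pat_lift = res.genomeset.liftover["paternal"][cand.contig]
        pat_pos, _ = pat_lift.from_ref(ref_pos)
        pat_seq = res.genomeset.paternal[cand.contig]
    except (KeyError, IndexError):
        return None, {"warning": "paternal locus not resolvable via liftover"}
    if not supporting_reads:
        return False, {}
    max_len = max(r.read_length for r in supporting_reads)
    ws = max(0, pat_pos - max_len - 8)
    we = min(len(pat_seq), pat_pos + max_len + 8)
    window = encode(pat_seq[ws:we])
    matched_at = []
    for r in supporting_reads:
        q = encode(r.seq)
        L = q.size
        if window.size < L:
            return False, {}
        best_mm, best_off = L + 1, -1
        for off in range(window.size - L + 1):
            mm = _hamming(q, window[off : off + L])
            if mm < best_mm:
                best_mm, best_off = mm, off
        # the gapless paternal explanation must both be clean and score at
        # least as well as the read's gapped placement on the mapping haplotype
        gapless_score = (L - best_mm) * res.scoring.match - best_mm * res.scoring.mismatch
        if best_mm > p.paternal_mm_max or gapless_score < r.score:
            return False, {}
        matched_at.append(ws + best_off)
    return True, {
        "paternal_contig": cand.contig,
        "paternal_pos": pat_pos,
        "n_reads_matched": len(matched_at),
        "read_starts": matched_at[:10],
    }


def check_splice_junction(
    cand: IndelCandidate,
    flanks: FlankPair,
    supporting_reads: Sequence[AlignmentRecord],
    res: ClassifyResources,
) -> tuple[bool, dict]:
    """Three-way splice-junction artifact test against a single transcript."""
    p = res.params
    ref = res.genomeset.reference.get(cand.contig)
    if ref is None:
        return False, {}
    ref_pos, _ = res.liftover(cand.contig).to_ref(cand.pos)

    # criterion 1: genomic window aligns gaplessly at the expected reference locus
    ws = ref_pos - flanks.anchor_offset
    if ws < 0 or ws + len(flanks.genomic_window) > len(ref):
        return False, {}
    gw = encode(flanks.genomic_window)
    if _hamming(gw, encode(ref[ws : ws + gw.size])) > p.mm_max:
        return False, {}

    # transcripts must overlap the candidate's reference locus
    local_tx = [
        tx_id
        for tx_id, (c, s, e) in res._gene_span.items()
        if c == cand.contig and s - 50 <= ref_pos < e + 50
    ]
    if not local_tx:
        return False, {}

    gw_diag = _transcript_diagonals(res, gw)
    ew = encode(flanks.edited_window)
    ew_diag = _transcript_diagonals(res, ew)

    read_codes = [encode(r.seq) for r in supporting_reads]
    for tx_id in local_tx:
        tx = res.junction_db.transcripts[tx_id]
        tx_codes = encode(tx.seq)

        # criterion 2: only part of the genomic window aligns gaplessly
        span = 0
        g_full = False
        for orient in (0, 1):
            diags = gw_diag.get((tx_id, orient))
            if not diags:
                continue
            w = gw if orient == 0 else _revcomp_codes(gw)
            s, f, _ = _window_vs_transcript(w, tx.seq, tx_codes, diags, p.mm_max)
            span = max(span, s)
            g_full = g_full or f
        if g_full or span < p.min_anchor or span >= p.partial_max * gw.size:
            continue

        # criterion 3: the indel-including sequence fully fits the same transcript
        e_full = False
        e_mm = -1
        for orient in (0, 1):
            diags = ew_diag.get((tx_id, orient))
            if not diags:
                continue
            w = ew if orient == 0 else _revcomp_codes(ew)
            _, f, mm = _window_vs_transcript(w, tx.seq, tx_codes, diags, p.mm_max)
            if f:
                e_full = True
                e_mm = mm
                break
        reads_ok = 0
        if not e_full and read_codes:
            for q in read_codes:
                if _read_fits_transcript(q, tx_codes, p.mm_max):
                    reads_ok += 1
            # tolerate one unmatched read (sequencing errors) in small
            # support sets, a 10% minority in large ones
            unmatched = len(read_codes) - reads_ok
            if reads_ok == 0 or unmatched > max(
                1, int(len(read_codes) * (1 - p.read_match_min_fraction))
            ):
                continue
        elif not e_full:
            continue
        return True, {
            "transcript": tx_id,
            "partial_span": span,
            "edited_window_full": e_full,
            "edited_window_mismatches": e_mm,
            "supporting_reads_matched": reads_ok if not e_full else None,
        }
    return False, {}


def _read_fits_transcript(q: np.ndarray, tx_codes: np.ndarray, mm_max: int) -> bool:
    """Full-length ungapped fit of a read (either orientation) in a transcript."""
    L = q.size
    T = tx_codes.size
    if T < L:
        return False
    for w in (q, _revcomp_codes(q)):
        # seed on the first 12 bases to restrict offsets
        k = min(12, L)
        seed = w[:k]
        view = np.lib.stride_tricks.sliding_window_view(tx_codes, k)
        hits = np.flatnonzero((view == seed).all(axis=1))
        for off in hits.tolist():
            if off + L <= T and _hamming(w, tx_codes[off : off + L]) <= mm_max:
                return True
        # mismatches may fall in the seed: try a second anchor
        seed2 = w[L - k :]
        hits = np.flatnonzero((view == seed2).all(axis=1))
        for h in hits.tolist():
            off = h - (L - k)
            if 0 <= off and off + L <= T and _hamming(w, tx_codes[off : off + L]) <= mm_max:
                return True
    return False


def check_paralog(
    cand: IndelCandidate, flanks: FlankPair, res: ClassifyResources
) -> tuple[bool, dict]:
    """Gapless full-window alignment of the edited window elsewhere in the reference."""
    p = res.params
    idx = res.ref_index
    ew = encode(flanks.edited_window)
    L = ew.size
    ref_pos, _ = res.liftover(cand.contig).to_ref(cand.pos)
    own = idx.global_start(cand.contig) + ref_pos
    k = idx.seed_length
    G = idx.codes
    for w, orient in ((ew, 0), (_revcomp_codes(ew), 1)):
        starts: set[int] = set()
        for i in range(0, L - k + 1, 4):
            sub = w[i : i + k]
            if (sub >= 4).any():
                continue
            code = 0
            for c in sub.tolist():
                code = code * 4 + c
            lo = int(np.searchsorted(idx._sorted_kmers, code, side="left"))
            hi = int(np.searchsorted(idx._sorted_kmers, code, side="right"))
            if hi - lo > 4 * idx.max_hits:
                continue
            for pos in idx._sorted_pos[lo:hi].tolist():
                starts.add(pos - i)
        for s in sorted(starts):
            if s < 0 or s + L > G.size:
                continue
            anchor_g = s + flanks.anchor_offset
            if abs(anchor_g - own) <= p.own_locus_margin:
                continue
            seg = G[s : s + L]
            if (seg >= 4).any():  # crosses a contig boundary
                continue
            if _hamming(w, seg) <= p.paralog_mm_max:
                contig, local = idx.locate(s)
                return True, {
                    "paralog_contig": contig,
                    "paralog_pos": local,
                    "orientation": "-" if orient else "+",
                    "mismatches": _hamming(w, seg),
                }
    return False, {}


def check_known_variant(cand: IndelCandidate, res: ClassifyResources) -> tuple[bool, dict]:
    """Match against database indels after left-alignment normalization.

    An exact normalized (pos, kind, sequence) match is preferred; failing
    that, a database indel of the same kind and size within the
    left-alignment-equivalence window still matches — sequencing errors at
    the discriminating base can shift a real variant's called representation
    by a base or two.
    """
    pos, allele = res.candidate_ref_coords(cand)
    key = (cand.contig, pos, cand.kind, allele)
    if key in res._known_normalized:
        return True, {
            "database_id": res._known_ids.get(key, "."),
            "ref_pos": pos,
            "allele": allele,
        }
    for kkey in res._known_normalized:
        kcontig, kpos, kkind, kallele = kkey
        if (
            kcontig == cand.contig
            and kkind == cand.kind
            and len(kallele) == len(allele)
            and abs(kpos - pos) <= res.params.known_window
        ):
            return True, {
                "database_id": res._known_ids.get(kkey, "."),
                "ref_pos": kpos,
                "allele": kallele,
                "shifted": True,
            }
    return False, {}


# ---------------------------------------------------------------------------
# cascade


def classify_cascade(
    candidates: Sequence[IndelCandidate],
    supporting_reads: Sequence[Sequence[AlignmentRecord]],
    res: ClassifyResources,
) -> tuple[list[ClassificationResult], dict[str, int]]:
    """Assign each candidate exactly one label, filters in the fixed order
    paternal → splice junction → paralog → known variant, first match wins.

    Returns (results, category counts including ``initial_candidates``).
    """
    results: list[ClassificationResult] = []
    counts = {c: 0 for c in CATEGORIES}
    counts["initial_candidates"] = len(candidates)
    for cand, reads in zip(candidates, supporting_reads):
        flanks = extract_flanks(cand, res.mapping_genome, res.params.flank)
        matched, ev = check_paternal_allele(cand, reads, res)
        if matched:
            results.append(ClassificationResult(cand, "paternal_allele", ev))
            counts["paternal_allele"] += 1
            continue
        warning = ev.get("warning") if matched is None else None
        ok, ev = check_splice_junction(cand, flanks, reads, res)
        if ok:
            results.append(ClassificationResult(cand, "splice_junction", ev))
            counts["splice_junction"] += 1
            continue
        ok, ev = check_paralog(cand, flanks, res)
        if ok:
            results.append(ClassificationResult(cand, "paralog", ev))
            counts["paralog"] += 1
            continue
        ok, ev = check_known_variant(cand, res)
        if ok:
            results.append(ClassificationResult(cand, "known_variant", ev))
            counts["known_variant"] += 1
            continue
        ev = {"warning": warning} if warning else {}
        results.append(ClassificationResult(cand, "residual", ev))
        counts["residual"] += 1
    return results, counts


def gather_supporting_reads(
    candidates: Sequence[IndelCandidate],
    alignments: Sequence[AlignmentRecord],
    genome: dict[str, str],
    thresholds=None,
) -> list[list[AlignmentRecord]]:
    """Collect, per candidate, the alignment records whose (normalized) indel
    events match the candidate's site and allele.

    The same read-level criteria the caller applied (mapping quality, indel
    distance to the read end, mismatch cap, duplicates) are enforced, so the
    cascade judges each candidate on the reads that produced its statistics.
    """
    from .pileup_call import CallThresholds, _duplicate_flags, _read_events

    th = thresholds or CallThresholds()
    index: dict[tuple[str, int, str, str], int] = {
        (c.contig, c.pos, c.kind, c.seq): i for i, c in enumerate(candidates)
    }
    out: list[list[AlignmentRecord]] = [[] for _ in candidates]
    for rec, dup in zip(alignments, _duplicate_flags(alignments)):
        if dup or rec.mapq < th.min_mapping_quality:
            continue
        if len(rec.cigar) == 1 and rec.cigar[0][0] == "M":
            continue
        if rec.n_mismatches > th.max_read_mismatches:
            continue
        events = _read_events(rec, genome[rec.contig])
        if any(e["dist"] < th.min_end_distance for e in events):
            continue
        for e in events:
            key = (rec.contig, e["pos"], e["kind"], e["seq"])
            if key in index and e["qual"] >= th.min_base_quality:
                out[index[key]].append(rec)
    return out
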