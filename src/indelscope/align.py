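"""Seed-and-extend gapped read mapping against a haplotype genome.

The mapper indexes the genome with contiguous k-mer seeds, gathers candidate
alignment locations (CALs) for each read on both strands, and evaluates each
candidate with an affine-gap alignment. Seeds returning more than ``max_hits``
locations are ignored as repetitive, and the CAL count per read is capped.
Only full-length placements are reported: a read whose best alignment would
clip bases is unmapped, enforced by using a fitting (query-global) alignment
plus a minimum-score threshold. The pairwise aligner is also reused by the
false-positive filters.

Deliberately not splice-aware: junction-spanning reads either fail the score
threshold or are forced into gapped genomic placements — the artifact class
the downstream filters must recognize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _sw
from .dna import decode, encode, revcomp

__all__ = [
    "ScoringScheme",
    "AlignmentRecord",
    "SeedIndex",
    "smith_waterman_affine",
    "fitting_align",
    "compute_mapq",
    "map_read",
    "map_reads",
]

DEFAULT_MAX_CANDIDATES = 1280  # cap on CALs per read
DEFAULT_MAX_HITS = 8  # lookups above this are repetitive


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scores; a gap of length k costs gap_open + k * gap_extend.

    Defaults are chosen so a single 1 bp indel (penalty 7) outscores three
    mismatches in a short read, the regime in which gapped mappers report
    indels at all.
    """

    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("match must be positive and penalties non-negative")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


@dataclass
class AlignmentRecord:
    """One read's gapped placement (0-based leftmost position)."""

    read_id: str
    contig: str
    pos: int
    strand: str
    cigar: list[tuple[str, int]]
    mapq: int
    score: int
    n_mismatches: int
    seq: str  # aligned orientation (reverse-complemented for '-')
    base_qualities: np.ndarray | None = None

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        return self.pos + self.ref_span

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def _merge_ops(ops: list[str]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar


def _traceback(H, E, F, q, t, i, j, scoring, stop_at_zero: bool):
    """Shared traceback; prefers the diagonal at ties (fewer gaps)."""
    go_ge = scoring.gap_open + scoring.gap_extend
    ge = scoring.gap_extend
    ops: list[str] = []
    while i > 0 and (not stop_at_zero or H[i, j] > 0):
        if j > 0 and i > 0:
            s = scoring.match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else -scoring.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
                continue
        if j > 0 and H[i, j] == E[i, j]:
            while True:
                ops.append("D")
                if E[i, j] == H[i, j - 1] - go_ge:
                    j -= 1
                    break
                E_prev = E[i, j - 1]
                j -= 1
                if E[i, j + 1] != E_prev - ge:  # defensive; should not happen
                    break
            continue
        if H[i, j] == F[i, j]:
            while True:
                ops.append("I")
                if F[i, j] == H[i - 1, j] - go_ge:
                    i -= 1
                    break
                i -= 1
            continue
        break  # H==0 in local mode, or i reached 0
    ops.reverse()
    return _merge_ops(ops), i, j


def smith_waterman_affine(
    query: str, target: str, scoring: ScoringScheme = ScoringScheme()
) -> tuple[int, list[tuple[str, int]], tuple[int, int], tuple[int, int]]:
    """Optimal affine-gap local alignment.

    Returns (score, cigar, (query_start, query_end), (target_start,
    target_end)). A zero-score optimum returns an empty cigar. Ties are broken
    deterministically: the end cell with the smallest target then query
    coordinate, and the diagonal preferred during traceback (fewer gaps).
    ``N`` matches nothing, including another ``N``.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q = encode(query)
    t = encode(target)
    H, E, F = _sw.local_matrices(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    best = int(H.max())
    if best == 0:
        return 0, [], (0, 0), (0, 0)
    cells = np.argwhere(H == best)
    cells = cells[np.lexsort((cells[:, 0], cells[:, 1]))]
    ei, ej = int(cells[0][0]), int(cells[0][1])
    cigar, si, sj = _traceback(H, E, F, q, t, ei, ej, scoring, stop_at_zero=True)
    return best, cigar, (si, ei), (sj, ej)


def fitting_align(
    query: str | np.ndarray, target: str | np.ndarray, scoring: ScoringScheme = ScoringScheme()
) -> tuple[int, list[tuple[str, int]], int]:
    """Align the full query within a local target span.

    Returns (score, cigar, target_start); the cigar consumes the entire
    query (ops M/I/D, never S). Edge deletions are trimmed.
    """
    q = encode(query) if isinstance(query, str) else query
    t = encode(target) if isinstance(target, str) else target
    if q.size == 0 or t.size == 0:
        raise ValueError("query and target must be non-empty")
    H, E, F = _sw.fitting_matrices(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    n = q.shape[0]
    best_j = int(np.argmax(H[n]))
    score = int(H[n, best_j])
    cigar, _, sj = _traceback(H, E, F, q, t, n, best_j, scoring, stop_at_zero=False)
    # trim edge deletions (they only pad the reference span)
    while cigar and cigar[0][0] == "D":
        sj += cigar.pop(0)[1]
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    return score, cigar, sj


def alignment_mismatches(cigar: Sequence[tuple[str, int]], q: np.ndarray, t: np.ndarray, tstart: int) -> int:
    """Count mismatching bases in M ops of an alignment."""
    qi, ti = 0, tstart
    mm = 0
    for op, n in cigar:
        if op == "M":
            a = q[qi : qi + n]
            b = t[ti : ti + n]
            mm += int(((a != b) | (a >= 4) | (b >= 4)).sum())
            qi += n
            ti += n
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n
    return mm


# ---------------------------------------------------------------------------
# seed index


class SeedIndex:
    """Exact k-mer index over a genome (all contigs concatenated).

    ``lookup`` returns every position of a seed; seeds occurring more than
    ``max_hits`` times are flagged repetitive and contribute no candidate
    locations.
    """

    SEP = 80  # N-run separating contigs in the concatenated array

    def __init__(self, genome: dict[str, str], seed_length: int = 14, max_hits: int = DEFAULT_MAX_HITS):
        if not 4 <= seed_length <= 20:
            raise ValueError("seed_length must lie in [4, 20]")
        self.seed_length = seed_length
        self.max_hits = max_hits
        self.contig_names = list(genome)
        self.contig_lengths = {c: len(genome[c]) for c in self.contig_names}
        parts = []
        self._offsets = np.empty(len(self.contig_names), dtype=np.int64)
        off = 0
        sep = np.full(self.SEP, 4, dtype=np.uint8)
        for i, c in enumerate(self.contig_names):
            self._offsets[i] = off
            parts.append(encode(genome[c]))
            off += len(genome[c])
            parts.append(sep)
            off += self.SEP
        self.codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        k = seed_length
        n = self.codes.size
        if n >= k:
            kmers = np.zeros(n - k + 1, dtype=np.int64)
            bad = np.zeros(n - k + 1, dtype=bool)
            for i in range(k):
                col = self.codes[i : i + n - k + 1]
                kmers = kmers * 4 + col
                bad |= col >= 4
            pos = np.flatnonzero(~bad)
            kmers = kmers[pos]
            order = np.argsort(kmers, kind="stable")
            self._sorted_kmers = kmers[order]
            self._sorted_pos = pos[order]
        else:
            self._sorted_kmers = np.empty(0, dtype=np.int64)
            self._sorted_pos = np.empty(0, dtype=np.int64)

    def global_start(self, contig: str) -> int:
        return int(self._offsets[self.contig_names.index(contig)])

    def locate(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        return self.contig_names[i], gpos - int(self._offsets[i])

    def _seed_code(self, seed: str) -> int | None:
        codes = encode(seed)
        if (codes >= 4).any():
            return None
        code = 0
        for c in codes.tolist():
            code = code * 4 + c
        return code

    def hit_count(self, seed: str) -> int:
        code = self._seed_code(seed)
        if code is None:
            return 0
        lo = int(np.searchsorted(self._sorted_kmers, code, side="left"))
        hi = int(np.searchsorted(self._sorted_kmers, code, side="right"))
        return hi - lo

    def is_repetitive(self, seed: str) -> bool:
        return self.hit_count(seed) > self.max_hits

    def lookup(self, seed: str) -> list[tuple[str, int]]:
        """All (contig, position) hits of a seed; empty if absent or repetitive."""
        if len(seed) != self.seed_length:
            raise ValueError(f"seed length must be {self.seed_length}")
        code = self._seed_code(seed)
        if code is None:
            return []
        lo = int(np.searchsorted(self._sorted_kmers, code, side="left"))
        hi = int(np.searchsorted(self._sorted_kmers, code, side="right"))
        if hi - lo > self.max_hits:
            return []
        return [self.locate(int(p)) for p in self._sorted_pos[lo:hi]]

    def lookup_global(self, codes_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (lo, hi) ranges into the sorted position array."""
        lo = np.searchsorted(self._sorted_kmers, codes_arr, side="left")
        hi = np.searchsorted(self._sorted_kmers, codes_arr, side="right")
        return lo, hi


# ---------------------------------------------------------------------------
# mapping quality


def compute_mapq(best_score: int, second_score: int | None, score_range: int) -> int:
    """Phred-scaled placement confidence on a 0-60 scale.

    0 when the two best placements tie, 60 when there is no second candidate,
    otherwise monotone in the score gap. The scale is a contract, not a
    reproduction of any particular mapper's formula.
    """
    if second_score is None:
        return 60
    if best_score < second_score:
        raise ValueError("best_score must be >= second_score")
    if best_score == second_score:
        return 0
    gap = best_score - second_score
    return int(min(60, max(1, round(200.0 * gap / max(score_range, 1)))))


# ---------------------------------------------------------------------------
# read mapping


def _seed_offsets(read_len: int, k: int) -> list[int]:
    if read_len < k:
        return []
    offs = {0, (read_len - k) // 2, read_len - k}
    return sorted(offs)


def _candidate_starts(
    seq: str, index: SeedIndex, max_candidates: int
) -> list[tuple[int, int]]:
    """(strand, global_start) candidates for one read; strand 0=fwd, 1=rev."""
    k = index.seed_length
    out: set[tuple[int, int]] = set()
    for strand, s in ((0, seq), (1, revcomp(seq))):
        for off in _seed_offsets(len(seq), k):
            seed = s[off : off + k]
            code = index._seed_code(seed)
            if code is None:
                continue
            lo = int(np.searchsorted(index._sorted_kmers, code, side="left"))
            hi = int(np.searchsorted(index._sorted_kmers, code, side="right"))
            if hi == lo or hi - lo > index.max_hits:
                continue
            for p in index._sorted_pos[lo:hi].tolist():
                start = p - off
                if 0 <= start <= index.codes.size - len(seq):
                    out.add((strand, start))
            if len(out) >= max_candidates:
                break
    return sorted(out)[:max_candidates]


def _within_one_contig(index: SeedIndex, gstart: int, span: int) -> bool:
    c1, p1 = index.locate(gstart)
    return p1 + span <= index.contig_lengths[c1]


def map_read(
    read_id: str,
    seq: str,
    index: SeedIndex,
    scoring: ScoringScheme = ScoringScheme(),
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    max_penalty: int = 16,
    quals: np.ndarray | None = None,
    pad: int = 6,
) -> AlignmentRecord | None:
    """Map one read; returns the best full-length placement or None.

    Reference single-read implementation; ``map_reads`` is the batched
    equivalent used by the pipeline.
    """
    L = len(seq)
    if L < index.seed_length:
        return None
    min_score = L * scoring.match - max_penalty
    cands = _candidate_starts(seq, index, max_candidates)
    if not cands:
        return None
    q_fwd = encode(seq)
    q_rev = encode(revcomp(seq))
    G = index.codes

    # gapless pass
    best_mm = L + 1
    gapless: list[tuple[int, int, int]] = []  # (score, strand, start)
    for strand, start in cands:
        q = q_rev if strand else q_fwd
        w = G[start : start + L]
        mm = int(((w != q) | (w >= 4) | (q >= 4)).sum())
        gapless.append(((L - mm) * scoring.match - mm * scoring.mismatch, strand, start))
        best_mm = min(best_mm, mm)

    alignments: dict[tuple[int, int], tuple[int, list[tuple[str, int]], int]] = {}
    if best_mm <= 1:
        # a gapless placement with <=1 mismatch is provably optimal
        for sc, strand, start in gapless:
            key = (strand, start)
            if key not in alignments or sc > alignments[key][0]:
                alignments[key] = (sc, [("M", L)], start)
    else:
        for strand, start in cands:
            q = q_rev if strand else q_fwd
            ws = max(start - pad, 0)
            window = G[ws : start + L + pad]
            sc, cigar, toff = fitting_align(q, window, scoring)
            gpos = ws + toff
            key = (strand, gpos)
            if key not in alignments or sc > alignments[key][0]:
                alignments[key] = (sc, cigar, gpos)

    ranked = sorted(
        (
            (sc, sum(1 for op, _ in cig if op in "ID"), gpos, strand, cig)
            for (strand, gpos), (sc, cig, _) in alignments.items()
        ),
        key=lambda r: (-r[0], r[1], r[2], r[3]),
    )
    best = ranked[0]
    score, _, gpos, strand, cigar = best
    if score < min_score:
        return None
    span = sum(n for op, n in cigar if op in "MD")
    if not _within_one_contig(index, gpos, span):
        return None
    second = next((r[0] for r in ranked[1:] if abs(r[2] - gpos) > 3 or r[3] != strand), None)
    q = q_rev if strand else q_fwd
    nm = alignment_mismatches(cigar, q, G, gpos)
    contig, local = index.locate(gpos)
    out_quals = None
    if quals is not None:
        out_quals = np.asarray(quals)[::-1].copy() if strand else np.asarray(quals).copy()
    return AlignmentRecord(
        read_id=read_id,
        contig=contig,
        pos=local,
        strand="-" if strand else "+",
        cigar=cigar,
        mapq=compute_mapq(score, second, L * scoring.match),
        score=score,
        n_mismatches=nm,
        seq=decode(q),
        base_qualities=out_quals,
    )


def _batch_poly(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.zeros(mat.shape[0], dtype=np.int64)
    bad = np.zeros(mat.shape[0], dtype=bool)
    for i in range(k):
        col = mat[:, i]
        c = c * 4 + col
        bad |= col >= 4
    return c, ~bad


def map_reads(
    reads: Sequence,
    index: SeedIndex,
    scoring: ScoringScheme = ScoringScheme(),
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    max_penalty: int = 16,
    pad: int = 6,
) -> list[AlignmentRecord | None]:
    """Batched mapper: vectorized seeding and gapless scoring, affine DP only
    for reads whose best gapless placement has >= 2 mismatches.

    ``reads`` are SimulatedRead-like objects (read_id, sequence,
    phred_qualities) of uniform length. Result order matches input; unmapped
    reads yield None.
    """
    n = len(reads)
    if n == 0:
        return []
    L = len(reads[0].sequence)
    if any(len(r.sequence) != L for r in reads):
        raise ValueError("map_reads requires uniform read length")
    k = index.seed_length
    min_score = L * scoring.match - max_penalty
    G = index.codes
    Gn = G.size

    FWD = np.empty((n, L), dtype=np.uint8)
    for i, r in enumerate(reads):
        FWD[i] = encode(r.sequence)
    RC = FWD[:, ::-1].copy()
    acgt = RC < 4
    RC[acgt] = 3 - RC[acgt]

    cand_read: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    for strand, M in ((0, FWD), (1, RC)):
        for off in _seed_offsets(L, k):
            codes, valid = _batch_poly(M[:, off : off + k], k)
            lo, hi = index.lookup_global(codes)
            cnt = hi - lo
            sel = valid & (cnt > 0) & (cnt <= index.max_hits)
            idxs = np.flatnonzero(sel)
            if idxs.size == 0:
                continue
            c = cnt[sel]
            total = int(c.sum())
            rep = np.repeat(idxs, c)
            csum = np.concatenate(([0], np.cumsum(c)))
            within = np.arange(total) - np.repeat(csum[:-1], c)
            hitpos = index._sorted_pos[np.repeat(lo[sel], c) + within]
            starts = hitpos - off
            ok = (starts >= 0) & (starts <= Gn - L)
            cand_read.append(rep[ok])
            cand_strand.append(np.full(int(ok.sum()), strand, dtype=np.int64))
            cand_start.append(starts[ok])

    results: list[AlignmentRecord | None] = [None] * n
    if not cand_read:
        return results
    ri = np.concatenate(cand_read)
    st = np.concatenate(cand_strand)
    sp = np.concatenate(cand_start)
    key = (ri * 2 + st) * Gn + sp
    key = np.unique(key)
    sp = key % Gn
    st = (key // Gn) % 2
    ri = key // (2 * Gn)

    m = key.size
    mm = np.empty(m, dtype=np.int64)
    CH = 1 << 19
    for c0 in range(0, m, CH):
        c1 = min(c0 + CH, m)
        W = G[sp[c0:c1, None] + np.arange(L)]
        R = np.empty_like(W)
        f = st[c0:c1] == 0
        R[f] = FWD[ri[c0:c1][f]]
        R[~f] = RC[ri[c0:c1][~f]]
        mm[c0:c1] = ((W != R) | (W >= 4) | (R >= 4)).sum(axis=1)
    score = (L - mm) * scoring.match - mm * scoring.mismatch

    order = np.lexsort((sp, st, -score, ri))
    ri_o, st_o, sp_o, sc_o, mm_o = ri[order], st[order], sp[order], score[order], mm[order]
    seg_first = np.flatnonzero(np.concatenate(([True], ri_o[1:] != ri_o[:-1])))
    seg_end = np.concatenate((seg_first[1:], [m]))

    for si in range(seg_first.size):
        a, b = int(seg_first[si]), int(seg_end[si])
        read_i = int(ri_o[a])
        r = reads[read_i]
        if int(mm_o[a]) <= 1:
            best_sc = int(sc_o[a])
            if best_sc < min_score:
                continue
            gpos, strand = int(sp_o[a]), int(st_o[a])
            if not _within_one_contig(index, gpos, L):
                continue
            second = None
            for j in range(a + 1, b):
                if abs(int(sp_o[j]) - gpos) > 3 or int(st_o[j]) != strand:
                    second = int(sc_o[j])
                    break
            q = RC[read_i] if strand else FWD[read_i]
            contig, local = index.locate(gpos)
            quals = np.asarray(r.phred_qualities)
            results[read_i] = AlignmentRecord(
                read_id=r.read_id,
                contig=contig,
                pos=local,
                strand="-" if strand else "+",
                cigar=[("M", L)],
                mapq=compute_mapq(best_sc, second, L * scoring.match),
                score=best_sc,
                n_mismatches=int(mm_o[a]),
                seq=decode(q),
                base_qualities=quals[::-1].copy() if strand else quals.copy(),
            )
        else:
            # gapped evaluation of every candidate of this read
            evals: list[tuple[int, int, int, int]] = []  # score, strand, start, row
            for j in range(a, min(b, a + max_candidates)):
                strand, start = int(st_o[j]), int(sp_o[j])
                ws = max(start - pad, 0)
                window = G[ws : start + L + pad]
                q = RC[read_i] if strand else FWD[read_i]
                sc, _ = _sw.fitting_score(
                    q, window, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
                )
                evals.append((int(sc), strand, start, j))
            evals.sort(key=lambda e: (-e[0], e[1], e[2]))
            best_sc, strand, start, _ = evals[0]
            if best_sc < min_score:
                continue
            q = RC[read_i] if strand else FWD[read_i]
            ws = max(start - pad, 0)
            window = G[ws : start + L + pad]
            sc, cigar, toff = fitting_align(q, window, scoring)
            gpos = ws + toff
            span = sum(nn for op, nn in cigar if op in "MD")
            if not _within_one_contig(index, gpos, span):
                continue
            second = None
            for e in evals[1:]:
                if abs(e[2] - start) > 3 or e[1] != strand:
                    second = e[0]
                    break
            nm = alignment_mismatches(cigar, q, G, gpos)
            contig, local = index.locate(gpos)
            quals = np.asarray(r.phred_qualities)
            results[read_i] = AlignmentRecord(
                read_id=r.read_id,
                contig=contig,
                pos=local,
                strand="-" if strand else "+",
                cigar=cigar,
                mapq=compute_mapq(sc, second, L * scoring.match),
                score=int(sc),
                n_mismatches=nm,
                seq=decode(q),
                base_qualities=quals[::-1].copy() if strand else quals.copy(),
            )
    return results
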