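"""Pipeline sensitivity: recovery of known maternal-paternal indel differences.

The protocol mirrors the detection pipeline's own validation: locate every
single-base indel difference between the two haplotypes (from the truth
liftover when available, otherwise by whole-contig alignment), rank the
sites by read coverage, drop homopolymer-prone sites, and measure what
fraction of the covered sites the caller recovers before any false-positive
filtering — both from maternal-genome calling alone and with maternal and
paternal calling combined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dna import run_length_at
from .pileup_call import IndelCandidate
from .synthetic_data import GenomeSet, TruthVariant

__all__ = [
    "HaplotypeIndelSite",
    "locate_haplotype_indels",
    "locate_haplotype_indels_by_alignment",
    "rank_and_select",
    "recovery_fraction",
]


@dataclass
class HaplotypeIndelSite:
    contig: str
    ref_pos: int  # reference anchor
    maternal_pos: int
    paternal_pos: int
    kind: str  # insertion | deletion, relative to the reference
    seq: str
    haplotype: str  # which haplotype carries the variant
    coverage: int = 0
    homopolymer_run: int = 1

    @property
    def direction(self) -> str:
        """Which haplotype is longer at the site (method-independent form)."""
        if self.kind == "insertion":
            longer = self.haplotype
        else:
            longer = "paternal" if self.haplotype == "maternal" else "maternal"
        return f"{longer}_longer"


def locate_haplotype_indels(
    genomeset: GenomeSet, variants: Sequence[TruthVariant]
) -> list[HaplotypeIndelSite]:
    """Single-base indel differences between the haplotypes via the truth tables.

    A variant contributes a site when exactly one haplotype carries it (a
    variant present identically in both is no maternal-paternal difference).
    """
    keyed: dict[tuple, set[str]] = {}
    recs: dict[tuple, TruthVariant] = {}
    for v in variants:
        if v.kind == "snp":
            continue
        allele = v.alt_allele[1:] if v.kind == "insertion" else v.ref_allele[1:]
        if len(allele) != 1:
            continue
        key = (v.contig, v.ref_pos, v.kind, allele)
        keyed.setdefault(key, set()).add(v.haplotype)
        recs[key] = v
    sites = []
    for key, haps in sorted(keyed.items()):
        if len(haps) != 1:
            continue
        contig, ref_pos, kind, allele = key
        mp, _ = genomeset.liftover["maternal"][contig].from_ref(ref_pos)
        pp, _ = genomeset.liftover["paternal"][contig].from_ref(ref_pos)
        ref = genomeset.reference[contig]
        if kind == "deletion":
            run = run_length_at(ref, min(ref_pos + 1, len(ref) - 1))
        else:
            run = 1 + sum(
                1
                for i in (ref_pos, ref_pos + 1)
                if 0 <= i < len(ref) and ref[i] == allele
            )
        sites.append(
            HaplotypeIndelSite(
                contig=contig,
                ref_pos=ref_pos,
                maternal_pos=mp,
                paternal_pos=pp,
                kind=kind,
                seq=allele,
                haplotype=next(iter(haps)),
                homopolymer_run=run,
            )
        )
    return sites


def locate_haplotype_indels_by_alignment(genomeset: GenomeSet) -> list[HaplotypeIndelSite]:
    """Locate single-base maternal-paternal indels by anchored global alignment.

    Independent of the truth tables: each shared contig's maternal sequence
    is globally aligned against the paternal one and 1 bp gaps are read off
    the alignment path. Coordinates are reported in both haplotypes; the
    reference anchor is approximated through the maternal liftover.
    """
    import edlib

    sites: list[HaplotypeIndelSite] = []
    for contig in genomeset.maternal:
        if contig not in genomeset.paternal:
            raise ValueError(f"contig {contig} missing from the paternal haplotype")
        mat = genomeset.maternal[contig]
        pat = genomeset.paternal[contig]
        aln = edlib.align(mat, pat, mode="NW", task="path")
        mi = pi = 0
        for n, op in _parse_edlib_cigar(aln["cigar"]):
            if op in "=X":
                mi += n
                pi += n
            elif op == "I":  # consumes query (maternal): maternal has extra bases
                if n == 1:
                    sites.append(
                        _alignment_site(genomeset, contig, mi - 1, pi - 1, "maternal", mat[mi])
                    )
                mi += n
            elif op == "D":  # consumes target (paternal): paternal has extra bases
                if n == 1:
                    sites.append(
                        _alignment_site(genomeset, contig, mi - 1, pi - 1, "paternal", pat[pi])
                    )
                pi += n
    return sites


def _parse_edlib_cigar(cigar: str):
    import re

    for m in re.finditer(r"(\d+)([=XIDM])", cigar):
        yield int(m.group(1)), m.group(2)


def _alignment_site(
    genomeset: GenomeSet, contig: str, mpos: int, ppos: int, haplotype: str, base: str
) -> HaplotypeIndelSite:
    ref_pos, _ = genomeset.liftover["maternal"][contig].to_ref(mpos)
    return HaplotypeIndelSite(
        contig=contig,
        ref_pos=ref_pos,
        maternal_pos=mpos,
        paternal_pos=ppos,
        kind="insertion",
        seq=base,
        haplotype=haplotype,
        homopolymer_run=run_length_at(genomeset.reference[contig], min(ref_pos + 1, len(genomeset.reference[contig]) - 1)),
    )


def rank_and_select(
    sites: Sequence[HaplotypeIndelSite],
    depth: dict[str, np.ndarray] | None = None,
    top_n: int = 100,
    min_coverage: int = 5,
    max_homopolymer: int = 5,
) -> list[HaplotypeIndelSite]:
    """Rank sites by read coverage and keep the expressed, non-homopolymer top.

    ``depth`` holds per-contig coverage on the maternal genome (the calling
    haplotype); when given, each site's coverage is filled from it. Ties are
    broken by coordinate.
    """
    out = []
    for s in sites:
        if depth is not None:
            d = depth.get(s.contig)
            s.coverage = int(d[s.maternal_pos]) if d is not None and 0 <= s.maternal_pos < d.size else 0
        if s.homopolymer_run > max_homopolymer:
            continue
        if s.coverage < min_coverage:
            continue
        out.append(s)
    out.sort(key=lambda s: (-s.coverage, s.contig, s.ref_pos))
    return out[:top_n]


def _matches(site: HaplotypeIndelSite, cand: IndelCandidate, pos: int, window: int = 5) -> bool:
    return cand.contig == site.contig and abs(cand.pos - pos) <= window and cand.size == 1


def recovery_fraction(
    selected_sites: Sequence[HaplotypeIndelSite],
    candidates_maternal: Sequence[IndelCandidate],
    candidates_paternal: Sequence[IndelCandidate] | None = None,
) -> dict:
    """Fraction of selected sites recovered by the caller.

    A site counts as found when a single-base candidate lies within a small
    window of the site on the calling haplotype's coordinates. Returns both
    the maternal-only and the combined (maternal ∪ paternal) fractions along
    with per-site flags.
    """
    flags = []
    for s in selected_sites:
        found_m = any(_matches(s, c, s.maternal_pos) for c in candidates_maternal)
        found_p = (
            any(_matches(s, c, s.paternal_pos) for c in candidates_paternal)
            if candidates_paternal is not None
            else False
        )
        flags.append((s, found_m, found_p))
    n = len(flags)
    if n == 0:
        return {"maternal_only": 0.0, "combined": 0.0, "n_sites": 0, "flags": []}
    maternal_only = sum(1 for _, m, _ in flags if m) / n
    combined = sum(1 for _, m, p in flags if m or p) / n
    return {
        "maternal_only": maternal_only,
        "combined": combined,
        "n_sites": n,
        "flags": flags,
    }
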