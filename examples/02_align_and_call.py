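"""Map reads to the maternal haplotype and call indel candidates.

The seed-and-extend mapper reports only full-length gapped placements;
the caller builds a pileup, left-aligns every indel event, and applies the
initial filter set (base/mapping quality, end proximity, mismatch cap,
support, coverage, fraction, allele count, indel size, homopolymer).
"""

import indelscope as ix
from indelscope.align import SeedIndex, map_reads
from indelscope.pileup_call import call_indels_from_alignments

fr = ix.forge(ix.ForgeConfig(n_reads=50_000), seed=1)
index = SeedIndex(fr.genomeset.maternal, seed_length=14)
records = [r for r in map_reads(fr.reads, index) if r is not None]
records.sort(key=lambda r: (r.contig, r.pos))
print(f"mapped {len(records)}/{len(fr.reads)} reads "
      f"({len(fr.reads) - len(records)} junction-spanning or low-identity reads rejected)")

candidates, decisions, depth = call_indels_from_alignments(records, fr.genomeset.maternal)
print(f"{len(decisions)} raw indel sites, {len(candidates)} pass the initial filters\n")
print("contig     pos  kind       allele support/cover  fraction  qual")
for c in candidates[:10]:
    print(f"{c.contig:6} {c.pos:7}  {c.kind:9} {c.seq:>5} {c.n_support:5}/{c.n_total:<6}"
          f"  {c.support_fraction:7.2f}  {c.variant_qual:5.0f}")
# Passing candidates are apparent RNA-DNA indel differences; most are
# false positives that the classification cascade must explain.
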