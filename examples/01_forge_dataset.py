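"""Forge a synthetic diploid study set: genome, genes, artifact structures, reads.

Builds a two-contig reference with spliced genes, writes splice traps
(intron-end copies of exon tails) and paralog decoys into it, derives
maternal/paternal haplotypes with pinned exonic indels, injects
database-annotated misassembly indels into the transcripts, and simulates
33 bp single-end reads from both haplotypes.
"""

import indelscope as ix

cfg = ix.ForgeConfig(n_reads=50_000, n_editing_sites=5)
fr = ix.forge(cfg, seed=1)

gs = fr.genomeset
print(f"reference contigs : {[f'{c}:{len(s)}bp' for c, s in gs.reference.items()]}")
print(f"genes             : {len(fr.main_genes)} spliced + {len(fr.genes) - len(fr.main_genes)} paralog-copy")
print(f"splice traps      : {len(fr.traps)} (intronic exon-tail copies, 1 bp indel each)")
print(f"paralog pairs     : {len(fr.paralogs)} (~{fr.paralogs[0].percent_identity:.0%} identity, decoy contigs)")
n_indels = sum(1 for v in fr.variants if v.kind != "snp")
print(f"haplotype variants: {len(fr.variants)} ({n_indels} exonic single-base indels)")
print(f"database indels   : {len(fr.misassemblies)} (carried by all molecules, absent from the assembly)")
print(f"editing events    : {len(fr.editing)} (fraction {cfg.editing_fraction} of molecules)")
print(f"reads             : {len(fr.reads)} x {cfg.read_length} bp at {cfg.error_rate:.0%} error")
# Each number above is a planted ground truth the detection pipeline must
# either call (editing) or explain away (everything else).
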