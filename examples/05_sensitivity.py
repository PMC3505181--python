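"""Measure pipeline sensitivity on known maternal-paternal indel differences.

Every single-base indel differing between the haplotypes is located from the
truth tables, ranked by read coverage (homopolymer-prone sites excluded),
and checked against the caller's pre-cascade candidates — from maternal
calling alone and with paternal calling combined.
"""

import indelscope as ix

cfg = ix.RunConfig(seed=1, outdir=None, write_artifacts=False, run_sensitivity=True)
cfg.forge.n_reads = 50_000
res = ix.run_pipeline(cfg)

sens = res.sensitivity
print(f"covered haplotype indel sites : {sens['n_sites']}")
print(f"recovered, maternal calling   : {100 * sens['maternal_only']:.0f}%")
print(f"recovered, combined calling   : {100 * sens['combined']:.0f}%")
# High combined recovery shows that finding no editing is not a sensitivity
# artifact: the pipeline does find real indels when they are present.
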