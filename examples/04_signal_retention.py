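"""Plant real editing signal and verify the cascade does not absorb it.

Twenty single-base transcript indels at 50% molecule fraction are injected
well away from junctions, paralogs and homopolymers; they must come through
the full cascade as residual candidates.
"""

import indelscope as ix

cfg = ix.RunConfig(seed=1, outdir=None, write_artifacts=False)
cfg.forge.n_reads = 50_000
cfg.forge.n_editing_sites = 20
res = ix.run_pipeline(cfg)

print(ix.render_report(res.summary, "tsv"))
ev = res.truth_eval
print(f"editing events planted : {ev['n_editing_planted']}")
print(f"recovered as residual  : {ev['n_editing_retained']} "
      f"({100 * ev['editing_retention']:.0f}%)")
# Retention near 100% shows the stringent filters reject artifacts without
# destroying genuine low-frequency signal.
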