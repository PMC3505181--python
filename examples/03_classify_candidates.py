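"""Classify every passing candidate through the false-positive cascade.

Order: paternal allele -> splice junction -> paralog -> known variant;
whatever survives is residual, i.e. a putative indel RNA-DNA difference.
"""

import indelscope as ix

cfg = ix.RunConfig(seed=1, outdir=None, write_artifacts=False)
cfg.forge.n_reads = 50_000
res = ix.run_pipeline(cfg)

print(ix.render_report(res.summary, "tsv"))
ev = res.truth_eval
print(f"mechanism-derived candidates labeled correctly: "
      f"{ev['n_mechanism_correct']}/{ev['n_mechanism_derived']}")
# With no editing planted, a residual count of 0 means every candidate was
# traced to a splice junction, paralog, diploid allele or known variant —
# the cascade leaves no unexplained "editing" calls.
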