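# Methods

This note records the models, parameter choices and numerical conventions
behind indelscope, and what the synthetic experiments do and do not show.

## Coordinates and indel representation

All in-memory coordinates are 0-based half-open; emitted SAM/VCF/GFF3 are
1-based per format convention. Indels are anchored on the base before the
event and left-aligned against the relevant sequence before any grouping or
comparison, so reads reporting the same event at shifted anchors collapse
onto one candidate and database comparisons are representation-independent.
Homopolymer run length at an indel site is the maximal single-base run
containing the first deleted base (deletions) or the inserted run plus
flanking identical bases (insertions).

## Synthetic study conditions

The generator's defaults are the package's study conditions: a 2 × 100 kb
random reference at 41% GC; 20 non-overlapping spliced genes (2–5 exons of
120–300 bp, introns of 120–400 bp, canonical GT-AG written in coding
orientation); 5 splice traps; 5 paralog pairs (500 bp, 2% divergence); 10
haplotype indels; SNPs at 5 × 10⁻⁴ per base per haplotype; 10
database-annotated indels; 200,000 single-end 33 bp reads at 1% substitution
error split evenly between haplotypes (a 54 bp setting mirrors longer-read
chemistry). Sample-size-critical tests state smaller read counts where a
property does not need full coverage; the acceptance script uses 50k-read
null runs and full-scale cascade runs.

Structures are planted so that each candidate's expected explanation is
unambiguous:

* **Haplotype indels** are pinned inside exon interiors ≥ 45 bp from exon
  boundaries, each randomly assigned to one haplotype; applying each
  haplotype's variants to the reference reproduces that haplotype
  byte-exactly, and block liftover tables link all three coordinate systems.
* **Splice traps** copy the last 20 bp of an exon (its final two bases set
  to AG, which then serves as the splice acceptor) into the adjacent intron
  3' end with exactly one 1 bp indel. This is the genomic structure that
  makes a non-splice-aware aligner place junction-spanning reads across the
  intron boundary with a spurious indel — generic junctions produce only
  chance-level artifacts. Traps are planted on plus-strand genes.
* **Paralogs** copy an intergenic interval onto a reference-only decoy
  contig with an exact substitution count (divergence × length, minus one
  for the single 1 bp indel). The decoy is transcribed (the locus exists in
  the individual's true genome; the assembly missed it), so its reads must
  cross-map to the source locus. Placing the copy on its own contig
  realizes the "far from the source" requirement.
* **Database ("misassembly") indels** are injected into the transcripts of
  both haplotypes at fraction 1.0 but left out of the assembled FASTAs, and
  written to the known-variants VCF — the signature of an indel the
  assembly missed. In-database germline indels are additionally flagged in
  the truth VCF.
* **Editing events** are single-base transcript indels carried by a
  configurable fraction of molecules (default 0.5), placed ≥ 40 bp from
  transcript ends and junctions, outside homopolymer runs > 5, and ≥ 120 bp
  from any other planted event. The inserted base is configurable rather
  than uridine-only, since the target signal class is not base-restricted.

Base-call qualities follow a two-state model (Q37/Q10); an error base is
low-quality with probability 0.9, a correct base with probability 0.02.
This suffices to exercise the Q20 filters without modeling real sequencer
error cycles.

## Mapper

A single contiguous k-mer index (default k = 14) replaces spaced-seed index
sets; spaced masks buy sensitivity at real genome scale and are irrelevant
at desk scale. Lookups returning more than K = 8 positions are ignored as
repetitive and the candidate-location cap per read is 1280 (both
configurable). Scoring (match +1, mismatch −3, gap open 5, gap extend 2;
gap of length k costs 5 + 2k) is chosen so one 1 bp indel outscores three
mismatches in a 33 bp read — the regime in which a gapped mapper reports
indels at all. Full-length mapping is enforced with a fitting alignment
(query-global, target-local), which cannot soft-clip by construction,
plus a minimum score of read_length − 16; reads failing it are unmapped.
`N` matches nothing, including another `N`. Ties prefer fewer gaps, then
the leftmost placement; the batched mapper runs the affine DP (numba
kernels) only for reads whose best gapless placement has ≥ 2 mismatches,
which is exact: under this scoring a gapless placement with ≤ 1 mismatch
cannot be beaten by any gapped alternative.

MAPQ is a contract, not a reproduction of any aligner's formula: 0 on a
score tie, 60 with no second candidate, otherwise monotone in the score gap
(≈ 6 points per score unit for 33 bp reads, clamped to [1, 60]). For reads
finished on the gapless fast path the second-best score is the best gapless
score at another locus, which can understate a gapped second placement and
hence overstate MAPQ slightly; ambiguous (duplicate-locus) reads still get
MAPQ 0 exactly.

## Caller

A candidate is emitted for every pileup column with at least one indel
event, with no minimum supporting fraction at emission (editing could occur
at low frequency); fraction is a downstream filter. Thresholds default to:
base quality ≥ 20 at the indel site (inserted-base quality for insertions,
minimum flanking quality for deletions); mapping quality ≥ 20; indel
anchored ≥ 3 bp from both read ends; ≤ 3 mismatches on indel-carrying
reads; ≥ 2 supporting non-duplicate reads; ≥ 5 covering reads; supporting
fraction ≥ 5%; one allele, size 1, no N; homopolymer run ≤ 5. A duplicate
is a read identical in (contig, start, strand, CIGAR). The coverage
denominator counts reads surviving the read-level filters (configurable in
interpretation but fixed here for internal consistency). Variant quality is
the Phred-scaled probability that all supporting events are errors — the
sum of supporting base qualities, capped at 255 — rather than a
genotype-likelihood model; the default threshold of 0.01 Phred is
deliberately permissive, and a probability-units interpretation (error
probability ≤ threshold) is selectable because the rule's original units
are ambiguous.

The vectorized caller is semantically identical to the column-stream path
(build pileup → read-level filters → call → site filters); the test suite
asserts their equivalence on mapped data. One edge is accepted: a read
discarded for end-proximity/mismatch reasons stops contributing coverage
everywhere in the vectorized path but only at its indel column in the
column path; only the indel column enters candidate statistics, where the
two agree.

Measured support fractions at planted 50%-fraction sites come out near
0.41, not 0.50: carrier reads whose indel lies within 2 bp of a read end
are discarded, and edge-truncated carriers align gaplessly and count only
as coverage. This attenuation is a property of any read-level indel
measurement, not of the simulation.

## Classification cascade

Filters run in a fixed order — paternal allele, splice junction, paralog,
known variant — and the first match assigns the label; residual means no
filter matched. Key quantifications of qualitative criteria (all
configurable):

* **Paternal allele**: every supporting read must fit the homologous
  paternal locus (via the liftover) full-length, gaplessly, with ≤ 3
  mismatches, *and* at least as well as its gapped placement scored on the
  mapping haplotype — without the score condition, reads whose gapped
  placement barely beats a 3-mismatch gapless one would spuriously
  "support" the paternal genome. An unresolvable paternal locus passes the
  candidate onward with a warning.
* **Splice junction**: against a single transcript whose gene overlaps the
  candidate's reference locus (this locus correspondence is essential:
  without it, paralog candidates whose copy gene is transcribed would
  satisfy the partial/full criteria on the *copy's* transcript): (1) the
  ±32 bp genomic window matches its own reference locus gaplessly with ≤ 3
  mismatches; (2) its best gapless segment on the transcript covers ≥ 15 bp
  but < 90% of the window; (3) the edited window aligns to the transcript
  gaplessly over its full length (≤ 3 mismatches) — or, since the window
  spans intronic sequence for most genuine junction artifacts, the
  supporting reads themselves (spliced molecules) fit the transcript
  full-length and gaplessly, tolerating one unmatched read in small support
  sets and a 10% minority in large ones. Both window orientations are
  tried (minus-strand genes).
* **Paralog**: the edited window aligns gaplessly over its full length at
  some reference locus ≥ 200 bp away from its own, with ≤ 6 mismatches
  (≈ 90% identity over 65 bp, approximating the tolerance of a
  similarity-search judgment; a stricter cap misses copies whose random
  substitutions cluster near the indel).
* **Known variant**: exact normalized (position, kind, sequence) match
  preferred; a same-kind, same-size database indel within 5 bp also
  matches, because a sequencing error at the discriminating base can shift
  a real variant's called representation into an equally-scoring twin.

## Sensitivity protocol

Haplotype indel sites come from the truth tables (variants carried by
exactly one haplotype) or, independently, from whole-contig maternal-vs-
paternal alignment (edlib, global mode) — the two agree on synthetic data
and the cross-check is a test. Sites are ranked by coverage on the calling
haplotype, homopolymer runs > 5 excluded, coverage ≥ 5 required, top-N
kept (default 100; with 10 planted indels the list is all covered sites,
so both possible denominators coincide here and both fractions are
reported). A site counts as recovered when a size-1 candidate lies within
5 bp on the calling haplotype's coordinates; paternal-side calling is the
identical pipeline with haplotypes swapped.

## Determinism and problem sizes

Every stage derives its randomness from one master seed through SeedSequence
spawning; two runs with the same config are byte-identical in all reports.
The acceptance script spans: one 50k-read null run, eight full-scale
(200k-read) specificity runs, and three full-scale retention runs with
sensitivity — about two minutes on one core. The 20-seed specificity
property in the test suite uses the same full-scale conditions.

## What the synthetic experiments do not show

The generator emulates the *structures* the filters target, not the
texture of real data: no position-dependent or context-dependent error
profiles, no PCR duplicates as a process, no paired ends, no expression
heterogeneity beyond transcript length, uniform coverage, exact GT-AG
splicing, and splice traps as the sole systematic junction-artifact source.
Passing tests therefore demonstrate the logic and the bookkeeping of the
pipeline — that each filter recognizes its mechanism and only its
mechanism — not the false-positive rates to expect on a real transcriptome,
which depend on repeat content, annotation completeness and sequencing
chemistry. Real-data use enters through the SAM/VCF/FASTA interfaces: an
external aligner's SAM can be called and classified provided a coordinate
map between haplotypes is supplied in place of the truth liftover.
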