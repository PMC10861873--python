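# Methods

This note documents the models, rules and numerical choices behind
`crisprikit`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the underlying biology leaves room.

## Coordinate model

All internal coordinates are 0-based, half-open, on the forward strand;
GFF3 (1-based inclusive) and BED6 (0-based half-open) are converted at the
I/O boundary, and all emitted reports use 1-based inclusive positions.
The TSS defaults to a gene's strand-aware 5' end; an optional `tss` GFF3
attribute overrides it for annotations derived from TSS-resolved
transcriptome maps. Ambiguity codes are tolerated in genomes but any
candidate window touching one is discarded — spacers must be synthesizable
and exactly matchable. Promoter windows truncated at a linear replicon edge
are kept with a warning; on circular replicons they wrap.

## Design rules

A candidate spacer is a `spacer_length` (default 20 nt) protospacer with a
TTV PAM immediately 5' on the protospacer strand, both lying inside the
union of the promoter window (`promoter_window`, default 50 nt upstream of
the TSS) and the gene body. Candidates are classified by the position of the
protospacer 5' end; promoter candidates may sit on either strand (the bound
RNP occludes polymerase recruitment), transcribed-region candidates are kept
only when the protospacer sits on the coding strand, i.e. the gRNA anneals
to the template strand — the orientation required to block elongation.

Soft preferences are applied as a lexicographic sort rather than a weighted
score, which keeps the ranking deterministic and auditable:

1. GC fraction within [`gc_min`, `gc_max`] (default 0.35–0.75) before outside;
2. promoter, then the 5' portion of the gene (`five_prime_fraction`,
   default 0.5, of the gene length), then the 3' portion;
3. extended TTTV PAM before plain TTV;
4. smaller |TSS offset|; then genomic coordinate and strand as tie-breaks.

Selection takes ranked, off-target-clean candidates: up to `guides_per_gene`
(default 3) gRNAs, preferring non-overlapping protospacers but — within the
preferred-GC tier first — allowing overlap when nothing else remains, so
overlap avoidance never costs a GC-compliant guide. Array spacers
(`array_spacers_per_gene`, default 3) must be pairwise non-overlapping and
disjoint from the gRNAs. Every shortfall is recorded in per-gene failure
notes rather than raised.

## Off-target search

A spacer is discarded when a *second* genomic locus (exact interval+strand
identity defines "self"; a shifted overlapping window counts as second)
matches it with at most `offtarget_max_mismatch` mismatches (default 2,
i.e. fewer than three) and carries a TTV immediately 5' on its strand.
Mismatches are plain Hamming counts over the full spacer — no seed
weighting, no indels — and the off-target PAM must match TTV, not the
extended TTTV. The search uses a pigeonhole seed index: the spacer is split
into `max_mismatch + 1` contiguous parts, any qualifying window matches at
least one part exactly, and candidate positions from exact k-mer lookup are
verified in full. The index is an acceleration only; tests assert exact
hit-set equality with a naive scan on linear and circular replicons.

## Array folding validation

Cas12a matures its own guides by cleaving at the 3'-terminal hairpin of each
direct repeat, and a spacer complementary to a neighbouring repeat can
sequester that hairpin in the precursor transcript. The check: fold the full
array transcript (ViennaRNA, RNA alphabet, default parameters), retain the
MFE structure plus suboptimals within `energy_window` (default 2 kcal/mol)
capped at `max_structures` (default 20), and require for each repeat
instance that some retained structure contains every base pair of the
repeat's reference hairpin (the helix containing the 3'-most paired base of
the isolated repeat's MFE structure), translated to transcript coordinates.

Two evaluation modes exist because "some near-optimal structure" is genuinely
ambiguous: the default judges each repeat instance independently; strict mode
requires a single structure satisfying all instances at once. The default is
the permissive reading; flip `strict` to compare. Enlarging the window or the
cap can only add structures, so a pass can never turn into a fail —
asserted as a property test.

Array assembly iterates over ranked spacer triples and their orderings
(overlapping pairs excluded) up to `attempt_cap` (default 50) fold
evaluations and returns the first passing transcript; on exhaustion the gene
keeps its single gRNAs only. The direct repeat is configuration input
(default: the canonical Francisella Cas12a repeat, whose MFE is a single
5-bp terminal hairpin); the test suite additionally uses synthetic repeats
because the checking procedure, not any one repeat sequence, is the product.

## Cloning output

Gibson fragments are plain concatenations `arm5 + spacer + arm3` with
config-supplied homology arms. CRATES oligo sets partition the array duplex
at unit boundaries into three fragments, each a top/bottom oligo pair offset
by 4 nt so annealing leaves 4-nt 5' overhangs; the junction overhang
defaults to the first 4 nt of the downstream unit's top strand and shifts by
±1..3 nt on a clash. Compatibility requires overhangs to be pairwise
distinct, non-palindromic, **and not reverse-complementary to one another** —
the last condition is stricter than mere distinctness but necessary: a pair
of reverse-complementary overhangs lets a fragment ligate in flipped
orientation, which the reassembly oracle (exhaustive backtracking over all
overhang-consistent chains; assembly must be unique) duly detects. The first
and last overhangs join the destination vector and are config constants.

## Screen scoring

Counting is member-level (an array is one member): reads are searched in
both mates and orientations for the constant 5' and 3' flanks (each
tolerating `max_flank_mismatch`, default 1), and the enclosed sequence is
matched exactly against the manifest. Fitness per member and replicate is
`log2((CPM_stress + pc) / (CPM_control + pc))` with pseudocount 0.5 on
counts-per-million — strict CPM makes the statistic exactly invariant to
rescaling any single sample's depth. Per-gene scores are unweighted means
over members; the p-value is a two-sided one-sample t test of the pooled
per-member-per-replicate values against zero, BH-corrected across genes; a
hit requires |mean log2FC| > 0.5 and FDR < 0.05, with the sign convention
that enrichment under stress is positive.

The original analysis style for such screens uses count-model packages
(edgeR and kin); this package deliberately specifies its own transparent
default and exposes a `stat_test` hook, so any statistic operating on the
pooled per-replicate values can be substituted, and externally computed
per-member fitness tables can enter at `aggregate_srna`.

## Synthetic data

`fixtures` generates: (i) genomes of i.i.d. bases at a target GC (default
0.35, the *Bacteroides* intergenic regime) with evenly spaced planted genes
(default length 60–200 nt, the sRNA size range) on a configurable strand
mix — at this GC the TTV density alone supplies ample candidates, and a
`GA`-tiled rewrite creates PAM-desert genes for negative controls;
(ii) off-target decoys: copies of chosen spacers at stated Hamming
distances, with a TTV or a scrambled context, placed in gene-free territory
with a truth table; (iii) screens: member baselines drawn log-normal
(sigma 0.5), stress means multiplied by 2^(planted log2FC) and renormalized
to depth (sequencing measures relative abundance), counts drawn
negative-binomial with variance mu + phi*mu^2 (default phi 0.1, depth 1e6,
135 genes x 4 members, 3 replicate pairs); optional FASTQ rendering embeds
spacers between the vector flanks at fixed high base quality.

What the generator does **not** emulate: real promoter architecture or TSS
uncertainty, sequence composition structure (repeats, skews, operons), PCR
bias, chimeras, bottleneck drift across passages, or quality-score error
profiles. Passing tests therefore demonstrate the correctness of the rules,
searches and statistics under controlled conditions — not designed-guide
efficacy or screen performance on any real genome.

## Problem sizes and numerics

The test suite and the acceptance script run the census oracle comparison on
100 random 1-kb sequences, the off-target oracle on a 50-kb genome with 30
planted decoys, design-rule checks on a 100-kb/20-gene genome, the
genome-scale design on 6.3 Mb with 135 genes (~25 s on one CPU), and screen
simulations over 20 seeds (~10 s). Free energies are reported to 0.01
kcal/mol as the engine prints them; structure ties are broken
lexicographically by dot-bracket string to keep folding output
deterministic. A deliberate caveat: the PAM-count dominance NGRR >= NGG is a
statistical property of AT-rich sequence (counterexample: `AGGC` contains an
NGG but no NGRR), so it is asserted on the AT-rich fixtures, not as a
universal invariant; TTV >= TTTV, by contrast, is a containment theorem and
is asserted unconditionally.
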