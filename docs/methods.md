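# Methods

This note records the models, conventions and deliberate choices behind
mitomosaic, at the level a maintainer or reviewer needs to judge what the
code computes and what passing tests do and do not show.

## Coordinate and topology conventions

All coordinates are 1-based inclusive, matching BLAST tabular output and
GFF3. Circular sequences are stored linearised from an arbitrary origin;
repeat search and the internal aligner honour matches that wrap the origin,
while the synthetic generator never *plants* a feature across the origin —
planted coordinates are the oracles for recovery tests and keeping them
non-wrapping keeps those oracles simple. Minus-strand alignment segments
are encoded the BLAST way, `s_start > s_end`.

## Repeat model

A repeat pair is two occurrences (direct, or inverted = reverse-complement)
whose Hamming distance is at most a budget *m*; it is **maximal** when no
one-base extension on either side stays within the budget. Each unordered
occurrence pair is reported once, so a three-copy family yields three
pairs. The census table's "% genome size" counts each pair's length once —
not both copies, not their union — which is documented so users can
recompute alternatives from the pair list; with overlapping pairs the
column can exceed 100 % and is a repeat "mass" rather than a coverage.

Two search strategies implement the same definition. Up to 2 kb an
exhaustive scan walks every circular diagonal (direct) and antidiagonal
(inverted), enumerating maximal ≤ *m*-mismatch windows from the mismatch
positions. Above 2 kb, exact k-mer seeds anchor extension; the seed length
is `min(20, ceil((min_length − m)/(m+1)))`, which by pigeonhole guarantees
every reportable window contains a seed, and every left/right split of the
mismatch budget is enumerated, followed by an explicit maximality check.
The two paths are asserted identical in the suite, and both are asserted
equal to an independent cumulative-sum window oracle on random genomes.
The minimum reportable length is 8: below that random sequence saturates
with chance matches. When an entire diagonal fits the budget (degenerate,
e.g. homopolymers) a single full-circle window anchored at position 1 is
reported.

## Depth classification

Nuclear-encoded copies of mitochondrial sequence ride along in organellar
assemblies but at a fraction of the read depth. The reference depth is the
median over the retained set, computed with one re-iteration (start from
all contigs, drop those under `threshold × median`, recompute), and a
contig is a nuclear copy iff its depth is *strictly* below
`threshold × reference`; the default threshold is 0.10. GC content is
recorded but unused — true nuclear copies have indistinguishable GC.

## Master-circle traversal

"Use every contig at least once" is formalised as a minimum-length closed
covering walk. The paper-trail for this convention: organellar assemblies
are small (tens of nodes), the minimal walk is unique up to
rotation/reflection for simple repeat structures, and minimality plus a
lexicographic tie-break (anchor at the smallest contig id in + orientation,
smallest step sequence among minimal walks) makes the traversal
deterministic and therefore testable. Search is iterative-deepening DFS
with memoised dead ends, with a step bound of `2n + 4`; a disconnected
graph, or none found within the bound, raises an error carrying the
connected components (which may be genuine independent subgenomic circles).

`count_configurations` counts minimal closed covering walks up to rotation
and reflection, with early stop at a cap. Note that two loops joined by a
shared repeat contig with uniformly oriented links admit only *one* class
(loop order is a rotation); two classes arise when a segment between
inverted-repeat copies can be traversed in either direction. Both
structures are fixed in tests.

Walk validation (edge consistency + coverage) is implemented separately
from the search and shares no code with it.

## Recombination model in the generator

Homologous recombination between repeat copies is string surgery: for an
inverted pair, `u R v R' w → u R rc(v) R' w` (the intervening segment
reverse-complemented; length conserved; the operation is an involution);
for a direct pair on a circle, excision into two circles `R v` and
`R w u`, whose lengths sum to the original. Both junctions carry a full
repeat copy — the footprint — and the truth records each junction as the
pair of pre-recombination coordinates flanking it, which is exactly what
split-alignment breakpoints report (`(left segment subject end, right
segment subject start)`), making recovery comparable within a merge
radius.

Planted repeat copies are written as fresh random sequence at both sites
with the requested interior substitutions, and the flanking bases are
forced to mismatch ("hardened" borders): the planted coordinates are then
exactly the maximal-repeat coordinates, so exact-length recovery assertions
are legitimate rather than probabilistic.

## Rearrangement classification

A query's segments, sorted by query start, chain colinearly when every
adjacent pair is same-strand, subject-order consistent with query order,
and at most 1 kb apart on the subject; any violation is a breakpoint.
The 1 kb default matches the gene-proximity window used for candidate
screening; no threshold is inherited from any aligner. Segments shorter
than 50 bp are ignored (the shortest informative published segment is
88 bp; 50 leaves headroom), and a segment whose query interval is contained
in another's is dropped as a secondary hit — a query spanning one copy of a
repeat also hits the other copy, and without containment filtering every
repeat-spanning colinear query would be misclassified as rearranged.
E-values are accepted on input, never computed; the internal aligner
filters by length instead.

The internal aligner is an exact seed-and-extend matcher (maximal ungapped
exact local matches, both strands, circular subject). It exists for
synthetic analyses, where the rearranged molecule derives from the
reference by recombination and is locally identical to it; externally
produced tabular alignments are the first-class input for real data, where
substitutions and indels require a full aligner.

Breakpoint footprint arithmetic:
`footprint = max(0, min(q_end) − max(q_start) + 1)` and
`insertion = max(0, max(q_start) − min(q_end) − 1)`; at most one is
positive. Published interval pairs [1, 612]/[512, 1096] give 101 and
[1, 7965]/[7733, 9596] give 233. For one published junction a 29 bp
sequence-level footprint is quoted where the printed intervals overlap by
only 20 and 4 bp; interval overlap and sequence-level footprint can differ
when alignment ends are trimmed, and this package reports the interval
quantity.

Gene distances are measured along the gene's own orientation: `d_start` is
positive upstream of the start codon, `d_end` positive before (upstream of)
the gene end. For a minus-strand gene at 156716–158245 and a segment
boundary at 158290, `d_start = 158290 − 158245 = 45`; for the boundary at
156744, `d_end = 156744 − 156716 = 28`.

Cross-sample presence matching treats breakpoints as the same event when
both subject coordinates agree within 50 bp — footprints up to ~100 bp blur
the junction base, so exact matching would fragment events.

## Fusion ORF calling

ORFs are ATG-to-stop, standard genetic code (plant mitochondria use the
standard code for the relevant codons), six frames, longest ORF per stop
(first ATG after the previous in-frame stop), minimum 30 aa by default.
Peptide matching is ungapped longest-common-substring; a call needs a
15 aa identical block — below that, chance matches dominate at these
peptide lengths. The block's position in the *donor* peptide is reported
(amino-terminal / carboxyl-terminal / internal / complete).

The generator's fusion scenario plants an inverted repeat whose first copy
sits in frame behind a novel ATG+head, with the inverted segment arranged
so that crossover splices the carboxyl-terminal tail (and stop) of an
intact donor gene onto it. The default sizes — 17-codon head, 10-codon
(30 bp) repeat, 23-codon tail — produce a 51 aa chimeric ORF whose last 33
residues (repeat + tail, i.e. the footprint codons plus the retained tail)
match the donor's carboxyl terminus, the size regime of the motivating CMS
case; the repeat is deliberately below the 15 aa reporting threshold so
only the in-frame junction yields a call.

## RNA-editing calling

Only C→U is considered (genomic C / RNA T; genomic G / RNA A on the
forward strand inside annotated minus-strand genes); all other mismatch
classes go to a diagnostics tally and are never called. Defaults: genomic
and RNA depth ≥ 10, genomic consensus purity ≥ 0.9, edit fraction ≥ 0.1 in
at least one sample. These are this package's documented choices — the
thresholds behind published counts from read data are not recoverable — and
all are exposed on the API and CLI. Per-sample fractions are recorded for
every sample so the differential comparison (edited in all samples except a
focal one, same threshold) needs no re-calling. Codon consequences are
computed in gene orientation by replacing the edited base with T and
translating; stop creation is flagged.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structural* statistics the analyses key on:
dispersed direct/inverted repeats (defaults include a 101 bp direct pair
with 1 mismatch and a 300 bp exact inverted pair), ORF-bearing
single-exon genes, repeat-mediated recombination with junction footprints,
contig tilings with oriented links, a three-fold spread of mitochondrial
read depths (uniform over 0.6–1.8 × the mean), nuclear-copy decoys at
0.2–0.6 × the nominal 8 % depth ratio and without links (nuclear
insertions do not scaffold with organellar contigs), six RNA samples, and
80 %-edited C→U sites with optional per-sample omissions.

Background sequence is i.i.d. uniform A/C/G/T: no codon bias, GC skew, or
tandem-repeat structure. Pileups are site-independent draws: no read-level
correlation, mapping ambiguity, or strand bias. Contigs tile the circle
exactly: no misassembly or overlap. Gene models are single-exon: no
introns or trans-splicing. Consequently, passing recovery tests
demonstrates correctness of the algorithms under their stated model, not
robustness to alignment artefacts, mapping error, or paralogy in real
sequencing data. The default genome length (12 kb) and the sizes used in
the heavier tests (8–9 kb, 20–50 replicates, 200-genome oracle sweeps) are
the package's chosen desk scale; all scale parameters are plain config
fields.

Determinism: one integer seed drives a single numpy Generator;
`simulate_all` draws in a fixed documented order (genome → recombination →
fragmentation → pileups), and identical configs are byte-identical.

## Numerical and degenerate-input notes

- Classification threshold comparisons are strict (`<`), so a contig at
  exactly 10 % of the reference depth stays mitochondrial.
- `breakpoint_footprint` of abutting segments is (0, 0).
- Empty alignment input classifies as `unaligned`; an empty pair list
  summarises to an all-zero census.
- A repeat whose two copies overlap is rejected for recombination.
- Requesting more editing sites than genic C positions raises.
- Feature placement uses rejection sampling with a 20 bp guard margin and
  fails loudly (`PlacementError`) after 500 attempts rather than degrading.

## Known limitations

- The internal aligner is exact-match only; real cross-variety comparisons
  should come in as external tabular alignments.
- Subgenomic-circle stoichiometry is not modelled or estimated.
- The walk search is exponential in the worst case; it is intended for
  graphs of tens of nodes, and `count_configurations` caps enumeration.
- Editing calls are per-site; no haplotype or partial-editing model.
- The cross-species conservation comparison of editing sites is reduced to
  agreement counting over an externally supplied table; no alignment is
  computed here.
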