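# Methods

This note documents the models, algorithms and numerical choices behind
`temark`, in the order the pipeline applies them, followed by what the
synthetic-data generator does and does not emulate.

## Coordinates

All coordinates are 1-based closed internally; interval length is
`end − start + 1`. BED input/output is converted at the boundary layer
(0-based half-open), and every report header states its convention.
When junction homology makes a breakpoint placement ambiguous, calls and
ground truth both use the *leftmost* placement and carry an explicit
`ambiguity_width` — the total number of bases the event can slide without
changing the derived sequence.

## Similarity blocks (the dot-plot primitive)

Blocks are gapless pairings of equal-length intervals found by
seed-and-extend: every maximal exact match of ≥ k bases (default k = 12)
is extended along its diagonal under +1/−4 match/mismatch scoring with an
X-drop of 25, then trimmed back to the score maxima. A block is reported
when it reaches the configured minimum length (default 100 bp) and overall
identity (default 0.95). Ambiguous bases (N) mismatch everything,
including other Ns, so assembly gaps always split blocks.

Why score-peak trimming instead of plain identity maximality: an interval
that merely keeps ≥95% identity overall can drag a low-identity tail of up
to length/14 into unrelated sequence (a 10 kb perfect block tolerates a
~700 bp random overhang at 95%), which would destroy breakpoint
resolution. Trimming to the score peaks pins block borders at the last
matching base of the homology plus, at most, a chance exact-match run
(~1 base of random sequence expected).

Seeding is exhaustive at the default thresholds: a ≥100 bp block at ≥95%
identity must contain an exact 12-mer, because killing every 12-mer in a
window of length L requires more than L/20 mismatches whenever L > 27.
Comparisons up to 4 kb total are scanned over every diagonal; larger ones
restrict work to diagonals carrying seeds, with 250 bp windows around seed
clusters (an X-drop extension cannot cross more than a few tens of bases
of unrelated sequence, so the clipping is lossless in practice). The
same definition is implemented naively (per-base, all diagonals, no
indexing) as the test oracle; the two agree exactly on all fixtures.

Scored local alignment (`local_align`) is a separate, plain
Smith–Waterman with linear gaps for flank-scale comparisons; significance
is a Karlin–Altschul-style expectation with λ solved for uniform base
composition and K fixed at 0.333 — a comparable statistic, not a
replication of BLAST's exact statistics.

## TE retrieval

Insertions are found as collinear chains of consensus-versus-genome blocks
(50 bp minimum block, 0.85 identity floor, both strands): chains advance
along the genome and along the consensus, bridge interruptions up to
2.5 kb (so an internally deleted copy stays one member), and may not
overlap a better-scoring chain (one member per locus). Chain significance
is the Karlin–Altschul expectation of the chain score at +1/−2 (cutoff
1e−3). Structure labels come from consensus coverage: full-length at
coverage ≥ length − 2×20 bp (the end-mismatch tolerance), solo-LTR when
matches are confined to one terminal-repeat interval, truncated otherwise.
For full-length calls the reported boundaries are the consensus-implied
element ends, which keeps them within the end tolerance even when terminal
bases have diverged. TSDs are recorded when the last ≤10 bases of the 5'
flank exactly match the first bases of the 3' flank at length ≥4.
Measured on the simulation: 100/100 planted copies at 5% divergence
recovered with exact boundaries; zero calls on a TE-free 1 Mb genome.

## Cross-genome matching and chromosome walking

Insertions are paired by best-reciprocal flank similarity (fraction of
flank covered by ≥90%-identity blocks ≥50 bp; cutoff 0.5), with an exact
32-mer index shortlisting candidates. Two donor insertions claiming one
counterpart are flagged `cnv_review` and analysed as a candidate tandem
array rather than dropped.

For each unmatched insertion, flanks of geometrically growing size
(5 kb, 10 kb, 20 kb, … up to 5 Mb) are aligned to the orthologous
chromosome until significant anchors (≥300 aligned bases) bracket the
site on both sides. The anchor pair is chosen to maximise total anchored
flank length net of the unanchored inner slack — a short multi-mapping
fragment (a TE copy inside the flank) then cannot outrank the long unique
flank match — and anchors are allowed to overlap on the target genome,
because junction repeats (microhomology, TSDs, recombination repeats,
collapsed tandem units) are matched by the flanks of both sides.

Polymorphism classification applies a fixed decision tree, cheapest and
most exculpatory evidence first: assembly artifact (N-run within 100 bp
of a putative breakpoint), empty site with a single TSD copy (deletion
matching element span + TSD), internal/chimeric element deletion
(consensus homology still present at the ortholocus), replacement by a
non-homologous insert ≥1 kb, and finally long-indel candidate. Matched
pairs whose structures differ (full-length vs truncated or solo-LTR) are
classified internal deletions and characterised like any other indel
locus.

## Breakpoint calling

Within an ortholocus pair, the prefix anchor is the forward block whose
coordinates start earliest on both genomes and the suffix anchor the one
ending latest; breakpoints are their inner borders. When the two anchors
overlap on one genome, the overlap *is* the junction-repeat ambiguity:
both reported intervals are slid left by the overlap (leftmost
normalisation) and the overlap recorded as `ambiguity_width`. With
exactly conserved flanks this makes recovered deletion intervals exact,
including chance junction microhomology, because the anchors absorb the
same repeat on both genomes.

Type assignment: `deletion_in_b` when the B-side junction remnant is
short (≤100 bp) — or long but homologous to the A flanks, the signature
of recombination between long repeats where one copy survives;
`replacement` when both sides carry substantial unique sequence;
`inversion` when reverse-orientation blocks cover ≥50% of the variant
region (measured by overlap, since chance palindromic matches let blocks
poke a few bases into the anchors); `none` for identical loci. Calls
with an N-run within 100 bp of a breakpoint are flagged and excluded as
artifacts. Tandem copy number comes from off-diagonal self-plot blocks:
only blocks spanning ≥80% of their own diagonal offset count as tandem
evidence (distinguishing adjacent duplications from distant repeat
pairs); the unit is the diagonal offset of the longest such block, copies
= 1 + round(length/offset), and the cross-comparison's discontinuity
borders provide a consistency check. Inversions are the best chain of
reverse blocks collinear in reversed order (quadratic DP with 50 bp
overlap slop).

## Junction mechanism classification

Precedence, with all evidence retained regardless of the final label:

1. **Introgression** — a replacement whose insert (≥1 kb) has no block
   ≥100 bp/0.95 against the donor genome or any supplied reference.
2. **Unequal recombination / LTR recombination** — a direct-repeat pair
   ≥100 bp at ≥95% identity with one copy overlapping each breakpoint
   (searched ±10 kb of each breakpoint, with the call's ambiguity as
   positional tolerance). If both breakpoint regions fall in
   same-family, same-orientation LTR annotations of distinct copies, the
   label refines to LTR recombination. (A strict "unequal before LTR"
   precedence would make the LTR label unreachable, since LTRs satisfy
   the repeat thresholds; annotation-based refinement keeps both labels
   meaningful.)
3. **SD-MMEJ** — only when the junction carries a net insertion and the
   reconstruction search explains it completely.
4. **MMEJ** — a 1–9 bp repeat flanking the deleted segment that appears
   exactly once at the derived junction. Junction repeats of 10–99 bp
   fall in a gap between the microhomology ceiling and the long-repeat
   floor; such junctions are labelled blunt/ambiguous with an
   "intermediate homology" note.
5. **Blunt / C-NHEJ or ambiguous** — everything else. If an apparently
   blunt junction admits an SD-MMEJ explanation (synthesis creating the
   annealing microhomology with no net insertion), the reconstructions
   are attached as evidence and a note added, but the label stays blunt:
   with a 1 bp minimum primer such explanations are common by chance, so
   they are reported, not asserted. Blunt labels on deletions >10 kb
   carry a note that MMEJ-family repair is more likely than C-NHEJ at
   that scale.

### SD-MMEJ reconstruction search

State: the two DSB ends, tracked as a string appended to the left flank
and a string prepended to the right flank. Each round, one end's
terminal 1–9 bases (the primer repeat) anneal to an occurrence within the
search context — direct, or inverted (snap-back) against the reverse
complement — and synthesis copies 1–n template bases onto that end. The
context consists of the flank tails and deleted-segment edges around both
breakpoints; a primer occurrence must *start* within the window (default
35 bp, matching the distances seen in real worked junctions: 12–29 bp)
but its template may extend up to 45 bp further. After ≤2 rounds the
ends must share a microhomology of 2–9 bases, at least partly created by
synthesis, and replaying the whole event must regenerate the observed
junction exactly. The search is exhaustive (the pruning only discards
states that can no longer reproduce the junction) and equals a plain
brute-force enumeration on small contexts. Reconstructions are ranked by
fewest rounds, then longest junction microhomology (annealing stability),
then least total synthesis, then template position; all co-optimal and
sub-optimal valid reconstructions are returned.

## The synthetic genome-pair generator

Background sequence is i.i.d. nucleotides at configurable GC (default
0.46, wheat-like) — the simplest null under which a 100 bp/95% block is
statistically impossible by chance. A synthetic LTR-retrotransposon
consensus (3 kb with 300 bp terminal repeats by default) stands in for a
real family consensus at desk scale. TE copies are planted with i.i.d.
substitutions at a configurable rate (default 2%), random strand, and
4–6 bp TSDs duplicated from the insertion site.

Each of the 11 event types plants exactly the sequence structure its
mechanism requires (direct-repeat pairs, microhomology motifs,
primer-repeat templates with the published spacings, tandem units,
foreign segments, N-runs) and records the surgery that derives genome B.
Deletion-type events carry a full TE copy inside the affected segment, so
the discovery pipeline can find them the same way the real analysis
does — through donor-specific insertions. Guard bases pin each planted
junction to its stated signature: a blunt junction cannot acquire chance
microhomology at the seam, a planted k-bp microhomology cannot extend
past the <10 bp ceiling, and a templated insertion cannot be absorbed
into the flanks (which would make the event interpretation-equivalent to
a shorter blunt deletion). Ground-truth ambiguity is the realised
placement freedom computed from the final sequences; for repeat-mediated
mechanisms it is at least the repeat length, since the crossover point
within the repeat is undefined in principle.

Default desk-scale study conditions: 5 kb deletions, 150 bp
recombination repeats at 99% identity, 5 kb tandem units at 99%, 2 kb
foreign inserts, 500 bp N-runs, 400 kb chromosomes. The end-to-end
validation uses six events per mechanism (66 events over six
chromosomes, ≈2.4 Mb per genome), sized so the whole run takes about a
minute on one CPU.

What the generator does **not** emulate: nested and fragmented repeat
landscapes (real wheat is >80% TE, so flank uniqueness is far worse than
here), indel-type sequencing/assembly errors inside conserved flanks
(flanks are exactly conserved except where an event touches them),
population-level variation, and biased substitution processes. Passing
tests therefore demonstrate the correctness of the method's logic and its
resolution under clean anchors, not its robustness to heavily repetitive
real assemblies — on real data the flank-matching and walking stages do
more work and multi-mapping is the dominant failure mode.

## Scoring conventions used in validation

Breakpoint recovery is asserted within each event's recorded ambiguity
plus a 3 bp slop for chance-match border resolution. Length recovery is
asserted on the net length change (donor-side minus derived-side length),
which is invariant to junction absorption: exact for mechanisms with
exactly conserved flanks (MMEJ, SD-MMEJ, blunt, full/empty sites,
internal deletions, introgression) and within the ambiguity for
repeat-mediated mechanisms, where anchor borders land on the first
divergent base inside a ~99%-identical repeat. Published locus lengths
are reproduced from their printed coordinate pairs exactly (all 22
cells). The worked junction contexts bundled in `temark.wheat_loci` are
synthetic: they embed the published motifs and spacings exactly, with
screened random filler, and reproduce the published junction logic rather
than the wheat sequence itself.

## Known limitations

- Gapless blocks mean a single indel inside a repeat splits it into two
  blocks; downstream chaining handles this, but reported repeat lengths
  are then per-fragment.
- The SD-MMEJ search is exhaustive only within its window/round bounds;
  junctions synthesised from templates farther than ~80 bp from either
  breakpoint, or needing more than two rounds, are not explained.
- `chimeric_deletion` (deletion running from inside an element into its
  flank) is implemented in the decision tree but not exercised by the
  generator's event suite.
- The inversion label reports the spanned interval only; breakpoint
  micro-signatures of inversion junctions are not classified.
- Mechanism labels are evidence summaries, not certainties; the blunt
  label in particular is "blunt or ambiguous" by design.
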