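# temark

TE-anchored discovery and repair-mechanism classification of large-scale
rearrangements between two related genome assemblies.

## The problem

Allopolyploid plant genomes — wheat is the motivating case — undergo massive
large-scale rearrangements: deletions up to the megabase scale, segmental
duplications, inversions, and occasional introgression of DNA from unknown
sources. Because these events preferentially remove transposable-element
(TE)-rich sequence, a dynamic TE family makes an effective genetic marker:
insertions of one family are retrieved from both assemblies, matched across
genomes by their flanking sequence, and every donor-specific insertion points
at a candidate rearrangement locus. The breakpoints of each event are then
read off a dot-plot comparison of the orthologous loci, and the junction
sequence itself carries the fingerprint of the DNA-repair mechanism that
produced it.

`temark` implements that whole procedure as a tested, reusable pipeline for
anyone comparing two related assemblies through the lens of a TE family:

1. **Retrieval** — consensus-driven recovery of every family insertion with
   500 bp flanks, classified as full-length / truncated / solo LTR, with
   target-site duplications (TSDs) recorded.
2. **Cross-genome matching** — best-reciprocal flank pairing; unmatched
   insertions are candidate species-specific sites.
3. **Chromosome walking** — progressively longer flanks locate the
   orthologous locus of each candidate on the other genome.
4. **Breakpoint calling** — gapless similarity blocks (default: ≥100 bp at
   ≥95% identity, the dot-plot parameters under which breakpoints are
   defined as block borders) delimit each indel; lengths follow the 1-based
   closed convention, length = end − start + 1.
5. **Mechanism classification** — each junction is assigned to unequal
   intra-strand recombination (long direct repeats ≥100 bp / ≥95%),
   inter-LTR recombination (solo-LTR formation), MMEJ (1–9 bp junction
   repeat retained in single copy), SD-MMEJ (templated "filler" insertions
   reconstructed by one or two rounds of primer-repeat annealing and
   fill-in synthesis), blunt/C-NHEJ, introgression, or tandem copy-number
   variation. Loci whose breakpoints abut assembly N-runs are excluded as
   artifacts.

A mechanism-explicit genome-pair simulator generates donor/derived assembly
pairs with full ground truth (11 event types), so every stage is validated
end-to-end at desk scale.

## The junction model at its core

For a deletion of segment *D* between retained flanks *L* and *R*:

- **MMEJ**: *D* is flanked by a short direct repeat *m* (1 ≤ |m| ≤ 9);
  annealing across the break deletes *D* and retains exactly one copy of
  *m* at the junction: `L·m·D'·m·R → L·m·R`.
- **SD-MMEJ**: a DSB end's terminal bases (the *primer repeat* p) anneal
  to a matching site within ~35 bp of either breakpoint (direct loop-out
  or snap-back to the reverse complement), and fill-in synthesis copies a
  template tract *t*. After ≤2 rounds the two ends share a synthesis-made
  microhomology μ, anneal, and seal. The reconstruction is accepted only
  if replaying it regenerates the observed junction byte-for-byte:
  `L + appended + (prepended + R)[|μ|:] == L + net_insertion + R`.
- **Unequal intra-strand recombination**: *D* lies between two long direct
  repeats (≥100 bp, ≥95% identity); one (possibly hybrid) copy survives.
  The crossover point inside the repeat is inherently ambiguous, so calls
  carry an explicit `ambiguity_width` and all coordinates are
  leftmost-normalised.

## Worked example

Simulate a genome pair with one event of every mechanism, then run the full
pipeline against the planted ground truth:

```python
from temark import (SimConfig, default_event_suite, simulate_genome_pair,
                    synthetic_consensus, PipelineConfig, run_pipeline)
from temark.annotate import AnnotationTrack

cfg = SimConfig(n_chromosomes=2, chromosome_length=300_000,
                te_copies_per_chromosome=4,
                event_specs=default_event_suite(1), seed=5)
pair = simulate_genome_pair(cfg)
track = AnnotationTrack(records=list(pair.te_annotation))
result = run_pipeline(PipelineConfig(genome_a=pair.genome_a,
                                     genome_b=pair.genome_b,
                                     consensus=synthetic_consensus(),
                                     te_annotation=track))
print(f"{result.monomorphic} monomorphic insertions; "
      f"{len(result.loci)} rearranged loci; "
      f"{len(result.excluded)} assembly artifacts excluded")
for loc in sorted(result.loci, key=lambda l: (l.chromosome, l.a_interval)):
    print(f"{loc.chromosome}:{loc.a_interval[0]}-{loc.a_interval[1]}  "
          f"{loc.a_length:>6}/{loc.b_length:<5} {loc.rearrangement_type:22} "
          f"{loc.mechanism or loc.category}")
```

prints

```
9 monomorphic insertions; 10 rearranged loci; 1 assembly artifacts excluded
chr1:129396-134395    5000/0     deletion_in_b          unequal_recombination
chr1:157417-162416    5000/0     deletion_in_b          mmej
chr1:185494-190493    5000/0     deletion_in_b          blunt_cnhej_or_ambiguous
chr1:213492-218491    5000/2000  replacement            introgression
chr1:241633-246632    5000/5000  inversion              long_indel_candidate
chr2:144069-146768    2700/0     deletion_in_b          ltr_recombination
chr2:173211-178210    5000/3     deletion_in_b          sdmmej
chr2:203964-213963   10000/5000  copy_number_variation  cnv_duplication
chr2:239984-242989    3006/0     deletion_in_b          empty_site_tsd
chr2:269598-270797    1200/0     deletion_in_b          blunt_cnhej_or_ambiguous
```

Every planted event surfaces with its true mechanism, the deleted/replaced
lengths on both genomes (`a_length/b_length`), and the assembly artifact is
routed to the exclusion report. Junction reconstruction can also be used
directly — here on the bundled synthetic junction that reproduces the motif
layout of a published one-round SD-MMEJ case:

```python
from temark import worked_junction, reconstruct_sdmmej

wj = worked_junction("3B_2")
top = reconstruct_sdmmej(wj.donor_left, wj.donor_right,
                         wj.net_insertion, wj.deleted)[0]
print(f"primer repeat      {top.primer_repeat!r}")
print(f"synthesis tract    {top.synthesis_tract!r} ({top.total_synthesis} nt, "
      f"{top.synthesis_rounds} round)")
print(f"junction microhomology {top.junction_microhomology!r}")
print(f"net insertion      {top.net_insertion_explained!r}")
```

```
primer repeat      'A'
synthesis tract    'AATTTG' (6 nt, 1 round)
junction microhomology 'TTG'
net insertion      'AAT'
```

A 1 bp primer repeat annealed 22 bp upstream of the break, six nucleotides
of synthesis created the 3 bp `TTG` microhomology, and the junction retains
the 3 bp templated insertion `AAT` in place of the deleted segment.

## Command line

```
temark simulate  --config sim.yaml --seed 1 --outdir out/   # genome pair + truth
temark dotplot   A.fa B.fa --min-len 100 --min-id 0.95      # similarity blocks
temark retrieve  genome.fa consensus.fa --flank 500         # TE insertions (BED)
temark callindels --pairs loci.tsv A.fa B.fa                # breakpoint calls
temark run       --config pipeline.yaml                     # full pipeline
```

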