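# Methods

## Rationale

Chromosomal rearrangements can fuse two genes into a chimeric transcript.
Detecting such fusions from RNA-seq by splitting short reads and mapping
the pieces to the genome suffers from low alignment specificity of short
fragments. `fusiondart` instead compares the tumour transcriptome directly
with the reference transcriptome: whole reads (or assembled contigs) are
aligned against spliced transcript sequences, so splice-site alignment
never has to be solved, a breakpoint inside a sequence is evidence in
itself, and the method works unchanged from 100 bp reads to full-length
transcripts, paired- or single-end.

## Pipeline model and assumptions

A *tumour sequence* is a read (Direct mode), a user-supplied contig
(Assembly mode), or a contig supplemented with transcriptome-unmapped reads
(Hybrid mode; the mode policy follows read length: < 60 bp assembly,
60–99 bp hybrid, ≥ 100 bp direct, because a candidate needs 30 aligned
bases either side of its breakpoint). The model assumes fusion transcripts
are exonic concatenations of two annotated genes — fusions incorporating
intronic or intergenic sequence are invisible by construction, and
breakpoints inside exons can at best reach LowConfidence.

Stages and their contracts:

1. *Preliminary filtering.* Keep pairs concordant on the transcriptome
   (both mates ≥ 98 % of their bases matching one transcript, opposite
   strands, implied fragment ≤ 1 kb); send the rest to an exon-masked
   genome and keep only those that fail there too. This removes
   intronic/intergenic/mitochondrial fragments while never touching
   fusion-spanning pairs, which map to neither reference.
2. *Duplicate removal* on exact (mate1, mate2) sequence; swapped-mate
   pairs are distinct fragment representations and both survive.
3. *Unmapped-read selection* (Direct/Hybrid): a read is "explained" when
   one alignment matches ≥ 98 % of its bases — the local-alignment
   surrogate of an accepted end-to-end mapping. A fusion read split
   between genes is never explained, whatever the split ratio.
4. *Transcriptome alignment* with the internal aligner (below):
   ≥ 98 % identity, ≥ 30 matched bases, no subject-side gaps.
5. *Multigene selection.* Per gene, the best alignment (most matches,
   then longest query span, then lexicographic transcript id). A
   candidate needs a prefix from one gene and a suffix from another, each
   with ≥ 30 bases of breakpoint flank, gene spans ≥ 1 kb apart (or
   different chromosomes), alignment overlap ≤ 13 bases and unaligned
   insert ≤ 10 bases at the junction.
6. *Chimera (shared-sequence) filter.* The junction homology is the
   number of bases over which the breakpoint could slide with both
   partner alignments still exact (forward continuation of the 5′ partner
   plus backward continuation of the 3′ partner). Candidates with > 13
   shared bases are rejected: de novo assemblers with a 19-base minimum
   k-mer can weld two transcripts through such windows into false
   chimeras, and the 13-base cap keeps a safety margin below that.
7. *Support.* Contig mode re-maps the sample's reads to the candidate
   sequence (best hit, ≥ 95 % identity, concordant pairs only): spanning
   reads cover breakpoint ± 15 bp; spanning pairs have mates entirely on
   opposite sides. Direct mode assigns each discovered breakpoint one
   spanning read per discovering read and finds spanning pairs among
   transcriptome alignments: one mate wholly on the 5′ partner reading
   toward the junction and ending before it, the other wholly on the 3′
   partner reading back toward it, each within 1 kb of the junction (the
   fragment-length bound). Spanning pairs cannot exist when the junction
   sits near a transcript end. Single-end data has no spanning-pair
   count at all (reported as `-`), which caps calls at MediumConfidence.
8. *Genome resolution.* Candidates are aligned to the genome (tile 11,
   subject gaps unlimited so exon blocks chain across introns) and the
   breakpoint is projected through the blocks overlapping each partner
   gene's annotated span; a side with no such alignment (paralog capture)
   drops the candidate. Positions are reported 1-based: last base of the
   5′ side, first base of the 3′ side.
9. *Classification* (ordered): genomic gap < 10 kb → discard (gene
   families and repeats produce these); gap < 200 kb with no
   rearrangement evidence → PotentialRegularTranscript (read-through
   transcription between neighbouring genes; excluded from default
   output); breakpoints on annotated exon boundaries → HighConfidence
   when both spanning reads and spanning pairs are present, else
   MediumConfidence; off-boundary → LowConfidence with ≥ 2 spanning
   reads and ≥ 1 spanning pair, else discard. Rearrangement evidence
   means the two genomic segments cannot lie on one co-linear
   transcription path: different chromosomes, opposite segment
   orientations, candidate orientation relative to the annotated gene
   strand differing between sides, or the 3′ side upstream of the 5′
   side along the transcription direction.
10. *Frame.* When both breakpoints are exon boundaries inside coding
    regions, each gene contributes the modal phase (spliced coding offset
    mod 3) over its isoforms, ties to the smallest phase; equal phases →
    in-frame. Anything else → unknown.
11. *Merging and ranking.* Calls with identical genomic breakpoints merge
    (support sums, representative = most spanning reads, classification
    recomputed — merging can only upgrade). Ranking: class, then spanning
    reads + pairs descending, then genomic gap ascending with
    interchromosomal last, then name — boundary-aligned low-support calls
    outrank heavily covered off-boundary ones because boundary alignment
    is the stronger signal of a genuine pre-splicing rearrangement.

## The internal aligner

A seed-and-extend local aligner stands in for an external BLAT: exact
k-mer tiles (default 15; 18 for sequences ≥ 100 bp or contigs, trading
sensitivity for speed exactly where queries are long enough to afford it)
are looked up in a subject index, hits on diagonals within ±5 are
clustered, and each cluster is extended ungapped to the exactly optimal
interval under match +1 / mismatch −1 via prefix sums. Ties break toward
the shortest optimal interval so zero-scoring junk is never absorbed at
block edges; if the optimal interval still fails the identity threshold
(junk absorbed beyond the homologous region at net-positive score), the
interval is re-extracted under a mismatch penalty consistent with the
threshold (49:1 for 98 %), which cannot cross into junk. For genome
alignment, co-linear blocks chain across unlimited subject gaps
(introns) with ≤ 10 unaligned query bases between blocks; block overlaps
at exon junctions are resolved by choosing the split that maximises total
matches, ties toward the earlier block.

`min_score` counts matched bases with an inclusive bound (≥ 30), close to
BLAT's score for the near-exact alignments this pipeline relies on; exact
parity with BLAT's score and percent-identity formulas is deliberately not
attempted, since only threshold behaviour matters here. Query sampling is
sparse (stride = tile size, final window always included) against the
densely indexed transcriptome, and dense (every position) against the
sparsely indexed genome; either way an end-anchored exact match of one
tile length is guaranteed to seed. Alignments are PSL records
(21-column, 0-based half-open, negative-strand qStarts in
reverse-complement coordinates), byte-stable under write∘read.

Two placement refinements keep breakpoints canonical in the presence of
near-matches: (a) when the two partner alignments overlap on the query,
the breakpoint walks forward from the suffix alignment's start for as long
as the sequence still matches the 5′ transcript *exactly* — under h bases
of true microhomology this is the canonical 3′-most placement, while
score-driven over-extension through a mismatch is undone; (b) when genome
projection of a junction base finds no covering block inside the expected
gene span (the contested bases were assigned to the partner's block
because they match both loci), the nearest in-span block edge within 13
bases is extrapolated along its diagonal, which is exact for exactly those
ambiguous bases.

## Simulator

`simulate` reproduces the validation designs at desk scale:

- *Reference*: a random genome (default 20 multi-exon coding genes on 4
  chromosomes; exons 100–400 bp, introns 0.2–2 kb, random strands,
  random CDS offsets) with genes separated by 250 kb so genuine fusions
  can never be mistaken for read-through events; an optional adjacent-pair
  subset is placed 5 kb apart for read-through testing.
- *Fusions*: two distinct coding transcripts joined at random internal
  exon edges (5′ portion of one + 3′ portion of the other), partner genes
  ≥ 1 kb apart, one fusion per unordered gene pair. Junctions are
  resampled until the partners share zero bases of microhomology there,
  so the transcriptional breakpoint is unambiguous and the truth table's
  genomic coordinates are exact under the pipeline's canonical placement.
  Default tiers: 20 fusions at each of 1, 2, 5, 10, 50 and 100× average
  coverage over the fusion transcript.
- *Reads*: 250 bp pairs from fragments of length N(500, 100²) clipped to
  [read length, transcript length]; pairs per transcript =
  round(coverage × length / (2 × read length)); uniform per-base
  substitution errors at 0.4 % as a stand-in for a position-dependent
  sequencer error profile (no indels, no quality modelling).
- *Background*: pairs from non-fusion transcripts, allocated
  multinomially by a per-gene log-normal(0, 1) expression draw; no
  chimeric fragments are ever generated, so background-only datasets
  carry zero fusion signal by construction.

What passing the simulation-based tests does **not** show: robustness to
indels, position-dependent error profiles, PCR duplicates,
reverse-transcription template switching, paralogous gene families with
near-identical sequence, alternative isoform complexity, or real
expression distributions — the toy genome is random sequence, where
cross-gene homology is essentially impossible. The threshold sweeps use
constructed two-gene references whose genes draw from disjoint base
alphabets ({A,C} vs {G,T}), making every boundary exact by eliminating
accidental homology.

## Numerical and design choices

- Coordinates are 0-based half-open internally; output tables are 1-based.
  "Exon boundary" means either edge of any annotated exon; the match
  tolerance defaults to 0 bases (configurable).
- Gap = |pos_b − pos_a| on a shared chromosome, absent (and always
  passing the gap rules) otherwise; gap exactly 10 kb survives, exactly
  200 kb is reported.
- The 10 kb discard precedes the read-through flag and applies regardless
  of rearrangement evidence (stricter ordering).
- Direct-mode spanning pairs are counted once per transcript-level
  breakpoint group, not once per discovering read, so the same physical
  pair is never multiply counted; genomic merging of genuinely distinct
  candidates still sums.
- Ties in "best alignment per gene": matches, then query span, then
  lexicographic transcript id. Modal-frame ties go to the smallest phase.
  Representative-sequence ties go to the longest sequence, then the
  lexicographically smallest id.
- Problem sizes in the test suite and acceptance script (20-gene
  references, 50–100 k read pairs, 200 aligner-oracle instances) are the
  package's chosen desk-scale study conditions; they exercise every
  decision path of the pipeline while keeping the whole validation
  reproducible on a laptop.

## Known limitations

- No de novo assembly: Assembly/Hybrid modes expect contigs built
  elsewhere. No quality trimming or adapter handling.
- No intron-aware alignment scoring; genome alignment chains exact blocks
  and will not recover heavily diverged loci.
- Gene aliases are not resolved internally; the known-fusion list accepts
  an alias column instead.
- Single-end data cannot reach HighConfidence (no spanning pairs) and
  LowConfidence is unreachable for it by design.
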