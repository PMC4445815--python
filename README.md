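# fusiondart

Fusion gene detection in cancer RNA-seq by **transcriptome comparison**.
Instead of splitting short reads and mapping the fragments to the genome,
`fusiondart` aligns whole tumour sequences — RNA-seq reads used directly
(≥ 100 bp), or pre-assembled contigs for shorter reads — against the
reference *transcriptome*. Sequences whose alignments split cleanly between
two genes become fusion candidates; candidates are filtered for
shared-sequence chimeras, scored by read support, resolved on the genome and
classified by whether their breakpoints fall on annotated exon–exon
boundaries.

It is written for researchers who want a self-contained, scriptable fusion
caller for paired- or single-end reads of any length ≥ 60 bp, together with
a seeded simulator for validating the caller end to end.

## Method

For each sample the pipeline:

1. **Prefilters** read pairs: pairs mapping concordantly to the
   transcriptome are kept; the remainder are kept only if they *fail* to map
   to an exon-masked genome (removing intronic/intergenic fragments).
2. **Removes duplicates** (exact fragment sequence).
3. Builds **tumour sequences**: the reads themselves (Direct mode), user
   contigs (Assembly mode), or contigs plus transcriptome-unmapped reads
   (Hybrid mode, 60–99 bp reads).
4. **Aligns** tumour sequences to the transcriptome with an internal
   seed-and-extend local aligner (k-mer tiles, ungapped extension; ≥ 98 %
   identity over ≥ 30 matched bases, no subject gaps). Alignments are
   PSL-compatible, so externally produced BLAT output can be substituted.
5. **Selects multigene sequences**: a candidate needs ≥ 30 aligned bases on
   each side of the breakpoint from two genes ≥ 1 kb apart. Candidates whose
   partner transcripts share **> 13 bases** at the junction are rejected as
   assembly/homology chimeras; the breakpoint is placed at the 3′-most
   position compatible with the 5′ partner (canonical under microhomology).
6. **Counts support**: *spanning reads* contain the breakpoint with a flank
   on both sides (15 bp when re-mapping reads to a contig; a Direct-mode
   candidate starts with one spanning read); *spanning pairs* have their
   mates entirely on opposite sides, in fusion-consistent orientation.
7. **Resolves breakpoints on the genome** and classifies:
   gap < 10 kb → discarded (gene-family artifact);
   gap < 200 kb without rearrangement evidence → `PotentialRegularTranscript`
   (read-through, hidden by default);
   breakpoints on exon boundaries → `HighConfidence` (spanning reads *and*
   pairs) or `MediumConfidence`;
   off-boundary → `LowConfidence` (needs ≥ 2 spanning reads and a pair).
   In-frame status uses the modal coding frame of each gene's isoforms.
8. **Ranks** by class, then spanning reads + pairs, then genomic gap, and
   merges calls that predict the same genomic breakpoint.

## Worked example

Simulate a toy dataset (two fusions at 50× on an 8-gene reference plus
background) and call fusions on it:

```bash
printf 'n_genes: 8\nn_chroms: 2\ncoverage_tiers: [[50, 2]]\nn_background_pairs: 300\nseed: 6\n' > sim.yaml
fusiondart simulate -o sim --config sim.yaml
fusiondart run --mode direct \
    --ref-genome sim/genome.fa --ref-annot sim/annotation.gtf \
    --sample demo=sim/reads_1.fastq,sim/reads_2.fastq -o out
```

which prints

```
2 fusions, 602 read pairs written to sim
demo: 2 fusions reported
```

and writes `out/demo.csv` (one row per call):

```
sample,fusion_genes,chrom1,base1,strand1,chrom2,base2,strand2,gap,spanning_pairs,spanning_reads,inframe,aligns_to_exon_boundary,known,classification,contig_or_read_id
demo,GENE02:GENE06,chr1,506141,-,chr2,509667,+,-,7,38,no,yes,no,HighConfidence,fusion001_98/2
demo,GENE07:GENE04,chr2,765910,-,chr1,1015908,-,-,8,29,yes,yes,no,HighConfidence,fusion002_91/2
```

Both simulated fusions are recovered as `HighConfidence`: each is supported
by dozens of breakpoint-spanning reads (38 and 29) and several spanning
pairs, the genomic breakpoints (1-based `base1` = last base of the 5′
partner, `base2` = first base of the 3′ partner) coincide exactly with the
rows of `sim/fusions_truth.tsv` and fall on annotated exon boundaries
(`gap` is `-` because the partners are interchromosomal), and `inframe`
reports whether the 3′ partner's reading frame is preserved. `out/demo.fasta`
holds the representative breakpoint sequences.

The library API mirrors the CLI (`fusiondart.run_sample`,
`fusiondart.SimConfig`, …); see the module docstrings and
`docs/methods.md` for the model details and parameter meanings.

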