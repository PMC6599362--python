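# plantmir

Plant miRNA gene prediction from small-RNA sequencing alignments.

Plant genomes encode hundreds of *MIR* genes whose hairpin precursors are far
more heterogeneous in size and structure than their animal counterparts, and
whose 24-nt products are easily confounded with heterochromatic siRNAs.
`plantmir` identifies miRNA-producing loci directly from a genome (FASTA) and
mapped sRNA-seq reads (BED, convertible from SAM/BAM): it finds read-enriched
regions that can fold into stable stem-loops, and grades every candidate with
an explicit, interpretable 0–6 star quality score instead of a black-box
classifier. It is written for small-RNA biologists annotating miRNAs in plant
genomes and for tool builders who need a scriptable, deterministic pipeline.

## Method

1. **Prefilter.** Reads overlapping masked annotation (CDS, tRNA, rRNA,
   snoRNA) are removed, reads mapping to more than 5 genomic loci are
   discarded (customizable), and reads inside known precursor coordinates are
   reported separately as expressed known miRNAs.
2. **Locus discovery.** Reads are gap-merged into clusters; a closed-form 1-D
   2-means on log₁₀ cluster counts separates enriched peaks from background.
   Each peak must base-pair (C-G, A-U, G-U; ≥14 pairs, ≤2 small bulges) with
   a window up to 350 nt away — the necessary signature of a stem-loop arm.
3. **Hairpin.** Candidate loci are folded with the ViennaRNA local-folding
   engine; single-terminal-loop components of 60–350 nt with ≥50% paired
   bases are kept. Each hairpin gets MFE (kcal/mol), AMFE = MFE/len·100 and
   MFEI = AMFE/GC%; an optional filter keeps MFEI < −0.6, and a
   dinucleotide-preserving shuffle test gives an empirical stability p-value.
4. **Scoring.** One star per criterion:
   C1 MFEI < −0.8; C2 ≥10 read copies per arm or ≥100 in total; C3 the most
   common read holds ≥33% of copies (it becomes the guide); C4 ≥75% of copies
   start within [−3,+3] of the guide or [−5,+5] of the expected passenger
   position; C5 ≥1 copy in the passenger window; C6 stable guide:passenger
   duplex with 2-nt 3′ overhangs (rule-based, pluggable). Loci without a
   clear miRNA score ≤2; without passenger evidence ≤5.
5. **Annotation.** Conservation against known mature miRNAs (≤3
   mismatches/indels, none adjacent), genomic duplication check of the guide,
   and weight = guide copies / genomic occurrences.

Exports: CSV summary, GFF3, dot-bracket FASTA, ORG-mode report and text read
clouds.

## Worked example

```
python examples/01_worked_example.py
```

```
precursor: 72 nt, MFE -48.1 kcal/mol, AMFE -66.8, MFEI -1.20
guide:     AGAUAUUAGUGCGGUUCAAUC (21 nt, 71/114 copies = 62%)
passenger: UUGAGCCGUGCCAAUAUCACG (27 copies, 3' overhang 2 nt)
criteria:  [True, True, True, True, True, True]
score:     6/6 stars
```

The locus carries 114 read copies over 7 unique reads. The dominant read
(71 copies, 62%) becomes the guide; 27 copies support the passenger exactly
at the position implied by the 2-nt-overhang duplex geometry; the hairpin is
strongly stable (MFEI −1.20 < −0.8). All six criteria hold, so the locus is
graded 6 stars — the highest-confidence class. The script then prints the
read cloud: sequence, structure, duplex brackets, and one line per unique
read with its length and depth.

Other examples cover the end-to-end pipeline on a synthetic genome
(`02_full_pipeline.py`), stability statistics and the shuffle test
(`03_stability_statistics.py`), and conservation/duplication annotation
(`04_conservation_and_duplication.py`).

## Command line

```
plantmir fixtures --out fix/ --seed 3        # synthetic genome + reads + truth
plantmir predict --genome fix/genome.fa --bed fix/reads.bed --out results/
plantmir bam2bed aligned.sam reads.bed       # SAM/BAM -> collapsed BED
```

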