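# Methods

## Model and assumptions

A plant *MIR* locus is modeled as a genomic interval that (i) accumulates
sRNA-seq reads in a characteristic two-stack profile — a dominant ~21-nt
guide and a rarer passenger offset by Dicer-type 2-nt 3′ overhangs — and
(ii) folds into a thermodynamically stable single-terminal-loop stem-loop.
The pipeline requires both signals: read evidence drives discovery, and
secondary structure gates and grades it. It assumes reads are already
adapter-trimmed and mapped (any short-read mapper; alignments supplied as
BED or SAM/BAM), and that miRNA expression is strand-specific.

All internal coordinates are 0-based half-open on the forward genome axis;
precursor-local coordinates run 5′→3′ on the expressed strand. Conversion
to 1-based conventions happens only at GFF boundaries.

## Stage-by-stage choices

### Prefiltering

Reads are partitioned with priority **known-miRNA > annotation mask >
multi-mapper**, which makes the filter report an exact partition of the
input (`n_input = n_known + n_masked + n_multimap + n_retained`). Masking
uses a ≥1-bp overlap on either strand — the conservative reading of
coordinate-based masking; known-precursor assignment additionally requires
strand agreement because miRNA biogenesis is strand-specific. The
multi-mapper cutoff removes reads with more than 5 genomic hits (default,
configurable); hit counts ride along in an optional 7th BED column and are
recomputed by the SAM converter.

### Peak calling

Reads separated by ≤30 nt (`cluster_gap`) are merged into raw clusters.
Enrichment is decided by 1-D 2-means on log₁₀ of cluster copy totals; on
sorted 1-D data the 2-means optimum is an exact split point, so the step is
deterministic and seed-free. Clusters in the high group become peaks, as
does any cluster with ≥10 copies (`peak_floor`) — the floor rescues genuine
passenger stacks (e.g. 27 copies next to a 1000-copy guide) that 2-means
assigns to the low group. If all clusters tie, all are kept; there is
nothing to separate.

### Duplex-partner search

Each peak must be able to pair with a window up to 350 nt up- or downstream
(`max_distance`). Pairing counts C-G, A-U and G-U interactions over the
best antiparallel alignment, allowing at most 2 bulges of ≤2 nt each,
computed by a banded DP vectorized across all windows; the default
acceptance threshold is 14 paired bases of a ~21-nt query (≈2/3), chosen so
canonical duplexes with a few mismatches pass while most random windows
fail. Peaks longer than 25 nt (`partner_query_len`) — typically a merged
guide+passenger cloud — are represented by their highest-depth 25-nt
sub-window, and only that query window is excluded from the search; this
keeps the opposite arm of an already-merged cloud discoverable, which a
whole-peak exclusion would forbid.

### Hairpin selection and thermodynamics

Candidate spans (peak ∪ partner window, ±30 nt flank) are folded with the
ViennaRNA sliding-window local-folding engine (window capped at 350 nt, the
same bound as the search radius). Each locally stable structure is reduced
to its maximal single-stem components: one per terminal loop, extended
outward while each enclosing pair encloses only that branch, which trims
external tails and dissolves multiloops. Components of 60–350 nt with ≥50%
paired bases qualify; the lowest evaluated free energy wins, with leftmost
as the tie-break.

MFE is the nearest-neighbor (Matthews–Turner) free energy of the selected
structure; AMFE = MFE/length×100 normalizes across precursor sizes; MFEI =
AMFE/GC% corrects for base composition. GC is expressed in percent units
(50, not 0.5) so that the conventional MFEI thresholds (−0.6 screening,
−0.8 for the stability star) keep their printed magnitudes. A GC-free
sequence leaves MFEI undefined and the candidate is rejected with a logged
reason.

The optional significance test draws dinucleotide-preserving shuffles
(Altschul–Erickson Eulerian-path sampling, implemented here; it preserves
all 16 dinucleotide counts and both terminal nucleotides, the invariants
the nearest-neighbor energy model cares about), folds each globally, and
reports the pseudocount-corrected empirical p = (k+1)/(n+1) with n = 100 by
default. It is a diagnostic, not a score component, and is off in the
default pipeline.

### Scoring

Criteria and their exact boundaries:

| star | criterion | boundary |
|---|---|---|
| C1 | hairpin stability | MFEI < −0.8, strict |
| C2 | read support | ≥10 copies on each arm, or ≥100 total |
| C3 | miRNA exists | top unique read ≥ 1/3 of copies (exact fraction) |
| C4 | processing precision | ≥3/4 of copies start in guide ±3 or passenger ±5 |
| C5 | passenger expressed | ≥1 copy starts in passenger ±5 |
| C6 | duplex stability | see below |

Frequencies compare exact rationals (`Fraction`), so 34/102 counts as
exactly one third and passes, while 33/100 fails; copy counts (not unique
reads) are used throughout. A read belongs to the arm holding the majority
of its span; loop-straddling reads count toward totals but no arm. Guide
ties break by 5′-most start, then lexicographic sequence. The expected
passenger 5′ start maps the guide base 2 positions in from its 3′ end
through the structure's pair table (linear extrapolation from the nearest
paired base when that base is unpaired) — the 2-nt 3′-overhang geometry.

C6 is a rule-based predicate behind a pluggable interface
(`ScoringConfig.duplex_rule` accepts any callable on (hairpin, guide)): the
built-in rule requires ≥75% of guide bases paired outside the guide
interval, no internal loop >3 nt on either duplex strand, and — when a
passenger read is observed — its start within ±1 nt of the expected
position. A machine-learned duplex classifier can be slotted in without
touching the pipeline. Structure-only passengers (no reads) satisfy the
overhang clause by construction, which is what makes a guide-only locus
able to reach 5 stars but never 6: C5 demands actual passenger reads.

Consequences of the definitions, verified by randomized sweeps: no defined
guide ⇒ C3–C6 false ⇒ score ≤ 2; guide but empty passenger window ⇒ C5
false ⇒ score ≤ 5.

### Annotation and reporting

Conservation hits are computed by a semi-global edit-distance DP (query =
known mature, free ends on the precursor) with ≤3 total edits and a state
bit forbidding adjacent indel columns; one best (fewest edits, leftmost)
hit per database entry. Hits overlapping the guide are "double-checked" in
the summary. The duplication check is an exact scan of the guide and its
reverse complement over the whole genome; weight = guide copies / number of
occurrences. Note that a perfect-complement stem makes the guide's reverse
complement occur at its own passenger arm, halving the weight — visible on
mismatch-free synthetic fixtures, rare on real precursors.

Overlapping same-strand predictions (one locus discovered from both its
guide and passenger peaks) are deduplicated keeping the higher score, then
lower MFE, then leftmost. Predictions are named `chrom__start-end_strand`.
The pipeline contains no random number draws, so identical inputs give
byte-identical exports.

## Synthetic data

The generators plant hairpins with a random GC-controlled 5′ arm, an exact
reverse-complement 3′ arm, optional non-pairing mismatches (kept away from
helix ends), and a loop; passenger offsets follow the overhang geometry on
the planted structure. Read clouds place guide and passenger stacks at
their planted offsets and spread degradation reads uniformly with ±3-nt
start jitter and 1+Poisson(1) copies, truncated so copy totals are exact.
Default cloud sizes (71 guide / 27 passenger / 16 background, 114 copies
over 7 unique reads) mirror the bundled worked example. Genomes are uniform
random DNA with planted precursors, optional tandem repeats (multi-mapping
traps) and CDS mask features.

What the generators do **not** emulate: sequencing errors, isomiR length
heterogeneity, expression from both strands, chained/overlapping loci, GC
composition gradients, and hc-siRNA-like dsRNA loci. Passing tests
therefore demonstrate the pipeline's correctness on clean two-stack clouds
and its specificity on featureless background, not its false-positive rate
against heterochromatic siRNA loci in real genomes.

Sweep-style checks use a pool of 40 folded hairpins with fresh random read
clouds per locus (1000 loci per sweep): cloud randomness dominates the
variability being tested, and folding is the expensive step. The
end-to-end sensitivity/specificity sweeps use 20 seeds each on 10-kb
genomes with one planted locus (guide 40–120 copies, passenger 5–40, ≤2
stem mismatches, degradation at ~15% of signal).

## Known limitations

* The duplex-partner DP is a declared substitute for an exact published
  binding test; its threshold (14/21) and bulge policy are config-exposed.
* C6 is a geometric rule, not a trained classifier; borderline duplexes
  (large asymmetric loops just under the limits) may be graded differently
  than a learned model would.
* Minus-strand loci are fully supported in the data model and pipeline, but
  the synthetic genome generator plants precursors on the forward strand
  only.
* The conservation aligner reports one best hit per database sequence, not
  all co-optimal locations.
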