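"""Readers and writers for every external format the pipeline touches.

Coordinate conventions at file boundaries:

* BED: 0-based half-open (as internal).
* GFF3: 1-based inclusive in the file, converted at read/write time.
* SAM/BAM: parsed with pysam, which already exposes 0-based coordinates.

The BED dialect carries the read sequence in column 4, the collapsed copy
count in column 5, the strand in column 6, and (optionally) the number of
genome-wide hits of the read sequence in column 7.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
from Bio import SeqIO

from .model import (
    AnnotationFeature,
    GenomeIndex,
    Prediction,
    ReadAlignment,
    revcomp_dna,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed record in an input file."""


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> GenomeIndex:
    """Load a FASTA genome into memory."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeIndex(seqs)


def read_mature_db(path: str | Path) -> list[tuple[str, str]]:
    """Load a mature-miRNA FASTA (miRBase ``mature.fa`` dialect).

    Returns ``(id, sequence)`` pairs with sequences as RNA (T -> U).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    return out


def read_bed(path: str | Path) -> list[ReadAlignment]:
    """Parse the alignment BED dialect into ReadAlignment records."""
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                seq = fields[3].upper()
                count = int(fields[4])
                strand = fields[5]
                hits = int(fields[6]) if len(fields) > 6 and fields[6] else 1
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if count <= 0:
                raise FormatError(f"{path}: line {lineno}: count must be positive")
            try:
                reads.append(
                    ReadAlignment(chrom, start, end, strand, seq, count, hits)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return reads


def sam_to_bed(path_sam: str | Path) -> list[ReadAlignment]:
    """Convert SAM/BAM alignments to collapsed ReadAlignment records.

    Identical reads at the same locus are collapsed with summed copy count;
    ``n_genomic_hits`` is the number of distinct loci each read sequence
    aligns to anywhere in the file.  Minus-strand alignments are stored with
    the sequence reverse-complemented back to read orientation.
    """
    path = str(path_sam)
    mode = "rb" if path.endswith(".bam") else "r"
    counts: Counter[tuple[str, int, int, str, str]] = Counter()
    n_mapped = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            n_mapped += 1
            strand = "-" if aln.is_reverse else "+"
            seq = aln.query_sequence.upper()
            if aln.is_reverse:
                # pysam reports the reference-forward sequence
                seq = revcomp_dna(seq)
            key = (
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                strand,
                seq,
            )
            counts[key] += 1
    if n_mapped == 0:
        logger.warning("%s: no mapped reads", path)
        return []
    loci_per_seq: defaultdict[str, int] = defaultdict(int)
    for (_, _, _, _, seq) in counts:
        loci_per_seq[seq] += 1
    reads = [
        ReadAlignment(chrom, start, end, strand, seq, n, loci_per_seq[seq])
        for (chrom, start, end, strand, seq), n in counts.items()
    ]
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand, r.sequence))
    return reads


def read_gff(
    path: str | Path,
    feature_types: set[str] | None = None,
    strict: bool = False,
) -> list[AnnotationFeature]:
    """Parse a GFF3 file into AnnotationFeatures (0-based half-open).

    ``feature_types`` restricts output to the given SO types; an empty or None
    set keeps everything.  Unparsable lines are skipped with a warning unless
    ``strict`` is set.
    """
    wanted = feature_types or set()
    out: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
                if feat.start is None or feat.end is None:
                    raise ValueError("missing coordinates")
                ann = AnnotationFeature(
                    chrom=feat.seqid,
                    start=int(feat.start) - 1,  # GFF is 1-based inclusive
                    end=int(feat.end),
                    strand=feat.strand or ".",
                    feature_type=feat.featuretype,
                    attributes=str(feat.attributes) if feat.attributes else "",
                )
            except Exception as exc:
                if strict:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
                logger.warning("%s: line %d unparsable, skipped (%s)", path, lineno, exc)
                continue
            if wanted and ann.feature_type not in wanted:
                continue
            out.append(ann)
    return out


# ---------------------------------------------------------------------------
# writers


def write_bed(reads: Iterable[ReadAlignment]) -> str:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.sequence}\t{r.count}\t{r.strand}\t{r.n_genomic_hits}"
        for r in reads
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_gff(predictions: Sequence[Prediction]) -> str:
    """GFF3 export of predictions (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for p in predictions:
        h = p.hairpin
        attrs = f"ID={p.name};quality_score={p.quality.score};mfei={h.mfei:.3f}"
        lines.append(
            "\t".join(
                [
                    h.chrom,
                    "plantmir",
                    "miRNA_primary_transcript",
                    str(h.start + 1),
                    str(h.end),
                    str(p.quality.score),
                    h.strand,
                    ".",
                    attrs,
                ]
            )
        )
        if p.duplex is not None:
            g0, g1 = _guide_genomic_interval(p)
            lines.append(
                "\t".join(
                    [
                        h.chrom,
                        "plantmir",
                        "miRNA",
                        str(g0 + 1),
                        str(g1),
                        ".",
                        h.strand,
                        ".",
                        f"ID={p.name}.mature;Parent={p.name}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def _guide_genomic_interval(p: Prediction) -> tuple[int, int]:
    h = p.hairpin
    assert p.duplex is not None
    s = p.duplex.guide_local_start
    e = s + len(p.duplex.guide_seq)
    if h.strand == "+":
        return h.start + s, h.start + e
    return h.end - e, h.end - s


CSV_COLUMNS = [
    "name",
    "position",
    "strand",
    "reads",
    "reads_flag",
    "reads_distribution",
    "mfei",
    "mfei_flag",
    "mirna_sequence",
    "mirna_length",
    "weight",
    "alignment",
]


def write_csv(predictions: Sequence[Prediction]) -> str:
    """CSV export mirroring the summary table."""
    from .report import summary_rows  # local import to avoid a cycle

    lines = [",".join(CSV_COLUMNS)]
    for row in summary_rows(predictions):
        lines.append(",".join(str(row[c]) for c in CSV_COLUMNS))
    return "\n".join(lines) + "\n"


def write_dotbracket(predictions: Sequence[Prediction]) -> str:
    """FASTA-with-structure export: header, sequence, dot-bracket per candidate."""
    chunks = []
    for p in predictions:
        h = p.hairpin
        chunks.append(f">{p.name}\n{h.sequence}\n{h.structure} ({h.mfe:.2f})\n")
    return "".join(chunks)


def write_org(predictions: Sequence[Prediction]) -> str:
    """Plain-text report in ORG-mode outline format."""
    from .report import render_read_cloud

    lines = ["#+TITLE: plantmir predictions", ""]
    for p in predictions:
        h = p.hairpin
        lines.append(f"* {p.name}")
        lines.append(f"  :position: {h.chrom}:{h.start + 1}-{h.end} ({h.strand})")
        lines.append(f"  :quality_score: {p.quality.score}")
        lines.append(
            f"  :mfe: {h.mfe:.2f} kcal/mol  :amfe: {h.amfe:.2f}  :mfei: {h.mfei:.3f}"
        )
        lines.append(f"  :reads: {p.total_reads} ({p.n_unique_reads} unique)")
        if p.duplex is not None:
            lines.append(f"  :guide: {p.duplex.guide_seq} ({p.duplex.guide_arm})")
        lines.append("")
        lines.append("#+BEGIN_EXAMPLE")
        lines.append(render_read_cloud(p).rstrip("\n"))
        lines.append("#+END_EXAMPLE")
        lines.append("")
    return "\n".join(lines) + "\n"
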