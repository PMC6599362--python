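"""Read prefiltering: annotation masking, multimapper removal, known loci.

Filters are applied in a fixed priority order — known-miRNA assignment first,
then annotation masking, then multimapper removal — so that the counts in
:class:`~plantmir.model.FilterReport` partition the input exactly.  All
filters preserve input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import AnnotationFeature, FilterReport, ReadAlignment

logger = logging.getLogger(__name__)

#: Annotation types masked by default: protein-coding and structural RNA loci
#: whose degradation products would otherwise produce spurious hairpins.
DEFAULT_MASK_TYPES = {"CDS", "tRNA", "rRNA", "snoRNA"}


def _overlaps(read: ReadAlignment, feat: AnnotationFeature) -> bool:
    return read.chrom == feat.chrom and read.start < feat.end and feat.start < read.end


def mask_by_annotation(
    reads: list[ReadAlignment], features: list[AnnotationFeature]
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Split reads into (retained, masked) by >=1 bp overlap with any feature.

    Masking is strand-agnostic: a read is discarded whichever strand the
    overlapping feature is annotated on.
    """
    by_chrom: dict[str, list[AnnotationFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for fl in by_chrom.values():
        fl.sort(key=lambda f: f.start)
    retained, masked = [], []
    for r in reads:
        hit = any(_overlaps(r, f) for f in by_chrom.get(r.chrom, ()))
        (masked if hit else retained).append(r)
    return retained, masked


def filter_multimapped(
    reads: list[ReadAlignment], max_hits: int = 5
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Remove reads mapping to more than ``max_hits`` genomic loci."""
    if max_hits < 1:
        raise ValueError(f"max_hits must be >= 1, got {max_hits}")
    retained = [r for r in reads if r.n_genomic_hits <= max_hits]
    removed = [r for r in reads if r.n_genomic_hits > max_hits]
    return retained, removed


@dataclass
class KnownLocusReport:
    """Expressed known-precursor loci with their read counts."""

    feature: AnnotationFeature
    total_count: int = 0
    reads: list[ReadAlignment] = field(default_factory=list)


def detect_known_mirnas(
    reads: list[ReadAlignment], known_precursors: list[AnnotationFeature]
) -> tuple[list[KnownLocusReport], list[ReadAlignment]]:
    """Assign reads to known miRNA precursor loci; return the rest.

    A read belongs to a known precursor when it overlaps it by >=1 bp on the
    same strand.  Assigned reads are excluded from de novo discovery.  Only
    precursors with at least one assigned read are reported.
    """
    reports = [KnownLocusReport(f) for f in known_precursors]
    remaining: list[ReadAlignment] = []
    for r in reads:
        assigned = False
        for rep in reports:
            f = rep.feature
            if _overlaps(r, f) and (f.strand == "." or f.strand == r.strand):
                rep.reads.append(r)
                rep.total_count += r.count
                assigned = True
                break
        if not assigned:
            remaining.append(r)
    return [rep for rep in reports if rep.reads], remaining


def apply_prefilters(
    reads: list[ReadAlignment],
    mask_features: list[AnnotationFeature] | None = None,
    known_precursors: list[AnnotationFeature] | None = None,
    max_hits: int = 5,
) -> tuple[list[ReadAlignment], list[KnownLocusReport], FilterReport]:
    """Run the full prefilter stage (known > mask > multimap priority)."""
    report = FilterReport(n_input=len(reads))
    known_reports, remaining = detect_known_mirnas(reads, known_precursors or [])
    report.n_known_mirna = sum(len(k.reads) for k in known_reports)
    if mask_features:
        remaining, masked = mask_by_annotation(remaining, mask_features)
        report.n_masked = len(masked)
    remaining, removed = filter_multimapped(remaining, max_hits=max_hits)
    report.n_multimap_removed = len(removed)
    report.n_retained = len(remaining)
    report.check()
    logger.info(
        "prefilter: %d in, %d known-miRNA, %d masked, %d multimap-removed, %d retained",
        report.n_input,
        report.n_known_mirna,
        report.n_masked,
        report.n_multimap_removed,
        report.n_retained,
    )
    return remaining, known_reports, report
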