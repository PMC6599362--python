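"""Prediction assembly, read-cloud rendering, summary table, pipeline driver."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import annotate, formats_io, hairpin as hairpin_mod, locus_discovery, prefilter
from .config import PipelineConfig
from .model import (
    FilterReport,
    GenomeIndex,
    Hairpin,
    Prediction,
    ReadAlignment,
    ReadCloudLocus,
    locus_name,
)
from .prefilter import KnownLocusReport
from .scoring import compute_quality_score

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """62.28 -> 62, 62.5 -> 63 (half rounds away from zero)."""
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# read cloud


def render_read_cloud(prediction: Prediction) -> str:
    """Text view of a precursor: sequence, structure, duplex, reads.

    Layout, line by line: the precursor sequence; its dot-bracket structure;
    a duplex-highlight line with square brackets over the guide and
    passenger intervals (when a guide is defined); a conservation line
    marking known-miRNA alignments with ``^`` (when hits exist); then one
    line per unique read — asterisks over the read's interval padded with
    dots, annotated ``length=L depth=D``.  The guide's own line prints its
    sequence in letters.
    """
    h = prediction.hairpin
    n = len(h.sequence)
    lines = [h.sequence, h.structure]

    duplex = prediction.duplex
    if duplex is not None:
        marks = ["."] * n
        spans = [(duplex.guide_local_start, len(duplex.guide_seq))]
        if duplex.star_local_start is not None and duplex.star_seq:
            spans.append((duplex.star_local_start, len(duplex.star_seq)))
        for start, length in spans:
            lo, hi = max(0, start), min(n, start + length)
            for i in range(lo, hi):
                marks[i] = "="
            if lo < n:
                marks[lo] = "["
            if hi - 1 >= 0:
                marks[hi - 1] = "]"
        lines.append("".join(marks))

    if prediction.conservation:
        marks = ["."] * n
        for hit in prediction.conservation:
            for i in range(max(0, hit.local_start), min(n, hit.local_end)):
                marks[i] = "^"
        lines.append("".join(marks))

    order = sorted(
        zip(prediction.locus.reads, prediction.locus.local_starts),
        key=lambda rs: (rs[1], rs[0].sequence),
    )
    guide_key = None
    if duplex is not None:
        guide_key = (duplex.guide_seq, duplex.guide_local_start)
    for read, start in order:
        lo, hi = max(0, start), min(n, start + len(read.sequence))
        if (read.sequence, start) == guide_key:
            body = read.sequence[lo - start : hi - start]
        else:
            body = "*" * (hi - lo)
        line = "." * lo + body + "." * (n - hi)
        lines.append(f"{line} length={len(read.sequence)} depth={read.count}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# summary table


def _alignment_flag(p: Prediction) -> str:
    if not p.conservation:
        return "none"
    if any(hit.overlaps_guide for hit in p.conservation):
        return "double-checked"
    return "checked"


def summary_rows(predictions: list[Prediction]) -> list[dict]:
    rows = []
    for p in predictions:
        h = p.hairpin
        q = p.quality
        rows.append(
            {
                "name": p.name,
                "position": f"{h.chrom}:{h.start + 1}-{h.end}",
                "strand": h.strand,
                "reads": p.total_reads,
                "reads_flag": q.c2,
                "reads_distribution": int(q.c4) + int(q.c5) + int(q.c6),
                "mfei": f"{h.mfei:.3f}",
                "mfei_flag": q.c1,
                "mirna_sequence": p.duplex.guide_seq if p.duplex else "",
                "mirna_length": len(p.duplex.guide_seq) if p.duplex else 0,
                "weight": f"{p.weight:g}" if p.weight is not None else "",
                "alignment": _alignment_flag(p),
                "_chrom": h.chrom,
                "_start": h.start,
                "_score": q.score,
            }
        )
    return rows


def build_summary(predictions: list[Prediction], sort: str = "position") -> pd.DataFrame:
    """Summary table, one row per prediction.

    ``sort='position'`` orders by genomic position; ``sort='quality'``
    orders by descending star score with position as tie-break.
    """
    if sort not in ("position", "quality"):
        raise ValueError(f"unknown sort key {sort!r}")
    rows = summary_rows(predictions)
    if sort == "position":
        rows.sort(key=lambda r: (r["_chrom"], r["_start"]))
    else:
        rows.sort(key=lambda r: (-r["_score"], r["_chrom"], r["_start"]))
    df = pd.DataFrame(rows, columns=formats_io.CSV_COLUMNS + ["_chrom", "_start", "_score"])
    return df.drop(columns=["_chrom", "_start", "_score"])


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    predictions: list[Prediction]
    filter_report: FilterReport
    known_loci: list[KnownLocusReport] = field(default_factory=list)

    def export_all(self) -> dict[str, str]:
        preds = self.predictions
        return {
            "summary.csv": formats_io.write_csv(preds),
            "predictions.gff": formats_io.write_gff(preds),
            "structures.txt": formats_io.write_dotbracket(preds),
            "report.org": formats_io.write_org(preds),
            "readclouds.txt": "\n".join(
                f">{p.name}\n{render_read_cloud(p)}" for p in preds
            ),
        }


def attach_reads(
    hp: Hairpin, reads: list[ReadAlignment]
) -> ReadCloudLocus:
    """Collect same-strand reads intersecting the hairpin; localize starts.

    Local offsets are on the precursor's 5'->3' axis: for a minus-strand
    hairpin the read's genomic end maps to its local 5' start.
    """
    locus = ReadCloudLocus(hairpin=hp)
    for r in reads:
        if r.chrom != hp.chrom or r.strand != hp.strand:
            continue
        if r.start < hp.end and hp.start < r.end:
            locus.reads.append(r)
            if hp.strand == "+":
                locus.local_starts.append(r.start - hp.start)
            else:
                locus.local_starts.append(hp.end - r.end)
    return locus


def _rebase(hp: Hairpin, cand_start: int, cand_end: int, chrom: str, strand: str) -> None:
    """Turn select_stemloop's local coordinates into genomic ones."""
    local_start, local_end = hp.start, hp.end
    if strand == "+":
        hp.start = cand_start + local_start
        hp.end = cand_start + local_end
    else:
        hp.start = cand_end - local_end
        hp.end = cand_end - local_start
    hp.chrom = chrom
    hp.strand = strand


def _dedupe(predictions: list[Prediction]) -> list[Prediction]:
    """Collapse overlapping same-strand predictions, keeping the best.

    Best = higher star score, then lower MFE, then leftmost.
    """
    ranked = sorted(
        predictions,
        key=lambda p: (-p.quality.score, p.hairpin.mfe, p.hairpin.chrom, p.hairpin.start),
    )
    kept: list[Prediction] = []
    for p in ranked:
        h = p.hairpin
        clash = any(
            k.hairpin.chrom == h.chrom
            and k.hairpin.strand == h.strand
            and h.start < k.hairpin.end
            and k.hairpin.start < h.end
            for k in kept
        )
        if not clash:
            kept.append(p)
    kept.sort(key=lambda p: (p.hairpin.chrom, p.hairpin.start, p.hairpin.strand))
    return kept


def run_pipeline(
    config: PipelineConfig,
    genome: GenomeIndex | None = None,
    reads: list[ReadAlignment] | None = None,
) -> PipelineResult:
    """Execute the full prediction workflow.

    Inputs may be passed pre-loaded (``genome``, ``reads``) or as paths in
    the config.  Stages: prefilter -> peak calling -> duplex-partner search
    -> local folding & stem-loop selection -> thermodynamics -> scoring ->
    annotation -> deduplicated, named predictions.  The pipeline is
    deterministic for fixed inputs.
    """
    if genome is None:
        if config.genome_fasta is None:
            raise ValueError("no genome provided (genome_fasta unset)")
        genome = formats_io.read_fasta(config.genome_fasta)
    if reads is None:
        if config.bed is None:
            raise ValueError("no reads provided (bed unset)")
        reads = formats_io.read_bed(config.bed)

    mask_features = []
    if config.mask_annotations and config.annotation_gff:
        mask_features = formats_io.read_gff(config.annotation_gff, set(config.mask_types))
    known = (
        formats_io.read_gff(config.known_mirna_gff)
        if config.known_mirna_gff
        else []
    )
    mature_db = (
        formats_io.read_mature_db(config.mature_db) if config.mature_db else []
    )

    retained, known_reports, filt_report = prefilter.apply_prefilters(
        reads,
        mask_features=mask_features,
        known_precursors=known,
        max_hits=config.max_genomic_hits,
    )

    peaks = locus_discovery.call_peaks(
        retained, cluster_gap=config.cluster_gap, peak_floor=config.peak_floor
    )
    candidates = []
    for peak in peaks:
        cand = locus_discovery.find_duplex_partner(
            peak,
            genome,
            reads=retained,
            max_distance=config.max_distance,
            min_paired=config.min_paired,
            query_len=config.partner_query_len,
        )
        if cand is not None:
            candidates.append(cand)
    logger.info("discovery: %d peaks -> %d paired candidates", len(peaks), len(candidates))

    predictions: list[Prediction] = []
    for cand in candidates:
        lo = max(0, cand.start - config.fold_flank)
        hi = min(genome.lengths[cand.chrom], cand.end + config.fold_flank)
        seq = genome.fetch_rna(cand.chrom, lo, hi, cand.strand)
        try:
            folds = hairpin_mod.fold_locally(seq, max_span=config.max_hairpin_len)
        except ValueError as exc:
            logger.warning("candidate %s:%d-%d skipped: %s", cand.chrom, lo, hi, exc)
            continue
        hp = hairpin_mod.select_stemloop(
            seq,
            folds,
            min_len=config.min_hairpin_len,
            max_len=config.max_hairpin_len,
            min_paired_frac=config.min_paired_frac,
        )
        if hp is None:
            continue
        _rebase(hp, lo, hi, cand.chrom, cand.strand)
        try:
            hairpin_mod.thermo_stats(hp)
        except ValueError as exc:
            logger.info("hairpin at %s:%d rejected: %s", hp.chrom, hp.start, exc)
            continue
        if config.mfei_filter and hp.mfei >= config.mfei_threshold:
            continue
        locus = attach_reads(hp, retained)
        if not locus.reads:
            continue
        quality, duplex = compute_quality_score(locus, config.scoring)
        predictions.append(
            Prediction(
                name=locus_name(hp.chrom, hp.start, hp.end, hp.strand),
                hairpin=hp,
                quality=quality,
                duplex=duplex,
                locus=locus,
            )
        )

    predictions = _dedupe(predictions)
    predictions = [p for p in predictions if p.quality.score >= config.min_score]

    for p in predictions:
        if p.duplex is None:
            continue
        dup = annotate.duplication_check(
            p.duplex.guide_seq, genome, predictions, own_name=p.name
        )
        p.duplication = dup
        p.weight = annotate.compute_weight(p.duplex.guide_count, dup.n_genomic_occurrences)
        if mature_db:
            g0 = p.duplex.guide_local_start
            p.conservation = annotate.align_to_known_matures(
                p.hairpin.sequence,
                mature_db,
                guide_interval=(g0, g0 + len(p.duplex.guide_seq)),
            )

    logger.info("pipeline: %d predictions", len(predictions))
    return PipelineResult(
        predictions=predictions,
        filter_report=filt_report,
        known_loci=known_reports,
    )
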