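"""Conservation and duplication annotation of predictions.

Conservation: each known mature miRNA is aligned against the candidate
precursor with a banded edit-distance DP allowing at most 3 edits
(mismatches + indels) and no two consecutive indel columns — the operative
definition of a cross-species match for ~21-nt sequences.

Duplication: the guide sequence is scanned exactly (both strands) over the
whole genome; multi-copy guides are flagged, and the guide's read count is
down-weighted by its number of genomic occurrences.
"""

from __future__ import annotations

from .model import (
    ConservationHit,
    DuplicationInfo,
    GenomeIndex,
    Prediction,
    revcomp_dna,
    to_dna,
)


def align_to_known_matures(
    candidate_seq: str,
    db: list[tuple[str, str]],
    max_edits: int = 3,
    guide_interval: tuple[int, int] | None = None,
) -> list[ConservationHit]:
    """Align each known mature sequence onto the precursor.

    Returns one hit per database sequence that aligns with at most
    ``max_edits`` total edits and no two adjacent indels, at its best
    (fewest-edit, then leftmost) location.  ``guide_interval`` marks hits
    overlapping the guide locus.
    """
    cand = candidate_seq.upper().replace("T", "U")
    hits: list[ConservationHit] = []
    for db_id, db_seq in db:
        res = _best_semiglobal(db_seq.upper().replace("T", "U"), cand, max_edits)
        if res is None:
            continue
        edits, start, end = res
        overlaps = bool(
            guide_interval
            and start < guide_interval[1]
            and guide_interval[0] < end
        )
        hits.append(
            ConservationHit(
                db_id=db_id,
                db_seq=db_seq,
                local_start=start,
                local_end=end,
                n_edits=edits,
                overlaps_guide=overlaps,
            )
        )
    hits.sort(key=lambda h: (h.local_start, h.n_edits, h.db_id))
    return hits


def _best_semiglobal(
    query: str, target: str, max_edits: int
) -> tuple[int, int, int] | None:
    """Minimum-edit alignment of all of ``query`` inside ``target``.

    DP over (query index, target index, last-column-was-indel) with free
    start/end in the target; indel-after-indel transitions are forbidden.
    Returns (edits, target_start, target_end) or None above ``max_edits``.
    """
    m, n = len(query), len(target)
    INF = max_edits + 1
    # dp[j][k] = (edits, start) best alignment of query[:i] ending at target[:j]
    prev = [[(0, j), (INF, -1)] for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [[(INF, -1), (INF, -1)] for _ in range(n + 1)]
        for j in range(n + 1):
            # insertion: query[i-1] aligned to a gap (target not consumed)
            e, s = prev[j][0]
            if e + 1 < INF and e + 1 < cur[j][1][0]:
                cur[j][1] = (e + 1, s)
            if j >= 1:
                sub = 0 if query[i - 1] == target[j - 1] else 1
                for k in (0, 1):
                    e, s = prev[j - 1][k]
                    if e + sub < cur[j][0][0]:
                        cur[j][0] = (e + sub, s)
                # deletion: target[j-1] aligned to a gap (query not consumed)
                e, s = cur[j - 1][0]
                if e + 1 < INF and e + 1 < cur[j][1][0]:
                    cur[j][1] = (e + 1, s)
        prev = cur
    best: tuple[int, int, int] | None = None
    for j in range(n + 1):
        for k in (0, 1):
            e, s = prev[j][k]
            if e <= max_edits and (
                best is None or e < best[0] or (e == best[0] and s < best[1])
            ):
                best = (e, s, j)
    return best


def find_genomic_occurrences(
    seq: str, genome: GenomeIndex
) -> list[tuple[str, int, int, str]]:
    """All exact occurrences of ``seq`` (either strand) on the genome."""
    dna = to_dna(seq)
    rc = revcomp_dna(dna)
    out: list[tuple[str, int, int, str]] = []
    for chrom, chrom_seq in genome.sequences.items():
        for pattern, strand in ((dna, "+"), (rc, "-")):
            pos = chrom_seq.find(pattern)
            while pos != -1:
                out.append((chrom, pos, pos + len(pattern), strand))
                pos = chrom_seq.find(pattern, pos + 1)
    out.sort()
    return out


def duplication_check(
    guide_seq: str,
    genome: GenomeIndex,
    predictions: list[Prediction],
    own_name: str | None = None,
) -> DuplicationInfo:
    """Locate the guide elsewhere in the genome and cross-check predictions.

    ``overlaps_other_prediction`` is set when any occurrence falls inside
    the precursor interval of a prediction other than ``own_name``.
    """
    occurrences = find_genomic_occurrences(guide_seq, genome)
    flagged = False
    for chrom, start, end, _ in occurrences:
        for p in predictions:
            if p.name == own_name:
                continue
            h = p.hairpin
            if h.chrom == chrom and start < h.end and h.start < end:
                flagged = True
    return DuplicationInfo(
        n_genomic_occurrences=max(1, len(occurrences)),
        other_loci=occurrences,
        overlaps_other_prediction=flagged,
    )


def compute_weight(guide_count: int, n_genomic_occurrences: int) -> float:
    """Guide read count normalized by its genomic copy number."""
    if n_genomic_occurrences < 1:
        raise ValueError("n_genomic_occurrences must be >= 1")
    return guide_count / n_genomic_occurrences
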