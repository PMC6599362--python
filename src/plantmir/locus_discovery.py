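"""Peak calling on read alignments and duplex-partner search.

A miRNA locus shows up in sRNA-seq as a read-enriched window (the guide
and/or passenger stack).  Enriched windows are found by gap-merging read
intervals into clusters and separating signal from background clusters with
a closed-form 1-D 2-means on log10 read counts.  Each peak is then required
to base-pair (C-G, A-U, G-U) with a window in its vicinity — the necessary
condition for being one arm of a stem-loop — before any folding is done.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import CandidateLocus, GenomeIndex, Peak, ReadAlignment

logger = logging.getLogger(__name__)

MIN_READ_LEN = 18

_NT_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# legal RNA pairs: C-G, A-U and the G-U wobble (both orientations);
# code 4 (ambiguous base) never pairs
_PAIR_OK = np.zeros((5, 5), dtype=bool)
for _x, _y in ((0, 3), (1, 2), (2, 3)):
    _PAIR_OK[_x, _y] = _PAIR_OK[_y, _x] = True


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_NT_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} (expected A/C/G/U)")


# ---------------------------------------------------------------------------
# peak calling


def _two_means_split(values: np.ndarray) -> np.ndarray:
    """Boolean mask of the high group under optimal 1-D 2-means.

    On sorted 1-D data the 2-means optimum is a split point, found exactly by
    minimizing within-group sums of squares over all splits; no seeds, no
    iteration.  If all values are equal there is nothing to separate and
    every point is 'high'.
    """
    n = len(values)
    if n <= 1 or np.all(values == values[0]):
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    v = values[order]
    best_cost, best_t = np.inf, 1
    for t in range(1, n):
        lo, hi = v[:t], v[t:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_t = cost, t
    mask = np.zeros(n, dtype=bool)
    mask[order[best_t:]] = True
    return mask


def call_peaks(
    reads: list[ReadAlignment],
    cluster_gap: int = 30,
    peak_floor: int = 10,
) -> list[Peak]:
    """Find read-enriched peaks per (chrom, strand).

    Reads separated by at most ``cluster_gap`` nt are merged into raw
    clusters.  Clusters in the high group of a 2-means split on
    log10(total count), plus any cluster with at least ``peak_floor`` read
    copies, become peaks.
    """
    groups: dict[tuple[str, str], list[ReadAlignment]] = {}
    for r in reads:
        groups.setdefault((r.chrom, r.strand), []).append(r)

    peaks: list[Peak] = []
    for (chrom, strand), grp in sorted(groups.items()):
        grp.sort(key=lambda r: (r.start, r.end))
        clusters: list[list[ReadAlignment]] = []
        cur: list[ReadAlignment] = []
        cur_end = -(10**12)
        for r in grp:
            if r.start - cur_end > cluster_gap and cur:
                clusters.append(cur)
                cur = []
            cur.append(r)
            cur_end = max(cur_end, r.end)
        if cur:
            clusters.append(cur)

        totals = np.array([sum(r.count for r in c) for c in clusters], dtype=float)
        high = _two_means_split(np.log10(totals))
        for cluster, total, is_high in zip(clusters, totals, high):
            if not is_high and total < peak_floor:
                continue
            start = min(r.start for r in cluster)
            end = max(r.end for r in cluster)
            peaks.append(
                Peak(
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    total_count=int(total),
                    max_depth=_max_depth(cluster),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.start))
    logger.info("call_peaks: %d reads -> %d peaks", len(reads), len(peaks))
    return peaks


def _max_depth(cluster: list[ReadAlignment]) -> int:
    events: dict[int, int] = {}
    for r in cluster:
        events[r.start] = events.get(r.start, 0) + r.count
        events[r.end] = events.get(r.end, 0) - r.count
    depth = best = 0
    for pos in sorted(events):
        depth += events[pos]
        best = max(best, depth)
    return best


# ---------------------------------------------------------------------------
# pairing


def _pairing_dp_batch(query: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Best pairing count of ``query`` against each window, vectorized.

    Each window is aligned reversed (antiparallel) against the query.  An
    alignment may open at most 2 bulges of at most 2 nt each (on either
    side); leading/trailing offsets are free.  Returns, per window, the
    maximum number of aligned positions forming a legal pair.
    """
    la = len(query)
    rw = windows[:, ::-1]  # antiparallel
    nwin, lw = rw.shape
    # dp[k][i][j] over windows: best pairs using query[:i], revwindow[:j],
    # k bulge events; free ends via the zero floor on every cell.
    dp = np.zeros((3, la + 1, lw + 1, nwin), dtype=np.int16)
    pair = _PAIR_OK[query[:, None, None], rw.T[None, :, :]]  # (la, lw, nwin)
    for i in range(la + 1):
        for j in range(lw + 1):
            if i == 0 or j == 0:
                continue
            diag = pair[i - 1, j - 1]
            for k in range(3):
                best = dp[k, i - 1, j - 1] + diag
                if k > 0:
                    for d in (1, 2):
                        if i - d >= 0:
                            np.maximum(best, dp[k - 1, i - d, j], out=best)
                        if j - d >= 0:
                            np.maximum(best, dp[k - 1, i, j - d], out=best)
                dp[k, i, j] = best
    return dp.max(axis=(0, 1, 2))


def pairing_matrix(a: str, b: str) -> int:
    """Maximum ungapped-window pairing count of ``a`` against reverse(``b``).

    Counts C-G, A-U and G-U pairs over the best alignment, allowing at most
    2 bulges of <=2 nt each.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    qa = _encode(a)
    wb = _encode(b)[None, :]
    return int(_pairing_dp_batch(qa, wb)[0])


# ---------------------------------------------------------------------------
# partner search


def find_duplex_partner(
    peak: Peak,
    genome: GenomeIndex,
    reads: list[ReadAlignment] | None = None,
    max_distance: int = 350,
    min_paired: int = 14,
    query_len: int = 25,
) -> CandidateLocus | None:
    """Look for a window near the peak that the peak can base-pair with.

    Candidate windows slide within ``[peak.start - max_distance,
    peak.end + max_distance)``, clipped to the contig.  Short peaks are used
    whole as the pairing query; a peak longer than ``query_len`` (e.g. a
    merged guide+passenger cloud) is represented by its highest-depth
    sub-window of ``query_len`` nt, so the opposite arm inside the same peak
    remains searchable.  Windows overlapping the query are excluded.
    Returns the locus spanning peak and best-pairing window when the best
    score reaches ``min_paired``.
    """
    clen = genome.lengths[peak.chrom]
    if peak.end - peak.start <= query_len:
        q_start, q_end = peak.start, peak.end
    else:
        q_start, q_end = _summit_window(peak, reads or [], query_len)
    qlen = q_end - q_start
    region_start = max(0, peak.start - max_distance)
    region_end = min(clen, peak.end + max_distance)
    if region_end - region_start < 2 * qlen:
        return None

    region_dna = genome.fetch(peak.chrom, region_start, region_end)
    region = _encode_region(region_dna, peak.strand)
    # local coordinates along the forward genome axis within the region
    q_lo, q_hi = q_start - region_start, q_end - region_start
    starts = np.array(
        [
            s
            for s in range(0, len(region) - qlen + 1)
            if s + qlen <= q_lo or s >= q_hi
        ],
        dtype=int,
    )
    if len(starts) == 0:
        return None
    windows_fwd = np.stack([region[s : s + qlen] for s in starts])
    if peak.strand == "+":
        query = region[q_lo:q_hi]
        windows = windows_fwd
    else:
        # expressed strand: reverse complement both query and windows
        query = _revcomp_codes(region[q_lo:q_hi])
        windows = np.stack([_revcomp_codes(w) for w in windows_fwd])
    scores = _pairing_dp_batch(query, windows)
    best_i = int(np.argmax(scores))
    best = int(scores[best_i])
    if best < min_paired:
        return None
    w_start = region_start + int(starts[best_i])
    w_end = w_start + qlen
    return CandidateLocus(
        chrom=peak.chrom,
        strand=peak.strand,
        start=min(peak.start, w_start),
        end=max(peak.end, w_end),
        peak=peak,
        partner_offset=w_start - peak.start,
        pairing_score=best,
    )


def _summit_window(
    peak: Peak, reads: list[ReadAlignment], query_len: int
) -> tuple[int, int]:
    """Highest-depth window of ``query_len`` nt inside the peak (leftmost tie)."""
    span = peak.end - peak.start
    depth = np.zeros(span + 1, dtype=int)
    for r in reads:
        if r.chrom != peak.chrom or r.strand != peak.strand:
            continue
        lo = max(r.start, peak.start) - peak.start
        hi = min(r.end, peak.end) - peak.start
        if hi > lo:
            depth[lo] += r.count
            depth[hi] -= r.count
    depth = np.cumsum(depth[:-1])
    window_sums = np.convolve(depth, np.ones(query_len, dtype=int), mode="valid")
    best = int(np.argmax(window_sums))
    return peak.start + best, peak.start + best + query_len


def _encode_region(dna: str, strand: str) -> np.ndarray:
    rna = dna.upper().replace("T", "U")
    # tolerate Ns in genomic background: code 4 never pairs
    codes = np.array([_NT_CODE.get(c, 4) for c in rna], dtype=np.int8)
    return codes


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    return comp[codes][::-1]
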