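"""The six quality criteria, guide/passenger selection, and the star score.

Each candidate precursor is scored 0-6, one star per satisfied criterion:

1. hairpin stability: MFEI < -0.8;
2. read support: >=10 read copies on each arm, or >=100 in total;
3. existence of the miRNA: the most common read holds >=33% of copies and
   becomes the guide;
4. processing precision: >=75% of copies start within [-3,+3] of the guide
   start or [-5,+5] of the expected passenger start;
5. expressed passenger: >=1 copy starts within [-5,+5] of the expected
   passenger start;
6. duplex stability: extensive guide:passenger base-pairing with the 2-nt
   3' overhangs characteristic of Dicer-type processing.

Criteria 4-6 are only defined once a guide exists, so loci without a clear
miRNA score at most 2, and loci without passenger evidence at most 5.
Criterion 6 is a pluggable predicate; the built-in rule checks the duplex
geometry directly on the structure (>=75% of guide bases paired, no
internal loop over 3 nt inside the duplex, observed passenger start within
1 nt of the 2-nt-overhang position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

from .model import DuplexCall, Hairpin, QualityScore, ReadCloudLocus


@dataclass
class ScoringConfig:
    mfei_star_threshold: float = -0.8
    min_arm_reads: int = 10
    min_total_reads: int = 100
    guide_min_freq: Fraction = Fraction(1, 3)
    precision_frac: Fraction = Fraction(3, 4)
    guide_window: int = 3
    star_window: int = 5
    duplex_min_paired_frac: float = 0.75
    duplex_max_loop: int = 3
    duplex_overhang_tol: int = 1
    # pluggable replacement for the duplex-stability classifier
    duplex_rule: Callable[[Hairpin, "GuideCall"], bool] | None = field(
        default=None, repr=False
    )


@dataclass(frozen=True)
class GuideCall:
    """The selected guide read with its precursor-local position."""

    sequence: str
    local_start: int
    count: int
    frequency: float
    arm: str | None  # "5p", "3p" or None for a loop-straddling guide


def read_arm(hairpin: Hairpin, local_start: int, length: int) -> str | None:
    """Arm holding the majority of a read's span; None for loop-only reads."""
    lo, hi = local_start, local_start + length
    ov5 = max(0, min(hi, hairpin.arm5[1]) - max(lo, hairpin.arm5[0]))
    ov3 = max(0, min(hi, hairpin.arm3[1]) - max(lo, hairpin.arm3[0]))
    span = hi - lo
    if ov5 * 2 > span:
        return "5p"
    if ov3 * 2 > span:
        return "3p"
    if ov5 == ov3 == 0 or (ov5 * 2 == span or ov3 * 2 == span):
        # exact 50/50 split: side with more overlap, 5p on tie
        if ov5 >= ov3 and ov5 > 0:
            return "5p"
        if ov3 > ov5:
            return "3p"
    return None


def criterion1_stability(hairpin: Hairpin, threshold: float = -0.8) -> bool:
    """MFEI strictly below the stability threshold."""
    return hairpin.mfei < threshold


def _arm_counts(locus: ReadCloudLocus) -> tuple[int, int, int]:
    c5 = c3 = 0
    total = 0
    for r, s in zip(locus.reads, locus.local_starts):
        total += r.count
        arm = read_arm(locus.hairpin, s, len(r.sequence))
        if arm == "5p":
            c5 += r.count
        elif arm == "3p":
            c3 += r.count
    return c5, c3, total


def criterion2_reads(
    locus: ReadCloudLocus, min_arm: int = 10, min_total: int = 100
) -> bool:
    """Either both arms carry >= min_arm copies, or the locus >= min_total."""
    c5, c3, total = _arm_counts(locus)
    return (c5 >= min_arm and c3 >= min_arm) or total >= min_total


def select_guide(
    locus: ReadCloudLocus, min_freq: Fraction | float = Fraction(1, 3)
) -> GuideCall | None:
    """The most common read, if it holds at least ``min_freq`` of all copies.

    Frequencies are over copy counts.  Ties on count break by 5'-most start,
    then lexicographically smallest sequence.
    """
    if not locus.reads:
        return None
    total = locus.total_count
    best = max(
        zip(locus.reads, locus.local_starts),
        key=lambda rs: (rs[0].count, -rs[1], _neg_lex(rs[0].sequence)),
    )
    read, start = best
    if Fraction(read.count, total) < Fraction(min_freq):
        return None
    return GuideCall(
        sequence=read.sequence,
        local_start=start,
        count=read.count,
        frequency=read.count / total,
        arm=read_arm(locus.hairpin, start, len(read.sequence)),
    )


class _NegLex(str):
    def __lt__(self, other):  # max() picks the lexicographically smallest
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _neg_lex(s: str) -> "_NegLex":
    return _NegLex(s)


def expected_star_position(
    hairpin: Hairpin, guide_local_start: int, guide_len: int
) -> int:
    """Passenger 5' start implied by 2-nt 3' overhangs on both strands.

    The guide base two positions in from its 3' end pairs with the
    passenger's 5' end; the mapping goes through the structure's pair
    table, extrapolating linearly from the nearest paired guide base when
    the target base itself is unpaired.
    """
    from .hairpin import pair_table

    g0, g1 = guide_local_start, guide_local_start + guide_len
    lo, hi = hairpin.loop
    if g0 < hi and lo < g1:
        raise ValueError("guide overlaps terminal loop")
    pt = pair_table(hairpin.structure)
    target = g1 - 3
    for offset in range(guide_len):
        for i in (target - offset, target + offset):
            if g0 <= i < g1 and 0 <= i < len(pt) and pt[i] != -1:
                return pt[i] - (target - i)
    raise ValueError("guide has no paired base to map through")


def _star_window_copies(
    locus: ReadCloudLocus, star_start: int, window: int
) -> tuple[int, tuple[str, int, int] | None]:
    """(copies starting in star_start +/- window, best-supported such read)."""
    n = 0
    best: tuple[str, int, int] | None = None
    for r, s in zip(locus.reads, locus.local_starts):
        if abs(s - star_start) <= window:
            n += r.count
            if best is None or r.count > best[2]:
                best = (r.sequence, s, r.count)
    return n, best


def criterion4_precision(
    locus: ReadCloudLocus,
    guide: GuideCall,
    star_start: int | None,
    frac: Fraction = Fraction(3, 4),
    guide_window: int = 3,
    star_window: int = 5,
) -> bool:
    """>=75% of copies start near the guide start or the passenger start."""
    total = locus.total_count
    in_windows = 0
    for r, s in zip(locus.reads, locus.local_starts):
        near_guide = abs(s - guide.local_start) <= guide_window
        near_star = star_start is not None and abs(s - star_start) <= star_window
        if near_guide or near_star:
            in_windows += r.count
    return Fraction(in_windows, total) >= Fraction(frac)


def criterion5_star_expressed(
    locus: ReadCloudLocus, star_start: int | None, window: int = 5
) -> bool:
    """At least one read copy starts within the passenger window."""
    if star_start is None:
        return False
    n, _ = _star_window_copies(locus, star_start, window)
    return n >= 1


def criterion6_duplex_stability(
    hairpin: Hairpin,
    guide: GuideCall,
    observed_star_start: int | None = None,
    min_paired_frac: float = 0.75,
    max_loop: int = 3,
    overhang_tol: int = 1,
) -> bool:
    """Rule-based duplex-stability check on the structure.

    True when (i) >=``min_paired_frac`` of guide bases pair outside the
    guide interval, (ii) no internal loop inside the duplex exceeds
    ``max_loop`` nt on either strand, and (iii) when a passenger read is
    observed, its start is within ``overhang_tol`` nt of the 2-nt-overhang
    position.
    """
    from .hairpin import pair_table

    pt = pair_table(hairpin.structure)
    g0, g1 = guide.local_start, guide.local_start + len(guide.sequence)
    if g0 < 0 or g1 > len(pt):
        return False
    paired_pos = [i for i in range(g0, g1) if pt[i] != -1 and not g0 <= pt[i] < g1]
    if len(paired_pos) / (g1 - g0) < min_paired_frac:
        return False
    for a, b in zip(paired_pos, paired_pos[1:]):
        if b - a - 1 > max_loop:  # loop on the guide side
            return False
        if abs(pt[a] - pt[b]) - 1 > max_loop:  # loop on the passenger side
            return False
    if observed_star_start is not None:
        try:
            expected = expected_star_position(hairpin, g0, g1 - g0)
        except ValueError:
            return False
        if abs(observed_star_start - expected) > overhang_tol:
            return False
    return True


def compute_quality_score(
    locus: ReadCloudLocus,
    config: ScoringConfig | None = None,
    criteria_overrides: dict[str, Callable] | None = None,
) -> tuple[QualityScore, DuplexCall | None]:
    """Evaluate all six criteria on a locus.

    ``criteria_overrides`` may replace any criterion by name ("c1".."c6")
    with a callable taking the same locus; used for decomposition testing
    and for plugging alternative classifiers.
    """
    cfg = config or ScoringConfig()
    ov = criteria_overrides or {}
    q = QualityScore()
    hp = locus.hairpin

    q.c1 = bool(ov["c1"](locus)) if "c1" in ov else criterion1_stability(
        hp, cfg.mfei_star_threshold
    )
    q.c2 = bool(ov["c2"](locus)) if "c2" in ov else criterion2_reads(
        locus, cfg.min_arm_reads, cfg.min_total_reads
    )

    guide = select_guide(locus, cfg.guide_min_freq) if locus.reads else None
    q.guide_defined = guide is not None
    q.c3 = bool(ov["c3"](locus)) if "c3" in ov else q.guide_defined
    if guide is None:
        # without a miRNA the processing criteria are undefined
        return q, None

    try:
        star_start = expected_star_position(hp, guide.local_start, len(guide.sequence))
    except ValueError:
        star_start = None

    n_star, star_read = (
        _star_window_copies(locus, star_start, cfg.star_window)
        if star_start is not None
        else (0, None)
    )

    q.c4 = bool(ov["c4"](locus)) if "c4" in ov else criterion4_precision(
        locus, guide, star_start, cfg.precision_frac, cfg.guide_window, cfg.star_window
    )
    q.c5 = bool(ov["c5"](locus)) if "c5" in ov else criterion5_star_expressed(
        locus, star_start, cfg.star_window
    )
    if "c6" in ov:
        q.c6 = bool(ov["c6"](locus))
    elif cfg.duplex_rule is not None:
        q.c6 = bool(cfg.duplex_rule(hp, guide))
    else:
        q.c6 = criterion6_duplex_stability(
            hp,
            guide,
            observed_star_start=star_read[1] if star_read else None,
            min_paired_frac=cfg.duplex_min_paired_frac,
            max_loop=cfg.duplex_max_loop,
            overhang_tol=cfg.duplex_overhang_tol,
        )

    duplex = DuplexCall(
        guide_seq=guide.sequence,
        guide_local_start=guide.local_start,
        guide_arm=guide.arm or "5p",
        guide_count=guide.count,
        star_seq=star_read[0] if star_read else None,
        star_local_start=star_read[1] if star_read else None,
        star_count=star_read[2] if star_read else 0,
        overhang_3p=(
            2 + (star_read[1] - star_start)
            if star_read is not None and star_start is not None
            else 2
        ),
        paired_in_duplex=_paired_in_guide(hp, guide),
    )
    return q, duplex


def _paired_in_guide(hp: Hairpin, guide: GuideCall) -> int:
    from .hairpin import pair_table

    pt = pair_table(hp.structure)
    g0, g1 = guide.local_start, guide.local_start + len(guide.sequence)
    return sum(1 for i in range(max(0, g0), min(len(pt), g1)) if pt[i] != -1)
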