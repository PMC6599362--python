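"""Synthetic genomes and read clouds with known ground truth.

Every generator is seeded and deterministic.  The read-cloud model emulates
what a genuine miRNA locus looks like in sRNA-seq: a dominant guide stack,
a smaller passenger stack offset by the 2-nt-overhang geometry, and sparse
uniform-position degradation reads with Poisson-distributed copy numbers.
Multi-mapping traps (tandem repeats) and maskable coding features can be
planted alongside to exercise the prefilters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    AnnotationFeature,
    GenomeIndex,
    Hairpin,
    ReadAlignment,
    ReadCloudLocus,
    to_dna,
)

_PAIRS = {"A": "U", "U": "A", "G": "C", "C": "G"}
_NON_PAIRING = {  # bases that form neither a Watson-Crick nor a wobble pair
    "A": ["C", "G", "A"],
    "C": ["A", "C", "U"],
    "G": ["G", "A"],
    "U": ["U", "C"],
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_hairpin(
    stem_len: int,
    loop_len: int,
    n_mismatches: int = 0,
    gc_frac: float = 0.5,
    seed=None,
) -> tuple[str, str]:
    """Random stem-loop sequence with its intended dot-bracket structure.

    The 5' arm is random with the requested GC fraction, the 3' arm its
    reverse complement; ``n_mismatches`` stem positions get a non-pairing
    partner base.  Mismatches avoid the outer/inner two stem positions so
    the planted helix stays foldable.
    """
    if stem_len < 18:
        raise ValueError(f"stem_len must be >= 18, got {stem_len}")
    if loop_len < 3:
        raise ValueError(f"loop_len must be >= 3, got {loop_len}")
    if n_mismatches > stem_len - 4:
        raise ValueError("too many mismatches for this stem length")
    rng = _rng(seed)

    def draw(n: int) -> list[str]:
        out = []
        for _ in range(n):
            if rng.random() < gc_frac:
                out.append("G" if rng.random() < 0.5 else "C")
            else:
                out.append("A" if rng.random() < 0.5 else "U")
        return out

    arm5 = draw(stem_len)
    loop = draw(loop_len)
    arm3 = [_PAIRS[c] for c in reversed(arm5)]
    struct5 = ["("] * stem_len
    struct3 = [")"] * stem_len
    if n_mismatches:
        sites = rng.choice(np.arange(2, stem_len - 2), size=n_mismatches, replace=False)
        for i in sites:
            partner = stem_len - 1 - int(i)
            choices = _NON_PAIRING[arm5[int(i)]]
            arm3[partner] = choices[rng.integers(len(choices))]
            struct5[int(i)] = "."
            struct3[partner] = "."
    sequence = "".join(arm5 + loop + arm3)
    structure = "".join(struct5) + "." * loop_len + "".join(struct3)
    return sequence, structure


@dataclass
class PlantedLocus:
    """A precursor planted in a synthetic genome, with its true read model."""

    precursor_seq: str
    structure: str
    guide_seq: str
    guide_offset: int
    star_seq: str
    star_offset: int
    guide_copies: int
    star_copies: int
    background_copies: int
    chrom: str = "chr1"
    position: int = 0

    @property
    def end(self) -> int:
        return self.position + len(self.precursor_seq)


def make_planted_locus(
    seed=None,
    chrom: str = "chr1",
    position: int = 0,
    stem_len: int = 35,
    loop_len: int = 12,
    guide_len: int = 21,
    guide_offset: int = 2,
    n_mismatches: int = 0,
    gc_frac: float = 0.55,
    guide_copies: int = 71,
    star_copies: int = 27,
    background_copies: int = 16,
) -> PlantedLocus:
    """Plant a hairpin whose guide/star placement obeys duplex geometry.

    The passenger offset follows the 2-nt 3' overhang rule on the planted
    (perfect-geometry) structure: with precursor length ``T+1``, a guide at
    ``g`` of length ``L`` puts the passenger 5' start at ``T - g - L + 3``.
    """
    seq, struct = make_hairpin(stem_len, loop_len, n_mismatches, gc_frac, seed)
    total = len(seq)
    g, L = guide_offset, guide_len
    if g + L > stem_len:
        raise ValueError("guide does not fit on the 5' arm")
    star = (total - 1) - g - L + 3
    if star + L > total:
        raise ValueError("passenger does not fit in the precursor")
    return PlantedLocus(
        precursor_seq=seq,
        structure=struct,
        guide_seq=seq[g : g + L],
        guide_offset=g,
        star_seq=seq[star : star + L],
        star_offset=star,
        guide_copies=guide_copies,
        star_copies=star_copies,
        background_copies=background_copies,
        chrom=chrom,
        position=position,
    )


def make_read_cloud(
    planted: PlantedLocus,
    seed=None,
    jitter: int = 3,
    strand: str = "+",
) -> list[ReadAlignment]:
    """Reads for a planted locus, in genomic coordinates.

    Guide and passenger copies sit exactly at their planted offsets;
    background reads get uniform positions with start jitter of up to
    ``jitter`` nt and 1 + Poisson(1) copies each, the last one truncated so
    copy totals match the request exactly.
    """
    rng = _rng(seed)
    n = len(planted.precursor_seq)
    records: dict[tuple[int, int], int] = {}

    def add(local_start: int, length: int, copies: int) -> None:
        local_start = max(0, min(n - length, local_start))
        key = (local_start, length)
        records[key] = records.get(key, 0) + copies

    if planted.guide_copies:
        add(planted.guide_offset, len(planted.guide_seq), planted.guide_copies)
    if planted.star_copies:
        add(planted.star_offset, len(planted.star_seq), planted.star_copies)
    remaining = planted.background_copies
    while remaining > 0:
        length = int(rng.integers(19, 25))
        pos = int(rng.integers(0, max(1, n - length)))
        if jitter:
            pos += int(rng.integers(-jitter, jitter + 1))
        copies = min(remaining, 1 + int(rng.poisson(1.0)))
        add(pos, length, copies)
        remaining -= copies

    reads = []
    for (local_start, length), copies in sorted(records.items()):
        seq = planted.precursor_seq[local_start : local_start + length]
        if strand == "+":
            start = planted.position + local_start
        else:
            start = planted.end - (local_start + length)
        reads.append(
            ReadAlignment(
                chrom=planted.chrom,
                start=start,
                end=start + length,
                strand=strand,
                sequence=seq,
                count=copies,
            )
        )
    return reads


def make_genome(
    loci: list[PlantedLocus],
    length: int = 10_000,
    seed=None,
    repeat_copies: int = 0,
    repeat_len: int = 80,
    cds_features: int = 0,
) -> tuple[GenomeIndex, list[AnnotationFeature]]:
    """Random genome with planted precursors; returns (genome, truth).

    Truth features: one ``miRNA_primary_transcript`` per planted locus, one
    ``repeat_region`` per planted tandem-repeat copy (multi-mapping traps)
    and optional ``CDS`` mask features on otherwise empty ground.
    """
    rng = _rng(seed)
    intervals = sorted((l.position, l.end, l) for l in loci)
    for (s1, e1, _), (s2, e2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"planted loci overlap: [{s1},{e1}) and [{s2},{e2})")
    chroms = {l.chrom for l in loci} or {"chr1"}
    seqs: dict[str, list[str]] = {
        c: list(rng.choice(list("ACGT"), size=length)) for c in sorted(chroms)
    }
    truth: list[AnnotationFeature] = []
    for l in loci:
        if l.end > length:
            raise ValueError("planted locus extends past the contig")
        dna = to_dna(l.precursor_seq)
        seqs[l.chrom][l.position : l.end] = list(dna)
        truth.append(
            AnnotationFeature(l.chrom, l.position, l.end, "+", "miRNA_primary_transcript")
        )

    occupied = [(l.chrom, l.position, l.end) for l in loci]

    def free_slot(chrom: str, size: int) -> int:
        for _ in range(1000):
            pos = int(rng.integers(0, length - size))
            if all(
                not (c == chrom and pos < e + 50 and s - 50 < pos + size)
                for c, s, e in occupied
            ):
                occupied.append((chrom, pos, pos + size))
                return pos
        raise RuntimeError("no free slot in synthetic genome")

    chrom0 = sorted(chroms)[0]
    if repeat_copies:
        unit = "".join(rng.choice(list("ACGT"), size=repeat_len))
        for _ in range(repeat_copies):
            pos = free_slot(chrom0, repeat_len)
            seqs[chrom0][pos : pos + repeat_len] = list(unit)
            truth.append(
                AnnotationFeature(chrom0, pos, pos + repeat_len, "+", "repeat_region")
            )
    for _ in range(cds_features):
        size = int(rng.integers(200, 400))
        pos = free_slot(chrom0, size)
        truth.append(AnnotationFeature(chrom0, pos, pos + size, "+", "CDS"))

    genome = GenomeIndex({c: "".join(s) for c, s in seqs.items()})
    return genome, truth


def background_reads(
    genome: GenomeIndex, n_unique: int, seed=None
) -> list[ReadAlignment]:
    """Scattered degradation-like reads over the whole genome."""
    rng = _rng(seed)
    reads = []
    for _ in range(n_unique):
        chrom = sorted(genome.lengths)[int(rng.integers(len(genome.lengths)))]
        length = int(rng.integers(19, 25))
        pos = int(rng.integers(0, genome.lengths[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome.fetch_rna(chrom, pos, pos + length, strand)
        reads.append(
            ReadAlignment(
                chrom, pos, pos + length, strand, seq, count=1 + int(rng.poisson(1.0))
            )
        )
    reads.sort(key=lambda r: (r.chrom, r.start, r.strand))
    return reads


# ---------------------------------------------------------------------------
# locus-level cloud construction (for direct scoring of synthetic loci)


def fold_planted(planted: PlantedLocus) -> Hairpin:
    """Fold the planted precursor and return a thermo-complete Hairpin."""
    import RNA

    from .hairpin import _set_arms, thermo_stats

    structure, _ = RNA.fold(planted.precursor_seq)
    hp = Hairpin(
        chrom=planted.chrom,
        strand="+",
        start=planted.position,
        end=planted.end,
        sequence=planted.precursor_seq,
        structure=structure,
    )
    _set_arms(hp)
    return thermo_stats(hp)


def cloud_from_offsets(
    hp: Hairpin, items: list[tuple[int, int, int]]
) -> ReadCloudLocus:
    """Build a read cloud on ``hp`` from (local_start, length, count) items."""
    locus = ReadCloudLocus(hairpin=hp)
    n = len(hp.sequence)
    for local_start, length, count in items:
        local_start = max(0, min(n - length, local_start))
        seq = hp.sequence[local_start : local_start + length]
        start = hp.start + local_start
        locus.reads.append(
            ReadAlignment(hp.chrom, start, start + length, hp.strand, seq, count)
        )
        locus.local_starts.append(local_start)
    return locus


# ---------------------------------------------------------------------------
# randomized locus sweeps


def hairpin_pool(n: int, seed=None) -> list[Hairpin]:
    """Folded, thermo-complete hairpins with varied stem/loop/GC geometry.

    Read-cloud randomization dominates sweep variability, so sweeps draw
    hairpins from a reusable pool rather than folding one per locus.
    """
    rng = _rng(seed)
    pool = []
    for i in range(n):
        planted = make_planted_locus(
            seed=rng.integers(2**31),
            chrom=f"pool{i}",
            stem_len=int(rng.integers(26, 42)),
            loop_len=int(rng.integers(8, 16)),
            n_mismatches=int(rng.integers(0, 3)),
            gc_frac=float(rng.uniform(0.45, 0.65)),
        )
        pool.append(fold_planted(planted))
    return pool


def sweep_no_guide_loci(
    n: int, seed=None, pool: list[Hairpin] | None = None
) -> list[ReadCloudLocus]:
    """Random loci in which no unique read reaches 1/3 of the copies.

    Copies are spread over >=5 distinct read positions in near-equal
    shares, so the most frequent read stays strictly below the
    guide-frequency threshold and no miRNA can be defined.
    """
    rng = _rng(seed)
    pool = pool or hairpin_pool(max(8, n // 25), rng.integers(2**31))
    loci = []
    for _ in range(n):
        hp = pool[int(rng.integers(len(pool)))]
        span = len(hp.sequence)
        total = int(rng.integers(60, 300))
        k = int(rng.integers(5, 12))
        base, rem = divmod(total, k)
        counts = [base + 1] * rem + [base] * (k - rem)
        starts = rng.choice(np.arange(0, span - 24), size=k, replace=False)
        items = [
            (int(s), int(rng.integers(19, 25)), c) for s, c in zip(starts, counts)
        ]
        locus = cloud_from_offsets(hp, items)
        assert max(r.count for r in locus.reads) * 3 < locus.total_count
        loci.append(locus)
    return loci


def sweep_no_star_loci(
    n: int, seed=None, pool: list[Hairpin] | None = None
) -> list[ReadCloudLocus]:
    """Random loci with a dominant guide read and an empty passenger window.

    The guide sits on the 5' arm with a clear majority of copies;
    background reads are confined to the 5' arm and any read starting
    within 5 nt of the expected passenger position is excluded, so the
    passenger-expression criterion can never be met.
    """
    from .scoring import expected_star_position

    rng = _rng(seed)
    pool = pool or hairpin_pool(max(8, n // 25), rng.integers(2**31))
    usable = []
    for hp in pool:
        try:
            star = expected_star_position(hp, 2, 21)
        except ValueError:
            continue
        usable.append((hp, star))
    loci = []
    while len(loci) < n:
        hp, star = usable[int(rng.integers(len(usable)))]
        guide_copies = int(rng.integers(40, 120))
        items = [(2, 21, guide_copies)]
        bg_budget = guide_copies // 2
        for _ in range(int(rng.integers(0, 6))):
            if bg_budget <= 0:
                break
            length = int(rng.integers(19, 25))
            start = int(rng.integers(0, max(1, hp.arm5[1] - length)))
            if abs(start - star) <= 5 or start == 2:
                continue
            copies = min(bg_budget, 1 + int(rng.poisson(1.0)))
            items.append((start, length, copies))
            bg_budget -= copies
        loci.append(cloud_from_offsets(hp, items))
    return loci


# ---------------------------------------------------------------------------
# the worked example distributed with the package

REFERENCE_GUIDE = "AGAUAUUAGUGCGGUUCAAUC"
REFERENCE_STAR = "UUGAGCCGUGCCAAUAUCACG"


def make_reference_locus(chrom: str = "chr1", position: int = 1000) -> PlantedLocus:
    """The canonical worked example: a conserved 21-nt miRNA locus.

    A 72-nt precursor is reconstructed around a real guide/passenger duplex
    (114 read copies in total: 71 guide, 27 passenger, 16 background over 5
    unique degradation reads).  The passenger sits at the 2-nt 3'
    overhang position implied by the duplex geometry.
    """
    g, L = 4, len(REFERENCE_GUIDE)
    stem, loop_len = 30, 12
    arm5 = list("GGCG" + REFERENCE_GUIDE + "GGCGC")  # 4 + 21 + 5 = 30
    loop = list("GAAUAUCUUGAC")
    arm3 = [_PAIRS[c] for c in reversed(arm5)]
    total = 2 * stem + loop_len
    star = (total - 1) - g - L + 3
    arm3_off = 2 * stem + loop_len - len(arm3)  # local start of the 3' arm
    for i, c in enumerate(REFERENCE_STAR):
        arm3[star - arm3_off + i] = c
    seq = "".join(arm5 + loop + arm3)
    struct5 = ["("] * stem
    struct3 = [")"] * stem
    for i in range(stem):
        if _PAIRS[seq[i]] != seq[total - 1 - i]:
            struct5[i] = "."
            struct3[stem - 1 - i] = "."
    structure = "".join(struct5) + "." * loop_len + "".join(struct3)
    return PlantedLocus(
        precursor_seq=seq,
        structure=structure,
        guide_seq=REFERENCE_GUIDE,
        guide_offset=g,
        star_seq=REFERENCE_STAR,
        star_offset=star,
        guide_copies=71,
        star_copies=27,
        background_copies=16,
        chrom=chrom,
        position=position,
    )


#: Deterministic background cloud of the worked example:
#: (local_start, length, copies), 5 unique reads totalling 16 copies.
REFERENCE_BACKGROUND = [(6, 20, 6), (52, 21, 4), (47, 20, 3), (30, 21, 2), (34, 22, 1)]


def reference_cloud(planted: PlantedLocus) -> list[tuple[int, int, int]]:
    """(local_start, length, count) items of the canonical 114-copy cloud."""
    items = [
        (planted.guide_offset, len(planted.guide_seq), planted.guide_copies),
        (planted.star_offset, len(planted.star_seq), planted.star_copies),
    ]
    items.extend(REFERENCE_BACKGROUND)
    return items


def write_fixture_dir(
    outdir: str | Path,
    n_loci: int = 1,
    genome_len: int = 10_000,
    seed: int = 0,
) -> dict[str, Path]:
    """Emit FASTA + BED + truth GFF for a synthetic dataset."""
    from . import formats_io

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = genome_len // max(1, n_loci)
    loci = [
        make_planted_locus(
            seed=rng.integers(2**31),
            position=i * spacing + 200,
            guide_copies=int(rng.integers(40, 120)),
            star_copies=int(rng.integers(5, 40)),
            background_copies=int(rng.integers(5, 25)),
        )
        for i in range(n_loci)
    ]
    genome, truth = make_genome(loci, length=genome_len, seed=rng.integers(2**31))
    reads: list[ReadAlignment] = []
    for locus in loci:
        reads.extend(make_read_cloud(locus, seed=rng.integers(2**31)))
    reads.extend(background_reads(genome, n_unique=20, seed=rng.integers(2**31)))
    reads.sort(key=lambda r: (r.chrom, r.start, r.strand))

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    bed = outdir / "reads.bed"
    bed.write_text(formats_io.write_bed(reads))
    gff = outdir / "truth.gff"
    lines = ["##gff-version 3"]
    for f in truth:
        lines.append(
            f"{f.chrom}\tplantmir_fixture\t{f.feature_type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t."
        )
    gff.write_text("\n".join(lines) + "\n")
    return {"fasta": fasta, "bed": bed, "gff": gff}
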