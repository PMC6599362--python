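"""Core domain types shared across the pipeline.

All genomic intervals are 0-based, half-open ``[start, end)`` on the forward
axis of the chromosome; conversion to/from 1-based file conventions happens
only inside :mod:`plantmir.formats_io`.  Read and precursor sequences are
stored 5'->3' in the orientation of the expressed strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field


_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped small-RNA read occurrence.

    ``sequence`` is the read as sequenced (5'->3' of the small RNA itself);
    ``strand`` records which genomic strand it aligned to.  ``count`` is the
    number of identical copies collapsed at this locus and ``n_genomic_hits``
    the number of distinct loci this read sequence maps to genome-wide.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    count: int = 1
    n_genomic_hits: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start},{self.end})")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"interval length {self.end - self.start} != sequence length "
                f"{len(self.sequence)} for read at {self.chrom}:{self.start}"
            )
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.n_genomic_hits < 1:
            raise ValueError(f"n_genomic_hits must be >= 1, got {self.n_genomic_hits}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class AnnotationFeature:
    """A genomic feature from an annotation file (mask or known precursor)."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start},{self.end})")


class GenomeIndex:
    """In-memory genome with bounds-checked subsequence extraction."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand DNA of ``chrom[start:end)``."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ValueError(
                f"request [{start},{end}) outside {chrom} of length {self.lengths[chrom]}"
            )
        return self.sequences[chrom][start:end]

    def fetch_rna(self, chrom: str, start: int, end: int, strand: str) -> str:
        """Expressed-strand RNA of the interval (reverse-complemented on '-')."""
        dna = self.fetch(chrom, start, end)
        if strand == "-":
            dna = revcomp_dna(dna)
        return to_rna(dna)


@dataclass
class FilterReport:
    """Read bookkeeping across the prefilter stage.

    Records partition exactly: input = known-miRNA + masked + multimap-removed
    + retained, applied in that priority order.
    """

    n_input: int = 0
    n_masked: int = 0
    n_multimap_removed: int = 0
    n_known_mirna: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = self.n_masked + self.n_multimap_removed + self.n_known_mirna + self.n_retained
        if total != self.n_input:
            raise AssertionError(
                f"filter partition broken: {self.n_input} input vs {total} accounted"
            )


@dataclass(frozen=True)
class Peak:
    """A read-enriched window on one genomic strand."""

    chrom: str
    strand: str
    start: int
    end: int
    total_count: int
    max_depth: int


@dataclass(frozen=True)
class CandidateLocus:
    """A peak plus the partner window it can base-pair with."""

    chrom: str
    strand: str
    start: int
    end: int
    peak: Peak
    partner_offset: int
    pairing_score: int


@dataclass
class Hairpin:
    """A candidate precursor stem-loop.

    ``sequence``/``structure`` are on the expressed strand; ``arm5``, ``loop``
    and ``arm3`` are half-open intervals in precursor-local coordinates that
    tile ``[0, len)``.  ``gc_percent`` is in percent units (50.0 not 0.5) so
    MFEI carries its conventional magnitude.
    """

    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    structure: str
    mfe: float = 0.0
    amfe: float = 0.0
    mfei: float = 0.0
    gc_percent: float = 0.0
    arm5: tuple[int, int] = (0, 0)
    loop: tuple[int, int] = (0, 0)
    arm3: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ShuffleResult:
    """Outcome of the dinucleotide-shuffle stability test."""

    n_shuffles: int
    n_as_stable: int
    empirical_p: float


@dataclass
class DuplexCall:
    """Guide/passenger call on a precursor."""

    guide_seq: str
    guide_local_start: int
    guide_arm: str  # "5p" or "3p"
    guide_count: int
    star_seq: str | None = None
    star_local_start: int | None = None
    star_count: int = 0
    overhang_3p: int = 2
    paired_in_duplex: int = 0


@dataclass
class QualityScore:
    """The six criterion booleans and their 0-6 star sum."""

    c1: bool = False
    c2: bool = False
    c3: bool = False
    c4: bool = False
    c5: bool = False
    c6: bool = False
    guide_defined: bool = False

    @property
    def score(self) -> int:
        return sum((self.c1, self.c2, self.c3, self.c4, self.c5, self.c6))


@dataclass
class ReadCloudLocus:
    """A hairpin with the reads that fall on it.

    ``local_starts[i]`` is the 5' start offset of ``reads[i]`` in
    precursor-local coordinates (5'->3' of the expressed strand).
    """

    hairpin: Hairpin
    reads: list[ReadAlignment] = field(default_factory=list)
    local_starts: list[int] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)


@dataclass(frozen=True)
class ConservationHit:
    """A known mature miRNA aligned onto the precursor within edit limits."""

    db_id: str
    db_seq: str
    local_start: int
    local_end: int
    n_edits: int
    overlaps_guide: bool = False


@dataclass
class DuplicationInfo:
    """Genome-wide occurrences of the guide sequence."""

    n_genomic_occurrences: int
    other_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    overlaps_other_prediction: bool = False


@dataclass
class Prediction:
    """A finalized, scored miRNA precursor locus."""

    name: str
    hairpin: Hairpin
    quality: QualityScore
    duplex: DuplexCall | None
    locus: ReadCloudLocus
    weight: float | None = None
    conservation: list[ConservationHit] = field(default_factory=list)
    duplication: DuplicationInfo | None = None

    @property
    def total_reads(self) -> int:
        return self.locus.total_count

    @property
    def n_unique_reads(self) -> int:
        return len(self.locus.reads)


def locus_name(chrom: str, start: int, end: int, strand: str) -> str:
    """Collision-free sortable locus name: ``chrom__start-end_strand``."""
    return f"{chrom}__{start}-{end}_{strand}"
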