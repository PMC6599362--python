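"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .scoring import ScoringConfig


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    Paths may be None when the corresponding input is optional; thresholds
    default to the values the scoring and discovery stages document.
    """

    genome_fasta: str | Path | None = None
    bed: str | Path | None = None

    # prefilter
    mask_annotations: bool = True
    annotation_gff: str | Path | None = None
    mask_types: frozenset[str] = frozenset({"CDS", "tRNA", "rRNA", "snoRNA"})
    known_mirna_gff: str | Path | None = None
    max_genomic_hits: int = 5

    # locus discovery
    cluster_gap: int = 30
    peak_floor: int = 10
    max_distance: int = 350
    min_paired: int = 14
    partner_query_len: int = 25

    # hairpin
    fold_flank: int = 30
    min_hairpin_len: int = 60
    max_hairpin_len: int = 350
    min_paired_frac: float = 0.5
    mfei_filter: bool = True
    mfei_threshold: float = -0.6

    # scoring
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    min_score: int = 0

    # annotation
    mature_db: str | Path | None = None

    # significance (optional diagnostic; not part of the score)
    run_shuffle_test: bool = False
    shuffle_n: int = 100
    rng_seed: int = 0

    sort: str = "position"
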