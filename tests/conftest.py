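"""Shared fixtures: the canonical worked-example locus and small genomes."""

from __future__ import annotations

import pytest

from plantmir import fixtures as fx
from plantmir.scoring import compute_quality_score


@pytest.fixture(scope="session")
def reference_locus():
    """The canonical 114-copy worked example, folded and cloud-attached."""
    planted = fx.make_reference_locus()
    hp = fx.fold_planted(planted)
    locus = fx.cloud_from_offsets(hp, fx.reference_cloud(planted))
    return planted, hp, locus


@pytest.fixture(scope="session")
def reference_scored(reference_locus):
    planted, hp, locus = reference_locus
    quality, duplex = compute_quality_score(locus)
    return planted, hp, locus, quality, duplex


@pytest.fixture(scope="session")
def small_pool():
    """A small pool of folded synthetic hairpins for sweep-style tests."""
    return fx.hairpin_pool(12, seed=20240915)


@pytest.fixture()
def planted_genome():
    """One planted locus in a 10-kb genome, with its read set."""
    planted = fx.make_planted_locus(seed=7, position=4000)
    genome, truth = fx.make_genome([planted], length=10_000, seed=7)
    reads = fx.make_read_cloud(planted, seed=7) + fx.background_reads(
        genome, 20, seed=8
    )
    reads.sort(key=lambda r: (r.chrom, r.start))
    return planted, genome, reads
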