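"""The six criteria, guide selection, star geometry, and the star score."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from plantmir import fixtures as fx
from plantmir.model import Hairpin, QualityScore
from plantmir.scoring import (
    ScoringConfig,
    compute_quality_score,
    criterion1_stability,
    criterion2_reads,
    criterion4_precision,
    criterion5_star_expressed,
    criterion6_duplex_stability,
    expected_star_position,
    select_guide,
)


@pytest.fixture(scope="module")
def hp(reference_locus):
    return reference_locus[1]


def cloud(hp, items):
    return fx.cloud_from_offsets(hp, items)


class TestCriterion1:
    @pytest.mark.parametrize("mfei,met", [(-0.81, True), (-0.80, False), (-2.0, True)])
    def test_strict_threshold(self, mfei, met):
        h = Hairpin("c", "+", 0, 60, "GC" * 30, "." * 60)
        h.mfei = mfei
        assert criterion1_stability(h) is met


class TestCriterion2:
    def test_ten_reads_each_arm(self, hp):
        star = hp.arm3[0] + 2
        locus = cloud(hp, [(2, 21, 10), (star, 21, 10)])
        assert criterion2_reads(locus)

    def test_99_on_one_arm_fails(self, hp):
        assert not criterion2_reads(cloud(hp, [(2, 21, 99)]))

    def test_100_total_on_one_arm_passes(self, hp):
        assert criterion2_reads(cloud(hp, [(2, 21, 100)]))

    def test_loop_reads_count_toward_total_only(self, hp):
        loop_start = hp.loop[0] - 2  # straddles the loop, majority in it
        locus = cloud(hp, [(2, 21, 50), (loop_start, 8, 50)])
        assert criterion2_reads(locus)  # total 100
        locus2 = cloud(hp, [(2, 21, 50), (loop_start, 8, 49)])
        assert not criterion2_reads(locus2)  # 99 total, one arm populated


class TestSelectGuide:
    def test_worked_example_frequency(self, reference_locus):
        _, _, locus = reference_locus
        g = select_guide(locus)
        assert g is not None
        assert g.sequence == fx.REFERENCE_GUIDE
        assert len(g.sequence) == 21
        assert g.count == 71
        assert round(100 * g.frequency) == 62

    def test_below_one_third_undefined(self, hp):
        # top read holds 33 of 100 copies, strictly below one third
        locus = cloud(hp, [(2, 21, 33), (30, 21, 33), (50, 21, 33), (26, 21, 1)])
        assert select_guide(locus) is None

    def test_exactly_one_third_defined(self, hp):
        locus = cloud(hp, [(2, 21, 34), (26, 21, 34), (48, 21, 34)])
        g = select_guide(locus)
        assert g is not None and g.count == 34

    def test_single_read_is_guide_at_full_frequency(self, hp):
        g = select_guide(cloud(hp, [(2, 21, 5)]))
        assert g is not None and g.frequency == 1.0

    def test_count_tie_breaks_five_prime_first(self, hp):
        locus = cloud(hp, [(10, 21, 40), (2, 21, 40)])
        g = select_guide(locus)
        assert g is not None and g.local_start == 2


class TestExpectedStarPosition:
    def test_perfect_geometry_matches_planting(self):
        planted = fx.make_planted_locus(seed=21)
        h = fx.fold_planted(planted)
        assert (
            expected_star_position(h, planted.guide_offset, len(planted.guide_seq))
            == planted.star_offset
        )

    def test_worked_example_two_nt_shift(self, reference_locus):
        planted, h, _ = reference_locus
        star = expected_star_position(h, planted.guide_offset, 21)
        assert star == planted.star_offset
        # naive pairing of the guide 3' end, without the overhang, lands 2 nt away
        from plantmir.hairpin import pair_table

        pt = pair_table(h.structure)
        naive = pt[planted.guide_offset + 20]
        assert star - naive == 2

    def test_guide_over_loop_is_an_error(self, hp):
        with pytest.raises(ValueError, match="loop"):
            expected_star_position(hp, hp.loop[0] - 5, 21)


class TestCriterion4:
    def test_worked_example_precision(self, reference_locus):
        planted, h, _ = reference_locus
        locus = cloud(
            h,
            [
                (planted.guide_offset, 21, 71),
                (planted.star_offset, 21, 27),
                (32, 20, 16),  # background far from both windows
            ],
        )
        g = select_guide(locus)
        assert criterion4_precision(locus, g, planted.star_offset)  # 98/114

    @pytest.mark.parametrize("in_windows,met", [(74, False), (75, True)])
    def test_three_quarters_boundary(self, hp, in_windows, met):
        locus = cloud(hp, [(2, 21, in_windows), (32, 20, 100 - in_windows)])
        g = select_guide(locus)
        star = expected_star_position(hp, 2, 21)
        assert criterion4_precision(locus, g, star) is met

    def test_guide_window_spans_three_nt(self, hp):
        star = expected_star_position(hp, 6, 21)
        locus = cloud(hp, [(6, 21, 40), (3, 21, 35), (32, 20, 25)])
        g = select_guide(locus)
        assert criterion4_precision(locus, g, star)  # 75/100, start within -3


class TestCriterion5:
    def test_worked_example_star_support(self, reference_locus):
        planted, h, locus = reference_locus
        assert criterion5_star_expressed(locus, planted.star_offset)

    def test_all_reads_on_guide_arm(self, hp):
        locus = cloud(hp, [(2, 21, 100)])
        star = expected_star_position(hp, 2, 21)
        assert not criterion5_star_expressed(locus, star)

    @pytest.mark.parametrize("offset,met", [(5, True), (-5, True), (6, False), (-6, False)])
    def test_window_boundary(self, hp, offset, met):
        star = expected_star_position(hp, 2, 21)
        # short read so the +6 start still fits inside the precursor
        locus = cloud(hp, [(2, 21, 100), (star + offset, 15, 1)])
        assert criterion5_star_expressed(locus, star) is met


class TestCriterion6:
    def test_reference_duplex_with_mismatches_passes(self, reference_locus):
        planted, h, locus = reference_locus
        g = select_guide(locus)
        assert criterion6_duplex_stability(h, g, observed_star_start=planted.star_offset)

    def test_sparse_pairing_fails(self):
        # guide with only 8 of 21 bases paired
        seq = "G" * 8 + "A" * 23 + "C" * 8 + "A" * 21
        struct = "(" * 8 + "." * 23 + ")" * 8 + "." * 21
        h = Hairpin("c", "+", 0, len(seq), seq, struct)
        from plantmir.hairpin import _set_arms

        _set_arms(h)
        from plantmir.scoring import GuideCall

        g = GuideCall("G" * 8 + "A" * 13, 0, 50, 0.9, "5p")
        assert not criterion6_duplex_stability(h, g)

    def test_shifted_star_fails_overhang_check(self, reference_locus):
        planted, h, locus = reference_locus
        g = select_guide(locus)
        assert not criterion6_duplex_stability(
            h, g, observed_star_start=planted.star_offset + 3
        )


class TestComputeQualityScore:
    def test_worked_example_scores_six(self, reference_scored):
        planted, hp, locus, quality, duplex = reference_scored
        assert quality.score == 6
        assert duplex.star_count == 27
        assert duplex.overhang_3p == 2

    def test_no_guide_caps_score_at_two(self, hp):
        # top read 40 of 125 copies: below one third
        locus = cloud(hp, [(2, 21, 40), (26, 21, 40), (48, 21, 40), (30, 21, 5)])
        q, duplex = compute_quality_score(locus)
        assert duplex is None
        assert not q.guide_defined
        assert (q.c3, q.c4, q.c5, q.c6) == (False, False, False, False)
        assert q.score <= 2

    def test_no_star_caps_score_at_five(self, hp):
        locus = cloud(hp, [(2, 21, 120)])
        q, duplex = compute_quality_score(locus)
        assert q.guide_defined and not q.c5
        assert q.score <= 5

    def test_score_decomposition_over_all_64_combinations(self, reference_locus):
        _, _, locus = reference_locus
        for combo in product([False, True], repeat=6):
            overrides = {
                f"c{i + 1}": (lambda _l, v=v: v) for i, v in enumerate(combo)
            }
            q, _ = compute_quality_score(locus, criteria_overrides=overrides)
            assert (q.c1, q.c2, q.c3, q.c4, q.c5, q.c6) == combo
            assert q.score == sum(combo)

    def test_guide_copies_monotonically_help(self, hp):
        """More guide-position copies never lose c2, c3 or c4."""
        star = expected_star_position(hp, 2, 21)
        prev = (False, False, False)
        for guide_copies in (5, 20, 40, 120, 400):
            locus = cloud(hp, [(2, 21, guide_copies), (32, 20, 3), (star, 21, 2)])
            q, _ = compute_quality_score(locus)
            now = (q.c2, q.c3, q.c4)
            assert all(b or not a for a, b in zip(prev, now))
            prev = now

    def test_random_loci_respect_score_bounds(self, small_pool):
        no_guide = fx.sweep_no_guide_loci(60, seed=5, pool=small_pool)
        no_star = fx.sweep_no_star_loci(60, seed=6, pool=small_pool)
        assert max(compute_quality_score(l)[0].score for l in no_guide) <= 2
        assert max(compute_quality_score(l)[0].score for l in no_star) <= 5
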