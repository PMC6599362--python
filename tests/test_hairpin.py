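"""Folding, stem-loop selection, thermodynamic stats, dinucleotide shuffle."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
import RNA

from plantmir import fixtures as fx
from plantmir.hairpin import (
    dinucleotide_shuffle,
    fold_locally,
    mfei_prefilter,
    pair_table,
    select_stemloop,
    shuffle_significance,
    thermo_stats,
)
from plantmir.model import Hairpin


class TestFoldLocally:
    def test_planted_inverted_repeat_recovers_stem(self):
        seq, planted_struct = fx.make_hairpin(30, 6, seed=1)
        folds = fold_locally(seq)
        assert folds
        struct, mfe, start = min(folds, key=lambda f: f[1])
        pt = pair_table(struct)
        recovered = 0
        for i in range(30):  # planted pair (i, len-1-i)
            li, lj = i - start, len(seq) - 1 - i - start
            if 0 <= li < len(struct) and 0 <= lj < len(struct) and pt[li] == lj:
                recovered += 1
        assert recovered >= 28

    def test_homopolymer_has_no_stable_structure(self):
        assert fold_locally("A" * 100) == []

    def test_non_acgu_rejected(self):
        with pytest.raises(ValueError):
            fold_locally("ACGT" * 20)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fold_locally("ACGU" * 5)

    def test_local_mfe_close_to_global_fold(self, reference_locus):
        """The best local structure is as stable as a global fold of its span."""
        planted, hp, locus = reference_locus
        folds = fold_locally(planted.precursor_seq)
        struct, mfe, start = min(folds, key=lambda f: f[1])
        sub = planted.precursor_seq[start : start + len(struct)]
        _, global_mfe = RNA.fold(sub)
        assert abs(mfe - global_mfe) <= 0.5


class TestSelectStemloop:
    def test_short_hairpin_rejected(self):
        seq, _ = fx.make_hairpin(18, 4, seed=2)  # 40 nt total
        folds = fold_locally(seq)
        assert select_stemloop(seq, folds, min_len=60) is None

    def test_lowest_mfe_wins(self):
        weak, _ = fx.make_hairpin(32, 8, gc_frac=0.2, seed=3)
        strong, _ = fx.make_hairpin(32, 8, gc_frac=0.9, seed=4)
        seq = weak + "AAAAAAAAAA" + strong
        hp = select_stemloop(seq, fold_locally(seq))
        assert hp is not None
        assert hp.start >= len(weak)  # the GC-rich, more stable stem-loop

    def test_single_terminal_loop_and_arm_tiling(self, reference_locus):
        planted, hp, locus = reference_locus
        sel = select_stemloop(planted.precursor_seq, fold_locally(planted.precursor_seq))
        assert sel is not None
        assert sel.arm5[0] == 0 and sel.arm3[1] == len(sel.sequence)
        assert sel.arm5[1] == sel.loop[0] and sel.loop[1] == sel.arm3[0]
        inner = sel.structure[sel.loop[0] : sel.loop[1]]
        assert set(inner) == {"."}

    def test_paired_fraction_threshold(self):
        seq, _ = fx.make_hairpin(32, 8, seed=5)
        folds = fold_locally(seq)
        assert select_stemloop(seq, folds, min_paired_frac=0.99) is None


class TestThermoStats:
    def test_interrelations_hold_exactly(self, reference_locus):
        planted, hp, locus = reference_locus
        assert hp.mfe < 0
        assert hp.amfe == pytest.approx(hp.mfe / len(hp.sequence) * 100, abs=1e-9)
        assert hp.mfei == pytest.approx(hp.amfe / hp.gc_percent, abs=1e-9)
        assert 0 < hp.gc_percent <= 100

    def test_reference_hairpin_is_mirna_like(self, reference_locus):
        planted, hp, locus = reference_locus
        assert hp.mfei < -0.6

    def test_gc_free_sequence_rejected(self):
        hp = Hairpin("c", "+", 0, 60, "AU" * 30, "." * 60)
        with pytest.raises(ValueError, match="GC"):
            thermo_stats(hp)

    def test_amfe_invariant_under_tandem_duplication(self):
        seq, _ = fx.make_hairpin(30, 8, gc_frac=0.6, seed=6)
        struct, _ = RNA.fold(seq)
        single = thermo_stats(Hairpin("c", "+", 0, len(seq), seq, struct))
        double = thermo_stats(
            Hairpin("c", "+", 0, 2 * len(seq), seq + seq, struct + struct)
        )
        assert double.amfe == pytest.approx(single.amfe, rel=0.05)
        assert double.mfei == pytest.approx(single.mfei, rel=0.05)


class TestMfeiPrefilter:
    def _hp(self, mfei):
        hp = Hairpin("c", "+", 0, 60, "GC" * 30, "." * 60)
        hp.mfei = mfei
        return hp

    @pytest.mark.parametrize("mfei,kept", [(-0.61, True), (-0.60, False), (-0.2, False)])
    def test_strict_threshold(self, mfei, kept):
        assert bool(mfei_prefilter([self._hp(mfei)])) == kept

    def test_disabled_is_identity(self):
        hps = [self._hp(-0.1), self._hp(-2.0)]
        assert mfei_prefilter(hps, enabled=False) == hps


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts_and_endpoints(self):
        rng = np.random.default_rng(9)
        nts = np.array(list("ACGU"))
        for _ in range(25):
            seq = "".join(rng.choice(nts, size=int(rng.integers(20, 120))))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))

    def test_shuffles_actually_vary(self):
        rng = np.random.default_rng(10)
        seq, _ = fx.make_hairpin(30, 10, seed=10)
        shufs = {dinucleotide_shuffle(seq, rng) for _ in range(20)}
        assert len(shufs) > 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("ACG", np.random.default_rng(0))


class TestShuffleSignificance:
    def test_strong_hairpin_is_significant_across_seeds(self):
        seq, _ = fx.make_hairpin(40, 10, gc_frac=0.6, seed=11)
        for seed in range(10):
            res = shuffle_significance(seq, n=60, seed=seed)
            assert res.empirical_p <= 0.05
            assert res.empirical_p == pytest.approx(
                (res.n_as_stable + 1) / (res.n_shuffles + 1)
            )

    def test_unstructured_sequence_not_significant(self):
        seq = ("AAAAC" * 20)[:100]  # folds to MFE 0, as do its shuffles
        res = shuffle_significance(seq, n=20, seed=1)
        assert res.empirical_p > 0.9

    def test_minimum_shuffles_enforced(self):
        with pytest.raises(ValueError):
            shuffle_significance("ACGU" * 20, n=5)
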