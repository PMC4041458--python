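"""Profile statistics: fractions, peaks, agreement, pairing registers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tryclip.analysis import (
    PAIR_GU,
    PAIR_NONE,
    PAIR_WC,
    annotate_register_with_crosslinks,
    call_peaks,
    duplex_register,
    region_fraction,
    render_register,
    replicate_agreement,
    splice_label,
)
from tryclip.profiles import CrosslinkProfile


def profile_from(counts, ref_id="U1", display_end=None, sample="s"):
    counts = np.asarray(counts, dtype=np.int64)
    return CrosslinkProfile(sample, ref_id, counts, display_end or len(counts))


class TestRegionFraction:
    def test_forty_percent_in_terminal_region(self):
        counts = np.zeros(60, dtype=int)
        counts[1] = 20  # position 2
        counts[4] = 20  # position 5
        counts[29] = 60  # position 30
        p = profile_from(counts, display_end=60)
        assert region_fraction(p, (1, 9)) == pytest.approx(0.40)

    def test_whole_display_range_is_one(self):
        p = profile_from([1, 2, 3, 0, 4], display_end=5)
        assert region_fraction(p, (1, 5)) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            region_fraction(profile_from([0, 0, 0]), (1, 2))

    def test_counts_beyond_display_end_ignored(self):
        p = profile_from([5, 0, 0, 0, 9], display_end=4)
        assert region_fraction(p, (1, 4)) == 1.0

    @settings(deadline=None, max_examples=100)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=4, max_size=40).filter(
            lambda c: sum(c) > 0
        ),
        data=st.data(),
    )
    def test_partition_identity(self, counts, data):
        """Fractions over a partition of the display range sum to 1."""
        p = profile_from(counts)
        cut = data.draw(st.integers(1, len(counts) - 1))
        total = region_fraction(p, (1, cut)) + region_fraction(p, (cut + 1, len(counts)))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestCallPeaks:
    def test_single_maximum(self):
        counts = np.zeros(60, dtype=int)
        counts[22] = 10  # position 23
        (peak,) = call_peaks(profile_from(counts))
        assert (peak.position, peak.height, peak.prominence_fraction) == (23, 10, 1.0)

    def test_flat_zero_profile(self):
        assert call_peaks(profile_from([0] * 30)) == []

    def test_four_characteristic_peaks(self):
        """Maxima at 15, 39, 50 and 53 are all recovered with +/-2 windows."""
        counts = np.ones(60, dtype=int)
        for pos, h in [(15, 40), (39, 70), (50, 30), (53, 35)]:
            counts[pos - 1] = h
        peaks = call_peaks(profile_from(counts), min_fraction=0.1, min_separation=2)
        assert [p.position for p in peaks] == [39, 15, 53, 50]  # by height
        # exhaustive window-check oracle
        x = counts
        expected = [
            i + 1
            for i in range(len(x))
            if x[i] >= 0.1 * x.max()
            and all(
                x[j] < x[i]
                for j in range(max(0, i - 2), min(len(x), i + 3))
                if j != i
            )
        ]
        assert sorted(p.position for p in peaks) == expected

    def test_plateau_reports_five_prime_start_and_extent(self):
        counts = [0, 0, 8, 8, 8, 0, 0]
        (peak,) = call_peaks(profile_from(counts))
        assert peak.position == 3 and peak.plateau_extent == 3

    def test_scaling_invariance(self):
        counts = [1, 5, 1, 0, 3, 1, 9, 2, 0, 4]
        base = call_peaks(profile_from(counts))
        scaled = call_peaks(profile_from([10 * c for c in counts]))
        assert [(p.position, p.plateau_extent) for p in base] == [
            (p.position, p.plateau_extent) for p in scaled
        ]

    def test_min_fraction_threshold(self):
        counts = [0, 100, 0, 0, 5, 0]
        peaks = call_peaks(profile_from(counts), min_fraction=0.1)
        assert [p.position for p in peaks] == [2]


class TestReplicateAgreement:
    def test_scaled_profile_perfectly_correlated(self):
        p1 = profile_from([1, 5, 2, 0, 9])
        p2 = profile_from([2, 10, 4, 0, 18])
        assert replicate_agreement(p1, p2) == pytest.approx(1.0)

    def test_reversed_profile_not_perfect(self):
        p1 = profile_from([9, 4, 1, 0, 0])
        p2 = profile_from([0, 0, 1, 4, 9])
        assert replicate_agreement(p1, p2) < 1.0

    def test_spearman_with_ties(self):
        p1 = profile_from([1, 1, 2, 3, 5])
        p2 = profile_from([2, 2, 3, 4, 9])
        assert replicate_agreement(p1, p2, method="spearman") == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            replicate_agreement(profile_from([3, 3, 3]), profile_from([1, 2, 3]))

    @settings(deadline=None, max_examples=60)
    @given(
        a=st.lists(st.integers(0, 20), min_size=5, max_size=20),
        b=st.lists(st.integers(0, 20), min_size=5, max_size=20),
    )
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if len(set(a)) == 1 or len(set(b)) == 1:
            return
        p1, p2 = profile_from(a), profile_from(b)
        for method in ("pearson", "spearman"):
            assert replicate_agreement(p1, p2, method) == pytest.approx(
                replicate_agreement(p2, p1, method)
            )


WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}


def brute_force_pairs(rna_segment, target, offset, allow_gu=True):
    """Independent pairing-table count (antiparallel register)."""
    n = 0
    for j, base in enumerate(reversed(rna_segment)):
        t = offset + j
        if 0 <= t < len(target):
            pair = (base, target[t])
            if pair in WC or (allow_gu and pair in GU):
                n += 1
    return n


class TestDuplexRegister:
    def test_acagag_register_fully_paired(self):
        """The invariant hexanucleotide pairs perfectly with a CTCTGT target."""
        reg = duplex_register("ACAGAG", (1, 6), "CTCTGT", splice_index=2, rna_id="U6")
        assert reg.n_paired == 6
        assert set(reg.pair_mask) == {PAIR_WC}

    def test_empty_target(self):
        reg = duplex_register("ACAGAG", (1, 6), "", splice_index=0)
        assert reg.n_paired == 0 and reg.pair_mask == ()

    def test_no_self_pairs(self):
        reg = duplex_register("AAAA", (1, 4), "AAAA", splice_index=1)
        assert reg.n_paired == 0
        assert set(reg.pair_mask) == {PAIR_NONE}

    def test_gu_wobble_toggle(self):
        # reversed RNA "G" faces target "T": GU wobble
        with_gu = duplex_register("G", (1, 1), "T", splice_index=1, allow_gu=True)
        without = duplex_register("G", (1, 1), "T", splice_index=1, allow_gu=False)
        assert with_gu.pair_mask == (PAIR_GU,)
        assert without.pair_mask == (PAIR_NONE,)

    def test_rna_alphabet_accepted(self):
        reg = duplex_register("ACAGAG", (1, 6), "CUCUGU", splice_index=2)
        assert reg.n_paired == 6

    def test_offset_out_of_range(self):
        with pytest.raises(ValueError, match="off the target"):
            duplex_register("ACAGAG", (1, 6), "CTCTGT", splice_index=2, offset=40)

    @settings(deadline=None, max_examples=200)
    @given(
        rna=st.text(alphabet="ACGT", min_size=1, max_size=12),
        target=st.text(alphabet="ACGT", min_size=1, max_size=12),
        offset=st.integers(-3, 12),
        allow_gu=st.booleans(),
    )
    def test_matches_brute_force_pairing_table(self, rna, target, offset, allow_gu):
        try:
            reg = duplex_register(
                rna, (1, len(rna)), target, splice_index=1, offset=offset, allow_gu=allow_gu
            )
        except ValueError:
            assert brute_force_pairs(rna, target, offset, allow_gu) == 0 or not (
                -len(rna) < offset < len(target)
            )
            return
        assert reg.n_paired == brute_force_pairs(rna, target, offset, allow_gu)
        assert reg.n_paired == sum(1 for m in reg.pair_mask if m != PAIR_NONE)


class TestSpliceLabels:
    def test_minus_one_plus_one_convention(self):
        # splice site after target position 4: 4 -> -1, 5 -> +1
        assert splice_label(4, 4) == -1
        assert splice_label(5, 4) == 1
        assert splice_label(1, 4) == -4
        assert splice_label(7, 4) == 3


class TestAnnotateRegister:
    def _register(self, toy_refset):
        u6 = toy_refset.get("U6").seq
        return duplex_register(u6, (37, 42), "CTCTGT", splice_index=2, rna_id="U6")

    def test_flanking_marks_reported(self, toy_refset):
        """Crosslinks at 32 and 43 flank, but do not fall inside, the box."""
        counts = np.zeros(97, dtype=int)
        counts[31] = 12  # position 32
        counts[42] = 9  # position 43
        profile = CrosslinkProfile("u1c", "U6", counts, display_end=82)
        reg = annotate_register_with_crosslinks(self._register(toy_refset), profile)
        assert reg.marks == ()
        assert reg.flank_marks == (32, 43)

    def test_zero_profile_zero_marks(self, toy_refset):
        profile = CrosslinkProfile("u1c", "U6", np.zeros(97, dtype=int), display_end=82)
        reg = annotate_register_with_crosslinks(self._register(toy_refset), profile)
        assert reg.marks == () and reg.flank_marks == ()

    def test_threshold_zero_marks_every_in_range_position(self, toy_refset):
        profile = CrosslinkProfile("u1c", "U6", np.zeros(97, dtype=int), display_end=82)
        reg = annotate_register_with_crosslinks(
            self._register(toy_refset), profile, threshold=0
        )
        assert reg.marks == tuple(range(37, 43))

    def test_missing_profile_rejected(self, toy_refset):
        profile = CrosslinkProfile("u1c", "U1", np.zeros(75, dtype=int), display_end=60)
        with pytest.raises(ValueError, match="no profile"):
            annotate_register_with_crosslinks(self._register(toy_refset), profile)

    def test_render_smoke(self, toy_refset):
        counts = np.zeros(97, dtype=int)
        counts[36] = 5
        profile = CrosslinkProfile("u1c", "U6", counts, display_end=82)
        reg = annotate_register_with_crosslinks(self._register(toy_refset), profile)
        text = render_register(reg)
        assert "U6" in text and "5'ss" in text
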