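"""5'-branch annotation: interval intersection, chromatin summaries, TFBS
counting, and PWM scanning with its gain/loss calls."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famprior.regulatory5p import (
    ChromatinProfile,
    MotifCall,
    annotate_5p,
    build_alt_window,
    count_tfbs,
    intersect_track,
    motif_delta,
    pwm_relative_score,
    revcomp,
    summarize_chromatin,
)
from famprior.types import GenomicInterval, IntervalTrack, PWM, VariantRecord


def _track(*ivs, name="t"):
    return IntervalTrack(name, [GenomicInterval(*iv) for iv in ivs])


class TestIntersectTrack:
    def test_snv_containment_and_half_open_boundary(self, make_variant):
        track = _track(("1", 50, 150))
        assert intersect_track(make_variant(pos=100), track)
        assert intersect_track(make_variant(pos=150), track)  # base 150 = [149,150)
        assert not intersect_track(make_variant(pos=151), track)
        assert not intersect_track(make_variant(pos=100, chrom="2"), track)

    def test_deletion_overlapping_edge_by_one_base(self, make_variant):
        # deletion at pos 100 (ACGT->A) removes 1-based bases 101..103;
        # a track starting at 1-based 103 (0-based 102) shares exactly base 103
        v = make_variant(pos=100, ref="ACGT", alt="A")
        assert intersect_track(v, _track(("1", 102, 200)))
        # track starting at 1-based 104 shares nothing
        assert not intersect_track(v, _track(("1", 103, 200)))

    def test_insertion_point_containment(self, make_variant):
        v = make_variant(pos=100, ref="A", alt="ACG")  # point after base 100
        assert intersect_track(v, _track(("1", 95, 105)))
        assert not intersect_track(v, _track(("1", 110, 120)))


class TestSummarizeChromatin:
    def test_chmm_20_percent_inclusive(self):
        states = {f"cl{i}": ("TssA" if i < 26 else "Quies") for i in range(127)}
        profile = ChromatinProfile(chmm_states=states)
        chmm, _ = summarize_chromatin(profile)
        assert "TssA" in chmm  # 26/127 = 20.47%
        states["cl25"] = "Quies"  # down to 25/127 = 19.7%
        chmm, _ = summarize_chromatin(ChromatinProfile(chmm_states=states))
        assert "TssA" not in chmm

    def test_histone_20_percent_exclusive(self):
        marks = {f"hl{i}": (frozenset({"H3K4Me3"}) if i < 3 else frozenset()) for i in range(14)}
        _, hist = summarize_chromatin(ChromatinProfile(histone_marks=marks))
        assert "H3K4Me3" in hist  # 3/14 = 21.4% > 20%
        marks["hl2"] = frozenset()
        _, hist = summarize_chromatin(ChromatinProfile(histone_marks=marks))
        assert "H3K4Me3" not in hist  # 2/14 = 14.3%

    def test_invariant_to_cell_line_ordering(self):
        fwd = {f"cl{i}": ("Enh" if i % 3 == 0 else "Tx") for i in range(30)}
        rev = dict(reversed(list(fwd.items())))
        assert summarize_chromatin(ChromatinProfile(chmm_states=fwd)) == summarize_chromatin(
            ChromatinProfile(chmm_states=rev)
        )

    def test_empty_profile_warns(self, caplog):
        with caplog.at_level("WARNING"):
            chmm, hist = summarize_chromatin(ChromatinProfile())
        assert chmm == frozenset() and hist == frozenset()


class TestCountTfbs:
    def test_distinct_tf_counting(self, make_variant):
        track = _track(
            ("1", 90, 110, {"tf_name": "CTCF"}),
            ("1", 95, 120, {"tf_name": "CTCF"}),
            ("1", 80, 105, {"tf_name": "EBF1"}),
        )
        assert count_tfbs(make_variant(pos=100), track) == (2, ["CTCF", "EBF1"])
        assert count_tfbs(make_variant(pos=500), track) == (0, [])

    def test_thirteen_tf_fixture(self, make_variant):
        tfs = [f"TF{i:02d}" for i in range(13)]
        track = _track(*[("1", 90, 110, {"tf_name": t}) for t in tfs])
        count, names = count_tfbs(make_variant(pos=100), track)
        assert count == 13 and names == sorted(tfs)


def _consensus_pwm(consensus, pwm_id="P1", weight=10):
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = weight
    return PWM(pwm_id, "TF", counts)


def _brute_best(pwm, seq, pseudo=0.8):
    """Independent scorer: explicit per-placement arithmetic, no numpy."""
    L = pwm.length
    cols = []
    for j in range(L):
        col = [pwm.counts[i, j] + pseudo / 4 for i in range(4)]
        tot = sum(col)
        cols.append([math.log2((c / tot) / 0.25) for c in col])
    smin = sum(min(c) for c in cols)
    smax = sum(max(c) for c in cols)
    best = None
    for s in (seq.upper(), revcomp(seq)):
        for off in range(len(s) - L + 1):
            window = s[off : off + L]
            if "N" in window:
                continue
            raw = sum(cols[j]["ACGT".index(b)] for j, b in enumerate(window))
            rel = 1.0 if smax == smin else (raw - smin) / (smax - smin)
            best = rel if best is None else max(best, rel)
    return best


class TestPwmRelativeScore:
    def test_consensus_scores_one(self):
        pwm = _consensus_pwm("ACGT")
        hit = pwm_relative_score(pwm, "ACGT")
        assert hit.score == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self):
        pwm = _consensus_pwm("AAAA")
        # the complement-poor anti-consensus on both strands
        hit = pwm_relative_score(pwm, "GGGG")
        assert hit.score == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_enumeration_on_toy(self):
        pwm = PWM("t", "T", np.array([[4, 0], [0, 3], [1, 1], [0, 1]], dtype=float))
        for seq in ("ACGT", "TTTT", "CANG", "GTAC"):
            hit = pwm_relative_score(pwm, seq)
            oracle = _brute_best(pwm, seq)
            if oracle is None:
                assert hit is None
            else:
                assert hit.score == pytest.approx(oracle, abs=1e-12)

    def test_sequence_shorter_than_motif(self):
        assert pwm_relative_score(_consensus_pwm("ACGTA"), "ACG") is None

    def test_all_n_window_unscannable(self):
        assert pwm_relative_score(_consensus_pwm("AC"), "NNN") is None

    @settings(max_examples=60, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=20),
        st.integers(min_value=0, max_value=2 ** 31 - 1),
    )
    def test_strand_symmetry(self, seq, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 9, size=(4, 3)).astype(float)
        counts[rng.integers(0, 4), :] += 1  # keep every column positive
        pwm = PWM("h", "H", counts)
        fwd = pwm_relative_score(pwm, seq)
        rev = pwm_relative_score(pwm, revcomp(seq))
        assert fwd is not None and rev is not None
        assert fwd.score == pytest.approx(rev.score, abs=1e-12)


class TestMotifDelta:
    WINDOW = "TTTTTTTTAACGTTTTTTTTT"  # consensus ACGT at offsets 9..12, variant base 10

    def _variant(self, make_variant, ref="C", alt="G"):
        return make_variant(pos=11, ref=ref, alt=alt)

    def test_destroying_planted_consensus_is_lost(self, make_variant):
        pwm = _consensus_pwm("ACGT")
        v = self._variant(make_variant)
        (delta,) = motif_delta(v, self.WINDOW, [pwm], tau=0.8)
        assert delta.call is MotifCall.LOST
        assert delta.ref_score >= 0.8 > delta.alt_score

    def test_swapping_ref_and_alt_maps_lost_to_gained(self, make_variant):
        pwm = _consensus_pwm("ACGT")
        v = self._variant(make_variant)
        alt_window = build_alt_window(self.WINDOW, v.ref, v.alt)
        v_swapped = make_variant(pos=11, ref=v.alt, alt=v.ref)
        (delta,) = motif_delta(v_swapped, alt_window, [pwm], tau=0.8)
        assert delta.call is MotifCall.GAINED

    def test_reverse_complement_invariance(self, make_variant):
        pwm = _consensus_pwm("ACGT")
        v = self._variant(make_variant)
        (fwd,) = motif_delta(v, self.WINDOW, [pwm], tau=0.8)
        rc_window = revcomp(self.WINDOW)
        v_rc = make_variant(pos=11, ref=revcomp(v.ref), alt=revcomp(v.alt))
        (rev,) = motif_delta(v_rc, rc_window, [pwm], tau=0.8)
        assert fwd.call is rev.call
        assert fwd.ref_score == pytest.approx(rev.ref_score, abs=1e-12)
        assert fwd.alt_score == pytest.approx(rev.alt_score, abs=1e-12)

    def test_subthreshold_everywhere_is_unchanged(self, make_variant):
        pwm = _consensus_pwm("GGGGG")
        (delta,) = motif_delta(self._variant(make_variant), self.WINDOW, [pwm], tau=0.8)
        assert delta.call is MotifCall.UNCHANGED

    def test_center_mismatch_errors(self, make_variant):
        v = make_variant(pos=11, ref="A", alt="G")  # window holds C at the center
        with pytest.raises(ValueError, match="not found at the center"):
            motif_delta(v, self.WINDOW, [_consensus_pwm("ACGT")])

    def test_indel_windows_scanned_fully(self, make_variant):
        # the deletion removes two bases of the planted consensus site
        window = "TTTTTTTTTTACGTTTTTTTT"
        v = make_variant(pos=11, ref="ACG", alt="A")
        pwm = _consensus_pwm("ACGT")
        (delta,) = motif_delta(v, window, [pwm], tau=0.8)
        assert delta.call is MotifCall.LOST


class TestAnnotate5p:
    def test_tri_state_unknown_when_track_missing(self, make_variant):
        ann = annotate_5p(make_variant(pos=100))
        assert ann.in_promoter is None and ann.in_cpg is None
        ann = annotate_5p(make_variant(pos=100), promoter_track=_track(("1", 90, 110)))
        assert ann.in_promoter is True and ann.in_cpg is None
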