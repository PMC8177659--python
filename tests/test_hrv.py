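"""rMSSD, classification matrices, beat matching and Bland-Altman."""

import numpy as np
import pytest

from ibiqc import (
    CleanTraceSpec,
    ClassificationMatrix,
    IBITrace,
    InsufficientDataError,
    bland_altman,
    generate_clean_trace,
    generate_reference_pair,
    match_beats,
    rmssd,
)


def brute_rmssd(ibis):
    """Direct evaluation of the defining formula."""
    d = [ibis[j + 1] - ibis[j] for j in range(len(ibis) - 1)]
    return (sum(x * x for x in d) / len(d)) ** 0.5


class TestRmssd:
    def test_constant_sequence_is_zero(self):
        assert rmssd([640.0] * 50) == 0.0

    def test_alternating_closed_form(self):
        assert rmssd([500.0, 510.0, 500.0, 510.0]) == pytest.approx(10.0, abs=1e-12)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(50):
            ibis = rng.uniform(400, 1500, size=300)
            assert rmssd(ibis) == pytest.approx(brute_rmssd(list(ibis)), rel=1e-9)

    def test_translation_invariance_and_linear_scaling(self, rng):
        ibis = rng.uniform(500, 1000, size=100)
        base = rmssd(ibis)
        assert rmssd(ibis + 123.4) == pytest.approx(base, rel=1e-12)
        assert rmssd(ibis * 2.5) == pytest.approx(base * 2.5, rel=1e-12)

    def test_exclusion_splits_difference_chain(self):
        # excluding the middle 5000 ms beat must not create a bridged diff
        ibis = np.array([500.0, 510.0, 5000.0, 520.0, 530.0])
        excl = np.array([False, False, True, False, False])
        assert rmssd(ibis, exclude=excl) == pytest.approx(10.0, abs=1e-12)

    def test_too_few_usable_beats(self):
        with pytest.raises(InsufficientDataError):
            rmssd([500.0])
        with pytest.raises(InsufficientDataError):
            rmssd([500.0, 600.0, 700.0], exclude=[False, True, False])


class TestClassificationMatrix:
    def test_flat_matrix_reproduces_published_percentages(self):
        m = ClassificationMatrix.from_counts("flat", 735429, 48196, 1071522, 2142533)
        assert m.total == 3997680
        assert m.n_flagged == 783625
        assert m.pct_of_corrected_flagged == pytest.approx(40.7, abs=0.06)
        assert m.pct_of_flagged_corrected == pytest.approx(93.9, abs=0.06)
        assert m.pct_of_noncorrected_flagged == pytest.approx(2.2, abs=0.06)

    def test_stair_matrix_reproduces_published_percentages(self):
        m = ClassificationMatrix.from_counts("stair", 99015, 227, 1707890, 2190548)
        assert m.total == 3997680
        assert m.n_flagged == 99242
        assert m.pct_of_corrected_flagged == pytest.approx(5.5, abs=0.06)
        assert m.pct_of_flagged_corrected == pytest.approx(99.8, abs=0.06)
        assert m.pct_of_noncorrected_flagged == pytest.approx(0.01, abs=0.006)

    def test_all_false_flags(self):
        t = IBITrace(ibi_ms=np.full(10, 500.0))
        m = ClassificationMatrix.from_trace(t, "flat")
        assert (m.a, m.b, m.c, m.d) == (0, 0, 0, 10)
        assert m.pct_of_corrected_flagged is None
        assert m.pct_of_flagged_corrected is None

    def test_cells_sum_to_beat_count(self, rng):
        n = 500
        t = IBITrace(
            ibi_ms=np.full(n, 500.0),
            corrected=rng.random(n) < 0.4, flat=rng.random(n) < 0.2,
        )
        m = ClassificationMatrix.from_trace(t, "flat")
        assert m.total == n
        assert m.a == int((t.flat & t.corrected).sum())

    def test_pooling(self):
        a = ClassificationMatrix.from_counts("flat", 1, 2, 3, 4)
        b = ClassificationMatrix.from_counts("flat", 10, 20, 30, 40)
        assert (a + b).total == 110


class TestMatchBeats:
    def test_identical_streams_fully_paired(self, clean_ar_trace):
        t, r, unmatched = match_beats(clean_ar_trace, clean_ar_trace)
        assert t.size == clean_ar_trace.n_beats
        assert unmatched == 0

    def test_shifted_beyond_tolerance_gives_no_pairs(self):
        a = IBITrace(ibi_ms=np.full(20, 1000.0))
        b = a.copy()
        b.ibi_ms = b.ibi_ms.copy()
        b.ibi_ms[0] += 500.0  # shift the whole reference stream +0.5 s
        t, r, unmatched = match_beats(a, IBITrace(ibi_ms=b.ibi_ms), max_offset_s=0.25)
        assert t.size == 0

    def test_jittered_pair_mostly_matched(self, clean_ar_trace):
        ref = generate_reference_pair(clean_ar_trace, 50.0, seed=3)
        t, r, unmatched = match_beats(clean_ar_trace, ref)
        assert t.size >= 0.99 * clean_ar_trace.n_beats


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.linspace(500, 900, 10)
        res = bland_altman(x, x)
        assert res.bias_ms == 0.0
        assert res.loa_lower_ms == res.loa_upper_ms == 0.0

    def test_hand_computed_two_differences(self):
        """Differences {+2, -2}: bias 0, sd = 2*sqrt(2), LoA = +/-5.5437."""
        res = bland_altman(np.array([2.0, -2.0]), np.zeros(2))
        assert res.bias_ms == pytest.approx(0.0, abs=1e-12)
        assert res.sd_diff_ms == pytest.approx(2.828427, abs=1e-6)
        assert res.loa_upper_ms == pytest.approx(5.5437, abs=1e-3)
        assert res.loa_lower_ms == pytest.approx(-5.5437, abs=1e-3)

    def test_constant_offset_pairs(self):
        x = np.linspace(500, 900, 20)
        res = bland_altman(x + 3.0, x)
        assert res.bias_ms == pytest.approx(3.0)
        assert res.loa_lower_ms == pytest.approx(3.0)
        assert res.loa_upper_ms == pytest.approx(3.0)

    def test_loa_matches_direct_arithmetic(self):
        res = bland_altman(np.array([2.0, -2.0, 2.0]), np.array([0.0, 0.0, 4.0]))
        d = np.array([2.0, -2.0, -2.0])
        assert res.bias_ms == pytest.approx(d.mean())
        assert res.sd_diff_ms == pytest.approx(d.std(ddof=1))
        assert res.loa_upper_ms == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman(np.array([1.0]), np.array([1.0]))

    def test_bias_recovery_coverage(self):
        """Synthetic pairs with bias 0.9 ms, diff SD 8 ms: the true bias lies
        inside the estimated 95% CI in >= 93 of 100 replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            ref = rng.uniform(500, 900, size=2500)
            test = ref + 0.9 + rng.normal(0, 8.0, size=2500)
            res = bland_altman(test, ref)
            if res.ci_bias[0] <= 0.9 <= res.ci_bias[1]:
                hits += 1
        assert hits >= 93
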