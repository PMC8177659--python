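"""Flats/stairs injection operations and the Monte-Carlo bias study."""

import numpy as np
import pytest
from scipy import stats

from ibiqc import (
    IBITrace,
    SpecError,
    flat_diff_fraction,
    inject_flat_step,
    inject_stair_block,
    rmssd,
    run_injection_study,
    stair_diff_coverage,
)


class TestFlatStep:
    def test_forced_copy_next(self, rng):
        t = IBITrace(ibi_ms=[500.0, 510.0])
        out, i = inject_flat_step(t, rng, index=0)
        assert i == 0
        np.testing.assert_array_equal(out.ibi_ms, [500.0, 500.0])

    def test_repeated_until_all_equal_gives_zero_rmssd(self, rng):
        t = IBITrace(ibi_ms=np.array([500.0, 510.0, 520.0, 530.0, 540.0]))
        for i in range(4):
            t, _ = inject_flat_step(t, rng, index=i)
        assert rmssd(t.ibi_ms) == 0.0
        assert flat_diff_fraction(t.ibi_ms) == 1.0

    def test_chosen_indices_uniform(self):
        """Chi-square uniformity of the chosen index over [0, n-2]."""
        rng = np.random.default_rng(99)
        t = IBITrace(ibi_ms=np.arange(1, 21, dtype=float) * 100)
        counts = np.zeros(19, dtype=int)
        for _ in range(10**5):
            _, i = inject_flat_step(t, rng)
            counts[i] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 0.001


class TestStairBlock:
    def test_forced_linear_fill(self, rng):
        t = IBITrace(ibi_ms=[600.0, 777.0, 888.0, 660.0])
        out, (i, j) = inject_stair_block(t, rng, indices=(0, 3))
        np.testing.assert_allclose(out.ibi_ms, [600.0, 620.0, 640.0, 660.0])

    def test_equal_anchors_degenerate_flat(self, rng):
        t = IBITrace(ibi_ms=[600.0, 777.0, 888.0, 600.0])
        out, _ = inject_stair_block(t, rng, indices=(0, 3))
        assert np.all(out.ibi_ms == 600.0)

    def test_replaced_count_matches_uniform_pair_expectation(self):
        """Mean replaced-beat count over many draws approaches E[j-i-1] for
        uniform index pairs with j-i >= 2."""
        rng = np.random.default_rng(7)
        n = 50
        t = IBITrace(ibi_ms=np.linspace(500, 1000, n))
        # enumerate the exact expectation over all valid pairs
        gaps = [(j - i - 1) for i in range(n) for j in range(i + 2, n)]
        expected = np.mean(gaps)
        counts = []
        for _ in range(4000):
            _, (i, j) = inject_stair_block(t, rng)
            counts.append(j - i - 1)
        se = np.std(gaps) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_invalid_indices(self, rng):
        t = IBITrace(ibi_ms=[500.0] * 6)
        with pytest.raises(SpecError):
            inject_stair_block(t, rng, indices=(2, 3))


class TestCoverageMetrics:
    def test_flat_fraction(self):
        assert flat_diff_fraction(np.array([5.0, 5.0, 6.0])) == pytest.approx(0.5)

    def test_stair_coverage_requires_three_equal_diffs(self):
        assert stair_diff_coverage(np.array([600.0, 620.0, 640.0, 660.0])) == 1.0
        assert stair_diff_coverage(np.array([600.0, 620.0, 640.0])) == 0.0
        assert stair_diff_coverage(np.array([600.0, 600.0, 600.0, 600.0])) == 0.0


@pytest.fixture(scope="module")
def curves(clean_ar_trace):
    flat = run_injection_study(clean_ar_trace, "flat", n_runs=120, seed=5)
    stair = run_injection_study(clean_ar_trace, "stair", n_runs=1000, seed=5)
    return flat, stair


class TestInjectionStudy:
    def test_requires_clean_trace(self, clean_ar_trace):
        t = clean_ar_trace.copy()
        t.corrected[0] = True
        with pytest.raises(SpecError):
            run_injection_study(t, "flat", n_runs=1)

    def test_base_bin_matches_uncontaminated_rmssd(self, curves, clean_ar_trace):
        flat, stair = curves
        assert flat.base_rmssd_ms == pytest.approx(rmssd(clean_ar_trace.ibi_ms))
        assert flat.value_at(0.01) == pytest.approx(flat.base_rmssd_ms, rel=0.02)

    def test_rmssd_zero_at_full_contamination(self, curves):
        flat, stair = curves
        assert flat.full_contamination_rmssd_ms == 0.0
        assert stair.full_contamination_rmssd_ms < 0.01 * stair.base_rmssd_ms

    def test_binned_mean_nonincreasing(self, curves):
        for curve in curves:
            m = curve.mean_rmssd_ms[~np.isnan(curve.mean_rmssd_ms)]
            # allow sampling noise: no increase larger than 2% of base
            assert np.all(np.diff(m) < 0.02 * curve.base_rmssd_ms)

    def test_low_contamination_effect_is_linear(self, curves):
        for curve in curves:
            m = curve.mean_rmssd_ms[:5]
            x = curve.bin_upper[:5]
            ok = ~np.isnan(m)
            fit = stats.linregress(x[ok], m[ok])
            assert fit.rvalue**2 >= 0.9

    def test_stairs_reduce_rmssd_faster_than_flats(self, curves):
        flat, stair = curves
        red_flat = flat.base_rmssd_ms - flat.value_at(0.05)
        red_stair = stair.base_rmssd_ms - stair.value_at(0.05)
        assert red_stair > red_flat > 0

    def test_seed_determinism(self, clean_ar_trace):
        a = run_injection_study(clean_ar_trace, "stair", n_runs=50, seed=3)
        b = run_injection_study(clean_ar_trace, "stair", n_runs=50, seed=3)
        np.testing.assert_array_equal(a.n_samples, b.n_samples)
        np.testing.assert_allclose(
            a.mean_rmssd_ms[a.n_samples > 0], b.mean_rmssd_ms[b.n_samples > 0]
        )

    def test_higher_rmssd_trace_loses_more(self, clean_ar_trace):
        """At equal contamination the absolute rMSSD reduction grows with
        the trace's baseline rMSSD (the study's conservativeness argument)."""
        from ibiqc import CleanTraceSpec, generate_clean_trace

        low = generate_clean_trace(
            CleanTraceSpec(duration_s=600.0, target_rmssd_ms=69.0, ar_coefficient=0.5, seed=21)
        )
        high = clean_ar_trace  # target 108 ms
        red = {}
        for name, tr in (("low", low), ("high", high)):
            c = run_injection_study(tr, "flat", n_runs=60, seed=9)
            red[name] = c.base_rmssd_ms - c.value_at(0.05)
        assert red["high"] > red["low"]

    def test_cumulative_stair_schedule_runs(self, clean_ar_trace):
        c = run_injection_study(
            clean_ar_trace, "stair", n_runs=3, seed=1, stair_schedule="cumulative", max_steps=30
        )
        assert c.n_samples.sum() == 90
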