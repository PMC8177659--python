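"""Monte-Carlo study of how injected flats or stairs bias rMSSD.

Starting from a clean trace, errors are injected step by step:

* a *flat step* picks a random IBI and copies its value onto the next IBI,
  creating two consecutive identical values;
* a *stair block* picks two random IBIs (at least two apart) and replaces
  every intervening IBI with a linear ramp between them (real-valued, so
  the successive differences are exactly equal).

After every step the realized contamination proportion and the rMSSD of
the modified trace are recorded; samples are pooled across runs into
proportion bins.  Contamination is measured on the *detected state*, as the
fraction of successive differences lying inside detected flat (zero
difference) or stair (>= 3 equal non-zero differences) runs — the quantity
that drives rMSSD directly, and the scale on which full contamination
(proportion 1.0) coincides with a fully flat trace or a single ramp.

Flat runs iterate until the trace is completely flat, so every run spans
the whole contamination range; stair runs add blocks until every
difference is covered by a ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import SpecError
from .trace import IBITrace

_RESERVOIR_K = 512  # per-bin sample cap for the percentile band


# -- single-step operations ------------------------------------------------

def inject_flat_step(trace: IBITrace, rng: np.random.Generator, index: int | None = None):
    """Copy IBI(i) onto IBI(i+1) for a uniform i in [0, n-2].

    Returns ``(modified copy, i)``.  ``index`` forces the choice (tests).
    """
    n = trace.n_beats
    if n < 2:
        raise SpecError("flat injection needs at least 2 beats")
    i = int(rng.integers(0, n - 1)) if index is None else int(index)
    out = trace.copy()
    out.ibi_ms[i + 1] = out.ibi_ms[i]
    return out, i


def inject_stair_block(
    trace: IBITrace, rng: np.random.Generator, indices: tuple[int, int] | None = None
):
    """Replace IBIs strictly between two random anchors with a linear ramp.

    Anchors i < j are uniform over pairs with j - i >= 2; the fill is
    real-valued so successive differences are exactly equal.  Returns
    ``(modified copy, (i, j))``.
    """
    n = trace.n_beats
    if n < 4:
        raise SpecError("stair injection needs at least 4 beats")
    if indices is None:
        while True:
            i, j = sorted(int(v) for v in rng.integers(0, n, size=2))
            if j - i >= 2:
                break
    else:
        i, j = indices
        if not (0 <= i < j < n and j - i >= 2):
            raise SpecError("need 0 <= i < j < n with j - i >= 2")
    out = trace.copy()
    out.ibi_ms[i : j + 1] = np.linspace(out.ibi_ms[i], out.ibi_ms[j], j - i + 1)
    return out, (i, j)


# -- contamination measurement ---------------------------------------------

def flat_diff_fraction(ibis: np.ndarray) -> float:
    """Fraction of successive differences that are exactly zero."""
    d = np.diff(ibis)
    return float((d == 0).sum() / d.size)


def stair_diff_coverage(ibis: np.ndarray, tol: float = 1e-6) -> float:
    """Fraction of successive differences inside stair runs.

    A difference is covered when it belongs to a chain of >= 3 consecutive
    equal (within ``tol``) non-zero differences.
    """
    d = np.diff(ibis)
    m = d.size
    if m == 0:
        return 0.0
    nz = np.abs(d) > tol
    link = nz[1:] & nz[:-1] & (np.abs(np.diff(d)) <= tol)
    # maximal chains of c linked pairs span c+1 diffs; covered when c >= 2
    padded = np.concatenate([[False], link, [False]])
    edges = np.diff(padded.astype(np.int8))
    chain_len = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
    covered = int(np.sum(chain_len[chain_len >= 2] + 1))
    return covered / m


# -- Monte-Carlo study ------------------------------------------------------

@dataclass(frozen=True)
class InjectionCurve:
    """Binned rMSSD-vs-contamination summary over Monte-Carlo runs.

    ``bin_upper`` are the right edges of left-open bins covering (0, 1];
    ``full_contamination_rmssd_ms`` is the mean rMSSD of the fully
    contaminated terminal states (exactly proportion 1.0).
    """

    kind: str
    bin_upper: np.ndarray
    mean_rmssd_ms: np.ndarray
    band_lo_ms: np.ndarray
    band_hi_ms: np.ndarray
    n_samples: np.ndarray
    base_rmssd_ms: float
    full_contamination_rmssd_ms: float
    n_runs: int
    seed: int

    def value_at(self, proportion: float) -> float:
        """Binned mean rMSSD at the bin containing ``proportion``."""
        nb = self.bin_upper.size
        b = min(nb - 1, max(0, int(np.ceil(proportion * nb)) - 1))
        if self.n_samples[b] == 0:
            raise ValueError(f"no samples in the bin containing {proportion}")
        return float(self.mean_rmssd_ms[b])


@njit(cache=True)
def _flats_kernel(x, seed, n_bins, bin_count, bin_sum, reservoir, res_count, max_steps):
    """One flats run: inject until the trace is fully flat, recording each
    step's (zero-difference fraction, rMSSD) into the shared bin
    accumulators.  Integer-valued IBIs keep the running sum of squared
    differences exact, so full flatness is detected as ss == 0.
    """
    np.random.seed(seed)
    n = x.size
    ss = 0.0
    eqc = 0
    for j in range(n - 1):
        d = x[j + 1] - x[j]
        ss += d * d
        if d == 0.0:
            eqc += 1
    steps = 0
    res_k = reservoir.shape[1]
    while eqc < n - 1 and steps < max_steps:
        i = np.random.randint(0, n - 1)
        old = x[i + 1]
        new = x[i]
        if old != new:
            d0 = old - new
            ss -= d0 * d0
            eqc += 1
            if i + 2 < n:
                nxt = x[i + 2]
                d1_old = nxt - old
                d1_new = nxt - new
                ss += d1_new * d1_new - d1_old * d1_old
                if d1_old == 0.0:
                    eqc -= 1
                if d1_new == 0.0:
                    eqc += 1
            x[i + 1] = new
        steps += 1
        p = eqc / (n - 1)
        r = np.sqrt(ss / (n - 1)) if ss > 0.0 else 0.0
        if p > 0.0:
            b = int(np.ceil(p * n_bins)) - 1
            if b >= n_bins:
                b = n_bins - 1
            bin_count[b] += 1
            bin_sum[b] += r
            if res_count[b] < res_k:
                reservoir[b, res_count[b]] = r
                res_count[b] += 1
    return np.sqrt(ss / (n - 1)) if ss > 0.0 else 0.0


def run_injection_study(
    trace: IBITrace,
    kind: str,
    n_runs: int = 1000,
    seed: int = 0,
    bin_width: float = 0.01,
    max_steps: int | None = None,
    stair_schedule: str = "single",
) -> InjectionCurve:
    """Monte-Carlo injection study on a clean trace.

    ``trace`` must carry no corrected/flat/stair flags (a 'perfect' trace).
    Flat runs start from a fresh copy and inject steps until the trace is
    fully flat, recording contamination and rMSSD after every step.  Stair
    runs by default place a single random block on a fresh copy per run
    (``stair_schedule="single"``), so block extents span the whole
    contamination range across runs; ``stair_schedule="cumulative"``
    instead accumulates blocks within each run (recording after each)
    until every difference is ramp-covered or ``max_steps`` blocks.
    Deterministic given ``seed``.
    """
    if kind not in ("flat", "stair"):
        raise SpecError("kind must be 'flat' or 'stair'")
    if trace.corrected.any() or trace.flat.any() or trace.stair.any():
        raise SpecError("injection study requires a trace with zero corrected/flat/stair flags")
    n = trace.n_beats
    if n < 4:
        raise SpecError("trace too short for the injection study")
    if not (0 < bin_width <= 1):
        raise SpecError("bin_width must be in (0, 1]")

    n_bins = int(round(1.0 / bin_width))
    bin_count = np.zeros(n_bins, dtype=np.int64)
    bin_sum = np.zeros(n_bins)
    reservoir = np.zeros((n_bins, _RESERVOIR_K))
    res_count = np.zeros(n_bins, dtype=np.int64)

    base = float(np.sqrt(np.mean(np.diff(trace.ibi_ms) ** 2)))
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    finals = []

    if kind == "flat":
        cap = max_steps if max_steps is not None else 3 * (n - 1) ** 2
        for r in range(n_runs):
            x = trace.ibi_ms.astype(np.float64).copy()
            final = _flats_kernel(
                x, int(run_seeds[r]), n_bins, bin_count, bin_sum, reservoir, res_count, cap
            )
            finals.append(final)
    elif stair_schedule == "single":
        for r in range(n_runs):
            rng = np.random.default_rng(int(run_seeds[r]))
            x = trace.ibi_ms.astype(np.float64).copy()
            while True:
                i, j = sorted(int(v) for v in rng.integers(0, n, size=2))
                if j - i >= 2:
                    break
            x[i : j + 1] = np.linspace(x[i], x[j], j - i + 1)
            p = stair_diff_coverage(x)
            rms = float(np.sqrt(np.mean(np.diff(x) ** 2)))
            if p > 0.0:
                b = min(n_bins - 1, int(np.ceil(p * n_bins)) - 1)
                bin_count[b] += 1
                bin_sum[b] += rms
                if res_count[b] < _RESERVOIR_K:
                    reservoir[b, res_count[b]] = rms
                    res_count[b] += 1
        # the fully contaminated endpoint: one ramp spanning the whole trace
        x = trace.ibi_ms.astype(np.float64).copy()
        x[:] = np.linspace(x[0], x[-1], n)
        finals.append(float(np.sqrt(np.mean(np.diff(x) ** 2))))
        b = n_bins - 1
        bin_count[b] += 1
        bin_sum[b] += finals[-1]
        if res_count[b] < _RESERVOIR_K:
            reservoir[b, res_count[b]] = finals[-1]
            res_count[b] += 1
    elif stair_schedule == "cumulative":
        cap = max_steps if max_steps is not None else 2000
        for r in range(n_runs):
            rng = np.random.default_rng(int(run_seeds[r]))
            x = trace.ibi_ms.astype(np.float64).copy()
            blocks = 0
            p = 0.0
            while p < 1.0 and blocks < cap:
                while True:
                    i, j = sorted(int(v) for v in rng.integers(0, n, size=2))
                    if j - i >= 2:
                        break
                x[i : j + 1] = np.linspace(x[i], x[j], j - i + 1)
                blocks += 1
                p = stair_diff_coverage(x)
                rms = float(np.sqrt(np.mean(np.diff(x) ** 2)))
                if p > 0.0:
                    b = min(n_bins - 1, int(np.ceil(p * n_bins)) - 1)
                    bin_count[b] += 1
                    bin_sum[b] += rms
                    if res_count[b] < _RESERVOIR_K:
                        reservoir[b, res_count[b]] = rms
                        res_count[b] += 1
            if p >= 1.0:
                finals.append(float(np.sqrt(np.mean(np.diff(x) ** 2))))
    else:
        raise SpecError("stair_schedule must be 'single' or 'cumulative'")

    mean = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    nonzero = bin_count > 0
    mean[nonzero] = bin_sum[nonzero] / bin_count[nonzero]
    for b in np.flatnonzero(res_count):
        vals = reservoir[b, : res_count[b]]
        lo[b], hi[b] = np.percentile(vals, [2.5, 97.5])
    return InjectionCurve(
        kind=kind,
        bin_upper=(np.arange(1, n_bins + 1) * (1.0 / n_bins)),
        mean_rmssd_ms=mean, band_lo_ms=lo, band_hi_ms=hi,
        n_samples=bin_count,
        base_rmssd_ms=base,
        full_contamination_rmssd_ms=float(np.mean(finals)) if finals else float("nan"),
        n_runs=n_runs, seed=seed,
    )
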