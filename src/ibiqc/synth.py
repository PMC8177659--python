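"""Synthetic seal-like IBI traces, corruption processes and activity series.

Clean traces are an AR(1) Gaussian IBI process plus an optional sinusoidal
respiratory-sinus-arrhythmia (RSA) component around a constant mean.  The
AR(1) innovation variance is chosen in closed form so that the process
rMSSD — sqrt(2 * var(X) * (1 - phi)) for lag-1 coefficient phi — hits the
requested target when the RSA amplitude is zero.  IBIs are rounded to
integer milliseconds (the device reports ms precision) and clipped below at
300 ms.

Corruption emulates the three field error processes: missed beats (an IBI
merges into its successor), spurious beats (an IBI splits in two) and
transmission-dropout bursts (a block of beats vanishes, leaving one long
IBI spanning the gap — the input that forces multi-beat interpolation
downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .trace import ActivitySeries, IBITrace

MIN_IBI_MS = 300.0  # clip floor for generated IBIs (200 bpm ceiling)


@dataclass(frozen=True)
class CleanTraceSpec:
    """Parameters of the clean AR(1)+RSA IBI generator.

    Defaults emulate a resting grey seal: mean IBI 1000 ms (60 bpm, inside
    the observed 41-124 bpm field range) and target rMSSD 90 ms (inside the
    69-108 ms range of the exemplar resting traces).
    """

    duration_s: float = 300.0
    mean_ibi_ms: float = 1000.0
    target_rmssd_ms: float = 90.0
    ar_coefficient: float = 0.5
    rsa_amplitude_ms: float = 0.0
    rsa_period_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise SpecError("duration_s must be positive")
        if self.mean_ibi_ms <= 0:
            raise SpecError("mean_ibi_ms must be positive")
        if self.target_rmssd_ms < 0:
            raise SpecError("target_rmssd_ms must be non-negative")
        if not (0 <= self.ar_coefficient < 1):
            raise SpecError("ar_coefficient must be in [0, 1)")
        if self.rsa_amplitude_ms < 0:
            raise SpecError("rsa_amplitude_ms must be non-negative")
        if self.rsa_period_s <= 0:
            raise SpecError("rsa_period_s must be positive")


@dataclass(frozen=True)
class CorruptionSpec:
    """Rates of the emulated field error processes."""

    p_missed_beat: float = 0.0
    p_spurious_beat: float = 0.0
    dropout_rate_per_min: float = 0.0
    dropout_mean_s: float = 5.0
    jitter_sd_ms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("p_missed_beat", "p_spurious_beat"):
            p = getattr(self, name)
            if not (0 <= p < 1):
                raise SpecError(f"{name} must be in [0, 1)")
        if self.dropout_rate_per_min < 0 or self.dropout_mean_s <= 0:
            raise SpecError("dropout rate must be >= 0 and mean burst length > 0")
        if self.jitter_sd_ms < 0:
            raise SpecError("jitter_sd_ms must be non-negative")


def _innovation_sd(spec: CleanTraceSpec) -> float:
    """Innovation SD giving the target rMSSD for the AR(1) component.

    rMSSD of a stationary AR(1) is sqrt(2 * sigma_x^2 * (1 - phi)) with
    sigma_x^2 = sigma_eps^2 / (1 - phi^2); invert for sigma_eps.
    """
    phi = spec.ar_coefficient
    var_x = spec.target_rmssd_ms**2 / (2.0 * (1.0 - phi))
    var_eps = var_x * (1.0 - phi**2)
    if var_eps < 0 or not np.isfinite(var_eps):
        raise SpecError("parameters imply a non-positive innovation variance")
    return float(np.sqrt(var_eps))


def generate_clean_trace(spec: CleanTraceSpec) -> IBITrace:
    """Generate a clean (flag-free) trace covering ``spec.duration_s``."""
    rng = np.random.default_rng(spec.seed)
    phi = spec.ar_coefficient
    sd_eps = _innovation_sd(spec) if spec.target_rmssd_ms > 0 else 0.0

    # enough beats to cover the duration even after downward noise; trimmed below
    n_guess = int(np.ceil(spec.duration_s * 1000.0 / spec.mean_ibi_ms * 1.25)) + 50

    ibis: list[float] = []
    x = 0.0
    if sd_eps > 0 and phi > 0:
        # start the AR state at stationarity so early beats are not atypical
        x = rng.normal(0.0, sd_eps / np.sqrt(1.0 - phi**2))
    t_ms = 0.0
    target_ms = spec.duration_s * 1000.0
    eps = rng.normal(0.0, sd_eps, size=n_guess) if sd_eps > 0 else np.zeros(n_guess)
    i = 0
    while t_ms < target_ms:
        if i >= eps.size:
            extra = rng.normal(0.0, sd_eps, size=n_guess) if sd_eps > 0 else np.zeros(n_guess)
            eps = np.concatenate([eps, extra])
        x = phi * x + eps[i]
        rsa = 0.0
        if spec.rsa_amplitude_ms > 0:
            rsa = spec.rsa_amplitude_ms * np.sin(2.0 * np.pi * (t_ms / 1000.0) / spec.rsa_period_s)
        ibi = max(MIN_IBI_MS, round(spec.mean_ibi_ms + rsa + x))
        ibis.append(ibi)
        t_ms += ibi
        i += 1
    return IBITrace(ibi_ms=np.array(ibis, dtype=float))


# -- corruption ------------------------------------------------------------

GENUINE, MERGED, SPLIT, GAP = "genuine", "merged", "split", "gap"


def corrupt_trace(trace: IBITrace, spec: CorruptionSpec) -> tuple[IBITrace, np.ndarray]:
    """Apply missed-beat, spurious-beat and dropout corruption.

    Returns the corrupted device stream and a per-output-beat provenance
    array with entries in {genuine, merged, split, gap}.  Elapsed time is
    conserved: merges, splits and gaps all preserve the summed duration
    (integer-ms rounding keeps each split within 1 ms of the original).
    """
    if trace.corrected.any() or trace.flat.any() or trace.stair.any() or trace.out_of_bounds.any():
        raise SpecError("corrupt_trace expects a clean (flag-free) trace")
    rng = np.random.default_rng(spec.seed)
    ibis = trace.ibi_ms.copy()
    origins = np.full(ibis.size, GENUINE, dtype="U8")

    # 1. dropout bursts: Poisson arrivals in time, exponential lengths.
    #    All beats whose R peak falls inside a burst are deleted; the receiver
    #    sees one long IBI from the last beat before the burst to the first
    #    beat after it.
    duration_s = trace.duration_s
    n_bursts = rng.poisson(spec.dropout_rate_per_min * duration_s / 60.0)
    if n_bursts > 0:
        starts = np.sort(rng.uniform(0.0, duration_s, size=n_bursts))
        lengths = rng.exponential(spec.dropout_mean_s, size=n_bursts)
        keep = np.ones(ibis.size, dtype=bool)
        absorb_into = {}  # index of surviving beat -> extra ms absorbed
        times = np.cumsum(ibis) / 1000.0
        for s0, L in zip(starts, lengths):
            inside = np.flatnonzero(keep & (times >= s0) & (times < s0 + L))
            # never delete the final beat: a trailing gap has no closing beat
            inside = inside[inside < ibis.size - 1]
            if inside.size == 0:
                continue
            keep[inside] = False
            lost = ibis[inside].sum()
            # find the first kept beat after the burst to absorb the gap
            after = inside[-1] + 1
            while after < ibis.size and not keep[after]:
                after += 1
            if after < ibis.size:
                absorb_into[after] = absorb_into.get(after, 0.0) + lost
            else:  # pragma: no cover - guarded by the final-beat exclusion
                keep[inside] = True
        for idx, extra in absorb_into.items():
            ibis[idx] += extra
            origins[idx] = GAP
        ibis = ibis[keep]
        origins = origins[keep]

    # 2. missed beats: beat k undetected, its IBI merges into beat k+1.
    if spec.p_missed_beat > 0 and ibis.size >= 2:
        miss = rng.random(ibis.size) < spec.p_missed_beat
        miss[-1] = False  # the last IBI has no successor to merge into
        out_ibis, out_orig = [], []
        carry = 0.0
        for k in range(ibis.size):
            if miss[k] and origins[k] == GENUINE:
                carry += ibis[k]
            else:
                if carry > 0:
                    out_ibis.append(ibis[k] + carry)
                    out_orig.append(MERGED if origins[k] == GENUINE else origins[k])
                    carry = 0.0
                else:
                    out_ibis.append(ibis[k])
                    out_orig.append(origins[k])
        ibis = np.array(out_ibis)
        origins = np.array(out_orig, dtype="U8")

    # 3. spurious beats: an extra detection splits an IBI at u in (0.2, 0.8).
    if spec.p_spurious_beat > 0 and ibis.size:
        split = (rng.random(ibis.size) < spec.p_spurious_beat) & (origins == GENUINE)
        fracs = rng.uniform(0.2, 0.8, size=ibis.size)
        out_ibis, out_orig = [], []
        for k in range(ibis.size):
            if split[k]:
                a = round(ibis[k] * fracs[k])
                a = min(max(a, 1.0), ibis[k] - 1.0)
                out_ibis.extend([a, ibis[k] - a])
                out_orig.extend([SPLIT, SPLIT])
            else:
                out_ibis.append(ibis[k])
                out_orig.append(origins[k])
        ibis = np.array(out_ibis)
        origins = np.array(out_orig, dtype="U8")

    device = IBITrace(
        ibi_ms=np.round(ibis),
        individual_id=trace.individual_id, tag_id=trace.tag_id,
        session_start=trace.session_start, covariates=dict(trace.covariates),
    )
    return device, origins


def generate_reference_pair(
    trace: IBITrace, jitter_sd_ms: float, seed: int, bias_ms: float = 0.0
) -> IBITrace:
    """Emulate an independently measured reference stream (e.g. digitised ECG).

    Each beat time is perturbed by independent Gaussian noise of SD
    ``jitter_sd_ms``; IBIs are recomputed from the perturbed times, then
    shifted by a constant ``bias_ms``.  Because consecutive IBIs share a
    perturbed endpoint, each paired IBI difference has SD sqrt(2) * jitter.
    """
    if jitter_sd_ms < 0:
        raise SpecError("jitter_sd_ms must be non-negative")
    rng = np.random.default_rng(seed)
    times_ms = np.cumsum(trace.ibi_ms)
    perturbed = times_ms + rng.normal(0.0, jitter_sd_ms, size=times_ms.size)
    ref_ibis = np.diff(np.concatenate([[0.0], perturbed])) + bias_ms
    if np.any(ref_ibis <= 0):
        ref_ibis = np.maximum(ref_ibis, 1.0)
    return IBITrace(
        ibi_ms=ref_ibis,
        individual_id=trace.individual_id, tag_id=trace.tag_id,
        session_start=trace.session_start, covariates=dict(trace.covariates),
    )


def generate_activity(
    duration_s: float, bout_mean_s: float, p_active: float, seed: int
) -> ActivitySeries:
    """Alternating exponential Active/Inactive bouts, one label per second.

    ``bout_mean_s`` is the mean Inactive bout length; the Active bout mean is
    scaled so the long-run Active fraction is ``p_active``.
    """
    if not (0 <= p_active <= 1):
        raise SpecError("p_active must be in [0, 1]")
    if duration_s <= 0 or bout_mean_s <= 0:
        raise SpecError("duration_s and bout_mean_s must be positive")
    n_sec = int(np.ceil(duration_s))
    seconds = np.arange(n_sec, dtype=np.int64)
    if p_active == 0.0:
        return ActivitySeries(seconds, np.full(n_sec, "Inactive", dtype="U8"))
    if p_active == 1.0:
        return ActivitySeries(seconds, np.full(n_sec, "Active", dtype="U8"))
    rng = np.random.default_rng(seed)
    mean_inactive = bout_mean_s
    mean_active = bout_mean_s * p_active / (1.0 - p_active)
    labels = np.empty(n_sec, dtype="U8")
    # start state drawn from the stationary fraction
    active = rng.random() < p_active
    t = 0
    while t < n_sec:
        mean = mean_active if active else mean_inactive
        length = max(1, int(np.ceil(rng.exponential(mean))))
        labels[t : t + length] = "Active" if active else "Inactive"
        t += length
        active = not active
    return ActivitySeries(seconds, labels)
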