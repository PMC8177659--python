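"""Device-style artefact correction for raw IBI streams.

Emulates the default behaviour of commercial heart-rate-belt software:
detect extreme IBIs against a running local median, delete spurious extra
beats (runs of extreme-short IBIs merged back into one beat) and
interpolate for missing beats (an extreme-long IBI replaced by several
derived beats).  Every replaced or derived IBI carries ``corrected=True``.

Multi-beat interpolation is what manufactures the downstream artefact
classes: a gap between two *equal* anchor IBIs is filled with a constant
value (a flat), a gap between *differing* anchors with a linear ramp (a
stair).  Fill values are integer milliseconds; any duration residual is
assigned to the final fill beat so total elapsed time is conserved exactly
while the leading fill beats keep an exactly constant value or step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .trace import IBITrace


@dataclass(frozen=True)
class CorrectionConfig:
    """Tuning of the extreme-IBI detector and the repair rules.

    An IBI is *extreme* when it deviates from the running median of
    ``local_window_beats`` raw IBIs by more than ``deviation_threshold``
    times that median (a Kubios-style "strong" threshold by default), or
    when it breaches the absolute ``hard_min_ms``/``hard_max_ms`` backstop.
    """

    local_window_beats: int = 7
    deviation_threshold: float = 0.25
    max_merge_span: int = 3
    hard_min_ms: float = 300.0
    hard_max_ms: float = 3000.0

    def __post_init__(self):
        if self.local_window_beats < 5 or self.local_window_beats % 2 == 0:
            raise SpecError("local_window_beats must be an odd integer >= 5")
        if not (0 < self.deviation_threshold < 1):
            raise SpecError("deviation_threshold must be in (0, 1)")
        if self.max_merge_span < 2:
            raise SpecError("max_merge_span must be >= 2")
        if not (0 < self.hard_min_ms < self.hard_max_ms):
            raise SpecError("hard_min_ms must be positive and below hard_max_ms")


@dataclass
class CorrectionEvent:
    """One logged repair: where it happened and what changed."""

    kind: str          # "merge" or "interpolate"
    raw_index: int     # first raw beat index involved
    before: list = field(default_factory=list)
    after: list = field(default_factory=list)


def _running_median(ibis: np.ndarray, window: int) -> np.ndarray:
    """Centred running median; edges use the nearest full window."""
    n = ibis.size
    half = window // 2
    med = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        hi = min(n, lo + window)
        med[i] = np.median(ibis[lo:hi])
    return med


def correct_artefacts(
    raw: IBITrace, config: CorrectionConfig | None = None
) -> tuple[IBITrace, list[CorrectionEvent]]:
    """Correct extreme IBIs, flagging every replaced/derived beat.

    Returns the corrected trace and the list of correction events.  A trace
    shorter than the detector window is returned untouched with a warning
    recorded in ``trace.warnings``.
    """
    if config is None:
        config = CorrectionConfig()
    if raw.corrected.any():
        raise SpecError("correct_artefacts expects a trace with no corrected flags")
    if raw.n_beats < config.local_window_beats:
        out = raw.copy()
        out.warnings.append("trace shorter than detector window; correction skipped")
        return out, []

    ibis = raw.ibi_ms
    med = _running_median(ibis, config.local_window_beats)
    dev = np.abs(ibis - med)
    extreme = dev > config.deviation_threshold * med
    extreme |= (ibis < config.hard_min_ms) | (ibis > config.hard_max_ms)
    short = extreme & (ibis < med)
    long_ = extreme & (ibis >= med)

    out_ibis: list[float] = []
    out_corr: list[bool] = []
    events: list[CorrectionEvent] = []
    n = ibis.size
    i = 0
    while i < n:
        if short[i]:
            # candidate spurious-beat run: consecutive extreme-shorts whose
            # sum restores a plausible single IBI
            j = i
            while j < n and short[j] and (j - i + 1) <= config.max_merge_span:
                j += 1
            run_sum = float(ibis[i:j].sum())
            if j - i >= 2 and abs(run_sum - med[i]) <= config.deviation_threshold * med[i]:
                out_ibis.append(run_sum)
                out_corr.append(True)
                events.append(
                    CorrectionEvent("merge", i, list(ibis[i:j]), [run_sum])
                )
                i = j
                continue
            # uncorrectable lone short: pass through unchanged
            out_ibis.append(float(ibis[i]))
            out_corr.append(False)
            i += 1
        elif long_[i]:
            fill = _interpolate_gap(ibis, i, med[i], config)
            if fill is None:
                # implied beat count is 1: nothing physical to derive, flag only
                out_ibis.append(float(ibis[i]))
                out_corr.append(True)
                events.append(CorrectionEvent("interpolate", i, [float(ibis[i])], [float(ibis[i])]))
            else:
                out_ibis.extend(fill)
                out_corr.extend([True] * len(fill))
                events.append(CorrectionEvent("interpolate", i, [float(ibis[i])], list(fill)))
            i += 1
        else:
            out_ibis.append(float(ibis[i]))
            out_corr.append(False)
            i += 1

    corrected = IBITrace(
        ibi_ms=np.array(out_ibis),
        corrected=np.array(out_corr, dtype=bool),
        individual_id=raw.individual_id, tag_id=raw.tag_id,
        session_start=raw.session_start, covariates=dict(raw.covariates),
    )
    return corrected, events


def _interpolate_gap(
    ibis: np.ndarray, i: int, local_med: float, config: CorrectionConfig
) -> list[float] | None:
    """Replacement beats for the extreme-long IBI at index ``i``.

    The gap duration D is divided into ``m = round(D / local median)`` beats
    (round half to even).  Values run linearly from the preceding valid IBI
    to the following valid IBI — constant when the anchors are equal.  The
    integer-ms residual lands on the last fill beat so duration is exact.
    Returns None when m <= 1 (no missing beat implied).
    """
    D = float(ibis[i])
    m = int(np.round(D / local_med))  # numpy rounds half to even
    if m <= 1:
        return None
    a = float(ibis[i - 1]) if i > 0 else local_med
    b = float(ibis[i + 1]) if i < ibis.size - 1 else local_med
    if a == b:
        q = float(np.round(D / m))
        fill = [q] * m
    else:
        step = float(np.round((b - a) / (m + 1)))
        fill = [a + step * (k + 1) for k in range(m)]
    residual = D - sum(fill)
    fill[-1] += residual
    if fill[-1] <= 0:  # degenerate ramp overshoot; fall back to a flat fill
        q = float(np.round(D / m))
        fill = [q] * m
        fill[-1] += D - sum(fill)
    return fill
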