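"""Windowing, activity matching, per-window summaries and retention filters.

Annotated traces are segmented into sequential fixed-length clock windows
(5 minutes by default).  Each window summarises its error burden (flats,
stairs, corrected artefacts, out-of-bounds beats), activity (percent of
beats time-matched to an Active second) and heart rate, and inherits the
trace covariates used for downstream determinant modelling.  A retention
policy then selects windows eligible for resting-HRV estimation — by
default at most 5% flats-or-stairs beats and no Active beats.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .hrv import rmssd
from .trace import ActivitySeries, IBITrace


@dataclass
class TraceWindow:
    """Summary of one fixed-length window of an annotated trace."""

    window_index: int
    start_s: float
    end_s: float
    n_beats: int
    n_flats: int = 0
    n_stairs: int = 0
    n_corrected: int = 0
    n_out_of_bounds: int = 0
    pct_flats_stairs: float = 0.0
    pct_artefact: float = 0.0
    pct_active: float | None = None
    mean_hr_bpm: float = float("nan")
    rmssd_ms: float | None = None
    individual_id: str = ""
    tag_id: str = ""
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RetentionPolicy:
    """Thresholds a window must pass to be retained for resting HRV.

    ``max_pct_flats_stairs`` defaults to 5 ("up to 5% flats or stairs");
    ``max_pct_active`` defaults to 0 (resting windows only).  ``None``
    disables a criterion.  Boundaries are inclusive.
    """

    max_pct_flats_stairs: float | None = 5.0
    max_pct_active: float | None = 0.0
    max_pct_artefact: float | None = None
    min_beats: int = 0

    def __post_init__(self):
        for name in ("max_pct_flats_stairs", "max_pct_active", "max_pct_artefact"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise SpecError(f"{name} must be in [0, 100]")
        if self.min_beats < 0:
            raise SpecError("min_beats must be non-negative")


def match_activity(trace: IBITrace, activity: ActivitySeries) -> IBITrace:
    """Label each beat with the activity state of the second containing it.

    Seconds absent from the series map to ``Unknown``.
    """
    out = trace.copy()
    seconds = np.floor(out.beat_time_s).astype(np.int64)
    out.activity = activity.label_at(seconds)
    return out


def segment_windows(trace: IBITrace, window_s: float = 300.0) -> list[TraceWindow]:
    """Split a trace into consecutive half-open windows [k*w, (k+1)*w).

    A beat belongs to the window containing its beat time.  The trailing
    partial window is discarded, as are windows with zero beats.  Windows
    are summarised via :func:`summarize_window`.
    """
    if window_s <= 0:
        raise SpecError("window_s must be positive")
    times = trace.beat_time_s
    duration = trace.duration_s
    n_windows = int(np.floor(duration / window_s))
    windows = []
    for k in range(n_windows):
        lo, hi = k * window_s, (k + 1) * window_s
        mask = (times >= lo) & (times < hi)
        if not mask.any():
            continue
        windows.append(summarize_window(trace, mask, k, lo, hi))
    return windows


def summarize_window(
    trace: IBITrace, mask: np.ndarray, window_index: int, start_s: float, end_s: float
) -> TraceWindow:
    """Flag tallies, activity percentage, mean HR and rMSSD for one window.

    ``Unknown`` activity labels are excluded from the pct_active
    denominator; if every label is Unknown the percentage is absent.
    rMSSD excludes out-of-bounds beats (chain-split) and is absent when
    fewer than two usable beats remain.
    """
    n = int(mask.sum())
    if n == 0:
        raise SpecError("summarize_window requires a non-empty window")
    ibis = trace.ibi_ms[mask]
    flat = trace.flat[mask]
    stair = trace.stair[mask]
    corrected = trace.corrected[mask]
    oob = trace.out_of_bounds[mask]
    activity = trace.activity[mask]

    known = activity != "Unknown"
    pct_active = None
    if known.any():
        pct_active = 100.0 * float((activity[known] == "Active").sum()) / float(known.sum())

    try:
        r = rmssd(ibis, exclude=oob)
    except Exception:
        r = None

    cov = dict(trace.covariates)
    if "time_of_day" in cov:
        # advance the trace-level time of day to the window start
        cov["time_of_day"] = (cov["time_of_day"] + start_s / 86400.0) % 1.0

    return TraceWindow(
        window_index=window_index, start_s=start_s, end_s=end_s, n_beats=n,
        n_flats=int(flat.sum()), n_stairs=int(stair.sum()),
        n_corrected=int(corrected.sum()), n_out_of_bounds=int(oob.sum()),
        pct_flats_stairs=100.0 * float((flat | stair).sum()) / n,
        pct_artefact=100.0 * float(corrected.sum()) / n,
        pct_active=pct_active,
        mean_hr_bpm=60000.0 / float(np.mean(ibis)),
        rmssd_ms=None if r is None else float(r),
        individual_id=trace.individual_id, tag_id=trace.tag_id,
        covariates=cov,
    )


def filter_windows(
    windows: list[TraceWindow], policy: RetentionPolicy | None = None
) -> tuple[list[TraceWindow], list[tuple[TraceWindow, str]]]:
    """Partition windows into (retained, rejected-with-first-failed-reason)."""
    if policy is None:
        policy = RetentionPolicy()
    retained, rejected = [], []
    for w in windows:
        reason = _rejection_reason(w, policy)
        if reason is None:
            retained.append(w)
        else:
            rejected.append((w, reason))
    return retained, rejected


def _rejection_reason(w: TraceWindow, policy: RetentionPolicy) -> str | None:
    if w.n_beats < policy.min_beats:
        return "min_beats"
    if (
        policy.max_pct_flats_stairs is not None
        and w.pct_flats_stairs > policy.max_pct_flats_stairs
    ):
        return "flats_stairs"
    if (
        policy.max_pct_active is not None
        and w.pct_active is not None
        and w.pct_active > policy.max_pct_active
    ):
        return "activity"
    if policy.max_pct_artefact is not None and w.pct_artefact > policy.max_pct_artefact:
        return "artefact"
    return None


COVARIATE_COLUMNS = [
    "individual_id", "tag_id", "window_index", "start_s", "end_s", "n_beats",
    "n_flats", "n_stairs", "n_corrected", "n_out_of_bounds",
    "pct_flats_stairs", "pct_artefact", "pct_active",
    "mean_hr_bpm", "rmssd_ms",
    "day_of_year", "time_of_day", "deploy_day", "mass_kg", "temperature_c",
]


def export_covariate_table(windows: list[TraceWindow], path) -> None:
    """Write one row per window: identity, error burden, HR/HRV, covariates.

    Column order is fixed (see ``COVARIATE_COLUMNS``); missing covariates
    and absent statistics are written as empty fields.  This is the input
    table for external determinant modelling.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COVARIATE_COLUMNS)
        for w in windows:
            row = []
            for col in COVARIATE_COLUMNS:
                if col in ("individual_id", "tag_id"):
                    row.append(getattr(w, col))
                elif col in w.covariates:
                    row.append(repr(w.covariates[col]) if col != "day_of_year"
                               else str(w.covariates[col]))
                elif hasattr(w, col):
                    v = getattr(w, col)
                    row.append("" if v is None else repr(v) if isinstance(v, float) else str(v))
                else:
                    row.append("")
            writer.writerow(row)
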