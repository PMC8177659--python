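"""Flats/stairs detection and physiological heart-rate limits.

A *flat* is a maximal run of two or more consecutive identical IBI values;
a *stair* is a maximal run of more than two identical, non-zero successive
differences (so at least four beats by default).  Both are uncorrectable
interpolation artefacts: they are flagged, never altered.

Device IBIs are integer milliseconds so the default equality tolerance is
exact; a tolerance is available for real-valued synthetic sequences, where
"identical" is chained pairwise agreement within the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import IBITrace


@dataclass(frozen=True)
class RunAnnotation:
    """One maximal flat or stair run."""

    kind: str          # "flat" or "stair"
    start_index: int   # 0-based index of the first beat in the run
    length: int        # number of beats in the run
    step_ms: float     # 0 for flats; the common successive difference for stairs


def _equal_runs(values: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Maximal runs (start, length>=2) of chained pairwise-equal values."""
    n = values.size
    runs = []
    i = 0
    while i < n - 1:
        if abs(values[i + 1] - values[i]) <= tol:
            j = i + 1
            while j < n - 1 and abs(values[j + 1] - values[j]) <= tol:
                j += 1
            runs.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs


def detect_flats(
    trace: IBITrace, tolerance_ms: float = 0.0, flag_run_head: bool = True
) -> tuple[IBITrace, list[RunAnnotation]]:
    """Flag every maximal run of >=2 consecutive equal IBIs.

    All beats of a run are flagged (set ``flag_run_head=False`` to leave the
    first beat of each run unflagged).  Returns an annotated copy and the
    run table.
    """
    out = trace.copy()
    runs = []
    for start, length in _equal_runs(out.ibi_ms, tolerance_ms):
        runs.append(RunAnnotation("flat", start, length, 0.0))
        lo = start if flag_run_head else start + 1
        out.flat[lo : start + length] = True
    return out, runs


def detect_stairs(
    trace: IBITrace,
    tolerance_ms: float = 0.0,
    stair_min_diffs: int = 3,
    flag_run_head: bool = True,
) -> tuple[IBITrace, list[RunAnnotation]]:
    """Flag every maximal run of >= ``stair_min_diffs`` equal non-zero
    successive differences ("more than two" identical differences).

    A run of d differences spans d+1 beats; all of them are flagged.
    """
    out = trace.copy()
    diffs = np.diff(out.ibi_ms)
    n = diffs.size
    runs = []
    i = 0
    while i < n:
        if abs(diffs[i]) <= tolerance_ms:
            i += 1
            continue
        j = i
        while (
            j < n - 1
            and abs(diffs[j + 1]) > tolerance_ms
            and abs(diffs[j + 1] - diffs[j]) <= tolerance_ms
        ):
            j += 1
        n_diffs = j - i + 1
        if n_diffs >= stair_min_diffs:
            runs.append(RunAnnotation("stair", i, n_diffs + 1, float(np.mean(diffs[i : j + 1]))))
            lo = i if flag_run_head else i + 1
            out.stair[lo : i + n_diffs + 1] = True
        i = j + 1
    return out, runs


def apply_physiological_limits(
    trace: IBITrace, min_bpm: float = 20.0, max_bpm: float = 200.0
) -> IBITrace:
    """Flag beats outside the acceptable heart-rate band.

    Defaults span 20-200 bpm, i.e. IBIs outside (300 ms, 3000 ms) are
    flagged ``out_of_bounds``.
    """
    if not (0 < min_bpm < max_bpm):
        raise ValueError("need 0 < min_bpm < max_bpm")
    out = trace.copy()
    upper_ms = 60000.0 / min_bpm
    lower_ms = 60000.0 / max_bpm
    out.out_of_bounds = (out.ibi_ms > upper_ms) | (out.ibi_ms < lower_ms)
    return out


def annotate_trace(
    trace: IBITrace,
    tolerance_ms: float = 0.0,
    stair_min_diffs: int = 3,
    min_bpm: float = 20.0,
    max_bpm: float = 200.0,
) -> tuple[IBITrace, list[RunAnnotation]]:
    """Convenience: flats + stairs + physiological limits in one pass."""
    out, flat_runs = detect_flats(trace, tolerance_ms)
    out, stair_runs = detect_stairs(out, tolerance_ms, stair_min_diffs)
    out = apply_physiological_limits(out, min_bpm, max_bpm)
    return out, flat_runs + stair_runs
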