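"""Core beat/trace data model and tabular I/O.

An :class:`IBITrace` is an ordered series of heartbeats, each defined by its
inter-beat interval (IBI, the R-R interval in milliseconds) plus
quality-control flags.  Beat times are not stored: they are the cumulative
sum of the IBIs from session start, so the k-th beat falls at
``sum(ibi_ms[:k+1]) / 1000`` seconds.  The first beat's time equals its own
IBI — an IBI is the interval *ending* at its beat.

Flags carried per beat:

``corrected``
    the device software (or its emulator) judged this IBI extreme and
    replaced or derived it,
``flat`` / ``stair``
    the beat belongs to an uncorrectable interpolation artefact — a run of
    identical IBIs, or a run of identical non-zero successive differences,
``out_of_bounds``
    the IBI falls outside the physiologically acceptable heart-rate band.

Two text dialects are supported: a canonical comma-delimited beat-per-row
format with ``#key=value`` metadata comment lines, and the common bare
RR-export convention of one integer IBI (ms) per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from .errors import TraceParseError, TraceValidationError

ACTIVITY_LABELS = ("Inactive", "Active", "Unknown")

COVARIATE_KEYS = ("day_of_year", "time_of_day", "deploy_day", "mass_kg", "temperature_c")

_CANONICAL_HEADER = "beat_time_s,ibi_ms,corrected,flat,stair,out_of_bounds,activity"

_TIME_TOL_S = 1e-6  # beat times must equal the cumulative IBI sum within this


class AnnotatedBeat(NamedTuple):
    """A single heartbeat view: interval, time and QC flags."""

    beat_time: float
    ibi_ms: float
    corrected: bool
    flat: bool
    stair: bool
    out_of_bounds: bool
    activity: str


@dataclass
class IBITrace:
    """Ordered beat series with identity metadata; the unit of I/O.

    Parameters
    ----------
    ibi_ms
        Positive IBIs in milliseconds, in temporal order.  Device-native
        values are integer ms; synthetic traces may carry reals.
    corrected, flat, stair, out_of_bounds
        Per-beat boolean flags (default all ``False``).
    activity
        Per-beat behavioural label, one of ``Inactive``/``Active``/``Unknown``.
    """

    ibi_ms: np.ndarray
    corrected: np.ndarray = None
    flat: np.ndarray = None
    stair: np.ndarray = None
    out_of_bounds: np.ndarray = None
    activity: np.ndarray = None
    individual_id: str = ""
    tag_id: str = ""
    session_start: str | None = None
    covariates: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        n = self.ibi_ms.size
        for name in ("corrected", "flat", "stair", "out_of_bounds"):
            v = getattr(self, name)
            if v is None:
                v = np.zeros(n, dtype=bool)
            else:
                v = np.asarray(v, dtype=bool)
            setattr(self, name, v)
        if self.activity is None:
            self.activity = np.full(n, "Unknown", dtype="U8")
        else:
            self.activity = np.asarray(self.activity, dtype="U8")
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_beats(self) -> int:
        return int(self.ibi_ms.size)

    @property
    def beat_time_s(self) -> np.ndarray:
        """Beat times in seconds: cumulative IBI sum from session start."""
        return np.cumsum(self.ibi_ms) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.ibi_ms.sum() / 1000.0)

    def validate(self) -> None:
        n = self.n_beats
        if np.any(~np.isfinite(self.ibi_ms)) or np.any(self.ibi_ms <= 0):
            raise TraceValidationError("all IBIs must be finite and positive")
        for name in ("corrected", "flat", "stair", "out_of_bounds", "activity"):
            if getattr(self, name).size != n:
                raise TraceValidationError(f"{name} length != number of beats")
        bad = set(np.unique(self.activity)) - set(ACTIVITY_LABELS)
        if bad:
            raise TraceValidationError(f"unknown activity labels: {sorted(bad)}")

    def beats(self) -> Iterator[AnnotatedBeat]:
        times = self.beat_time_s
        for k in range(self.n_beats):
            yield AnnotatedBeat(
                float(times[k]), float(self.ibi_ms[k]),
                bool(self.corrected[k]), bool(self.flat[k]), bool(self.stair[k]),
                bool(self.out_of_bounds[k]), str(self.activity[k]),
            )

    def copy(self) -> "IBITrace":
        return replace(
            self,
            ibi_ms=self.ibi_ms.copy(), corrected=self.corrected.copy(),
            flat=self.flat.copy(), stair=self.stair.copy(),
            out_of_bounds=self.out_of_bounds.copy(), activity=self.activity.copy(),
            covariates=dict(self.covariates), warnings=list(self.warnings),
        )

    def equals(self, other: "IBITrace") -> bool:
        """Field-by-field equality (metadata and every per-beat column)."""
        return (
            np.array_equal(self.ibi_ms, other.ibi_ms)
            and np.array_equal(self.corrected, other.corrected)
            and np.array_equal(self.flat, other.flat)
            and np.array_equal(self.stair, other.stair)
            and np.array_equal(self.out_of_bounds, other.out_of_bounds)
            and np.array_equal(self.activity, other.activity)
            and self.individual_id == other.individual_id
            and self.tag_id == other.tag_id
            and self.session_start == other.session_start
            and self.covariates == other.covariates
        )


@dataclass
class ActivitySeries:
    """Per-second behavioural labels on the trace session clock."""

    seconds: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.seconds = np.asarray(self.seconds, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.seconds.size != self.labels.size:
            raise TraceValidationError("seconds and labels must have equal length")
        if self.seconds.size:
            if np.any(self.seconds < 0):
                raise TraceValidationError("second indices must be non-negative")
            if np.any(np.diff(self.seconds) <= 0):
                raise TraceValidationError("second indices must be strictly increasing")
        bad = set(np.unique(self.labels)) - {"Inactive", "Active"}
        if bad:
            raise TraceValidationError(f"activity labels must be Inactive/Active, got {sorted(bad)}")

    @property
    def n_seconds(self) -> int:
        return int(self.seconds.size)

    def label_at(self, seconds: np.ndarray) -> np.ndarray:
        """Label of each integer second; 'Unknown' where the series has a gap."""
        seconds = np.asarray(seconds, dtype=np.int64)
        out = np.full(seconds.shape, "Unknown", dtype="U8")
        if self.seconds.size:
            idx = np.searchsorted(self.seconds, seconds)
            idx = np.clip(idx, 0, self.seconds.size - 1)
            hit = self.seconds[idx] == seconds
            out[hit] = self.labels[idx[hit]]
        return out

    def equals(self, other: "ActivitySeries") -> bool:
        return np.array_equal(self.seconds, other.seconds) and np.array_equal(
            self.labels, other.labels
        )


# -- covariate (de)serialisation helpers ----------------------------------

def _format_covariate(key: str, value) -> str:
    if key == "day_of_year":
        return str(int(value))
    return repr(float(value))


def _parse_covariate(key: str, text: str):
    if key == "day_of_year":
        return int(text)
    return float(text)


# -- readers / writers -----------------------------------------------------

def read_trace(path, dialect: str = "canonical") -> IBITrace:
    """Read an IBI trace file.

    ``dialect="canonical"`` expects the package's comma-delimited beat-per-row
    format; ``dialect="rr"`` accepts bare one-IBI-per-line text (integer ms,
    the common RR-export convention) with no header and no flags.
    """
    if dialect not in ("canonical", "rr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if dialect == "rr":
        return _parse_rr(lines)
    return _parse_canonical(lines)


def _parse_rr(lines) -> IBITrace:
    ibis = []
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        try:
            v = float(s)
        except ValueError:
            raise TraceParseError(f"non-numeric IBI {s!r}", lineno) from None
        if v <= 0:
            raise TraceParseError(f"non-positive IBI {s!r}", lineno)
        ibis.append(v)
    return IBITrace(ibi_ms=np.array(ibis, dtype=float))


def _parse_canonical(lines) -> IBITrace:
    meta: dict = {}
    covariates: dict = {}
    rows = []
    row_linenos = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                if key in COVARIATE_KEYS:
                    try:
                        covariates[key] = _parse_covariate(key, val)
                    except ValueError:
                        raise TraceParseError(f"bad covariate {key}={val!r}", lineno) from None
                else:
                    meta[key] = val
            continue
        if not header_seen:
            if s != _CANONICAL_HEADER:
                raise TraceParseError(
                    f"expected header {_CANONICAL_HEADER!r}, got {s!r}", lineno
                )
            header_seen = True
            continue
        rows.append(s)
        row_linenos.append(lineno)
    if not header_seen:
        raise TraceParseError("missing canonical header line")

    n = len(rows)
    ibi = np.empty(n)
    times = np.empty(n)
    flags = {k: np.zeros(n, dtype=bool) for k in ("corrected", "flat", "stair", "out_of_bounds")}
    activity = np.full(n, "Unknown", dtype="U8")
    for i, (s, lineno) in enumerate(zip(rows, row_linenos)):
        parts = s.split(",")
        if len(parts) != 7:
            raise TraceParseError(f"expected 7 fields, got {len(parts)}", lineno)
        try:
            times[i] = float(parts[0])
            ibi[i] = float(parts[1])
        except ValueError:
            raise TraceParseError(f"non-numeric field in {s!r}", lineno) from None
        if ibi[i] <= 0:
            raise TraceParseError(f"non-positive IBI {parts[1]!r}", lineno)
        for j, key in enumerate(("corrected", "flat", "stair", "out_of_bounds"), start=2):
            if parts[j] not in ("0", "1"):
                raise TraceParseError(f"flag {key} must be 0/1, got {parts[j]!r}", lineno)
            flags[key][i] = parts[j] == "1"
        if parts[6] not in ACTIVITY_LABELS:
            raise TraceParseError(f"unknown activity label {parts[6]!r}", lineno)
        activity[i] = parts[6]

    if n and np.any(np.diff(times) <= 0):
        raise TraceValidationError("beat times are not strictly increasing")
    expected = np.cumsum(ibi) / 1000.0
    if n and np.max(np.abs(times - expected)) > _TIME_TOL_S:
        raise TraceValidationError(
            "beat times do not equal the cumulative IBI sum (tolerance 1e-6 s)"
        )
    return IBITrace(
        ibi_ms=ibi, activity=activity,
        individual_id=meta.get("individual_id", ""),
        tag_id=meta.get("tag_id", ""),
        session_start=meta.get("session_start"),
        covariates=covariates,
        **flags,
    )


def write_trace(trace: IBITrace, path) -> None:
    """Write a trace in the canonical dialect (re-readable by read_trace)."""
    trace.validate()
    lines = []
    if trace.individual_id:
        lines.append(f"#individual_id={trace.individual_id}")
    if trace.tag_id:
        lines.append(f"#tag_id={trace.tag_id}")
    if trace.session_start:
        lines.append(f"#session_start={trace.session_start}")
    for key in COVARIATE_KEYS:
        if key in trace.covariates:
            lines.append(f"#{key}={_format_covariate(key, trace.covariates[key])}")
    lines.append(_CANONICAL_HEADER)
    times = trace.beat_time_s
    for k in range(trace.n_beats):
        lines.append(
            f"{float(times[k])!r},{float(trace.ibi_ms[k])!r},"
            f"{int(trace.corrected[k])},{int(trace.flat[k])},{int(trace.stair[k])},"
            f"{int(trace.out_of_bounds[k])},{trace.activity[k]}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_activity(path) -> ActivitySeries:
    """Read a comma-delimited ``second,label`` activity file."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    seconds, labels = [], []
    seen = set()
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith("#") or s == "second,label":
            continue
        parts = s.split(",")
        if len(parts) != 2:
            raise TraceParseError(f"expected 'second,label', got {s!r}", lineno)
        try:
            sec = int(parts[0])
        except ValueError:
            raise TraceParseError(f"non-integer second {parts[0]!r}", lineno) from None
        if parts[1] not in ("Inactive", "Active"):
            raise TraceParseError(f"unknown activity label {parts[1]!r}", lineno)
        if sec in seen:
            raise TraceValidationError(f"duplicate second {sec} at line {lineno}")
        seen.add(sec)
        seconds.append(sec)
        labels.append(parts[1])
    order = np.argsort(seconds, kind="stable")
    return ActivitySeries(
        seconds=np.array(seconds, dtype=np.int64)[order],
        labels=np.array(labels, dtype="U8")[order],
    )


def write_activity(series: ActivitySeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("second,label\n")
        for sec, lab in zip(series.seconds, series.labels):
            fh.write(f"{sec},{lab}\n")
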