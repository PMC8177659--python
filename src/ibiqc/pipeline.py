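"""End-to-end orchestration: correct -> annotate -> window -> filter -> HRV.

The pipeline takes raw trace files (plus optional activity files), applies
the artefact-correction emulator, flags flats/stairs and out-of-bounds
beats, segments into 5-minute windows, filters by the retention policy and
reports per-window rMSSD plus pooled artefact-vs-flats/stairs
classification matrices.  Every correction event and window rejection is
written to an append-only QC log so filtering decisions stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotate import annotate_trace
from .correction import CorrectionConfig, correct_artefacts
from .hrv import ClassificationMatrix
from .trace import ActivitySeries, IBITrace, read_activity, read_trace, write_trace
from .windows import (
    RetentionPolicy,
    TraceWindow,
    export_covariate_table,
    filter_windows,
    match_activity,
    segment_windows,
)


@dataclass
class PipelineConfig:
    """All pipeline settings in one place.

    Defaults reproduce the study conditions: 5-minute windows, 20-200 bpm
    physiological limits and retention at <= 5% flats-or-stairs beats with
    no Active beats.
    """

    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    min_bpm: float = 20.0
    max_bpm: float = 200.0
    window_s: float = 300.0
    retention: RetentionPolicy = field(default_factory=RetentionPolicy)
    tolerance_ms: float = 0.0
    stair_min_diffs: int = 3
    enable_correction: bool = True
    enable_annotation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "correction" in raw:
            kwargs["correction"] = CorrectionConfig(**raw["correction"])
        if "retention" in raw:
            kwargs["retention"] = RetentionPolicy(**raw["retention"])
        for key in (
            "min_bpm", "max_bpm", "window_s", "tolerance_ms",
            "stair_min_diffs", "enable_correction", "enable_annotation",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class TraceResult:
    """Per-trace pipeline output."""

    trace: IBITrace
    windows: list[TraceWindow]
    retained: list[TraceWindow]
    rejected: list[tuple[TraceWindow, str]]
    flat_matrix: ClassificationMatrix
    stair_matrix: ClassificationMatrix
    n_correction_events: int


@dataclass
class PipelineResult:
    """Pooled pipeline output over all input traces."""

    traces: list[TraceResult]
    pooled_flat_matrix: ClassificationMatrix
    pooled_stair_matrix: ClassificationMatrix
    qc_log: list[str]


def process_trace(
    raw: IBITrace,
    activity: ActivitySeries | None = None,
    config: PipelineConfig | None = None,
    log: list[str] | None = None,
) -> TraceResult:
    """Run one trace through correction, annotation, windowing and filtering."""
    if config is None:
        config = PipelineConfig()
    log = log if log is not None else []
    events = []
    trace = raw
    if config.enable_correction:
        trace, events = correct_artefacts(trace, config.correction)
        for ev in events:
            log.append(
                f"correct kind={ev.kind} raw_index={ev.raw_index} "
                f"before={ev.before} after={ev.after}"
            )
    if config.enable_annotation:
        trace, _ = annotate_trace(
            trace, config.tolerance_ms, config.stair_min_diffs, config.min_bpm, config.max_bpm
        )
    if activity is not None:
        trace = match_activity(trace, activity)
    windows = segment_windows(trace, config.window_s)
    retained, rejected = filter_windows(windows, config.retention)
    for w, reason in rejected:
        log.append(f"reject window={w.window_index} reason={reason}")
    return TraceResult(
        trace=trace, windows=windows, retained=retained, rejected=rejected,
        flat_matrix=ClassificationMatrix.from_trace(trace, "flat"),
        stair_matrix=ClassificationMatrix.from_trace(trace, "stair"),
        n_correction_events=len(events),
    )


def run_pipeline(
    trace_paths: list,
    activity_paths: list | None = None,
    config: PipelineConfig | None = None,
    output_dir=None,
) -> PipelineResult:
    """Process every input trace and pool the classification matrices.

    ``activity_paths`` pairs positionally with ``trace_paths`` (``None``
    entries allowed).  When ``output_dir`` is given, writes per-trace
    annotated traces, a pooled covariate table, a retained-window rMSSD
    table and the QC log.
    """
    if config is None:
        config = PipelineConfig()
    log: list[str] = []
    results = []
    pooled_flat = ClassificationMatrix.from_counts("flat", 0, 0, 0, 0)
    pooled_stair = ClassificationMatrix.from_counts("stair", 0, 0, 0, 0)
    all_windows: list[TraceWindow] = []
    retained_windows: list[TraceWindow] = []
    for k, tp in enumerate(trace_paths):
        ap = None
        if activity_paths is not None and k < len(activity_paths):
            ap = activity_paths[k]
        log.append(f"trace file={tp}")
        raw = read_trace(tp) if not isinstance(tp, IBITrace) else tp
        activity = None
        if ap is not None:
            activity = read_activity(ap) if not isinstance(ap, ActivitySeries) else ap
        res = process_trace(raw, activity, config, log)
        results.append(res)
        pooled_flat = pooled_flat + res.flat_matrix
        pooled_stair = pooled_stair + res.stair_matrix
        all_windows.extend(res.windows)
        retained_windows.extend(res.retained)
        if output_dir is not None:
            out = Path(output_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_trace(res.trace, out / f"trace_{k:03d}_annotated.csv")
    if output_dir is not None:
        out = Path(output_dir)
        export_covariate_table(all_windows, out / "windows.csv")
        with open(out / "retained_rmssd.csv", "w", encoding="utf-8") as fh:
            fh.write("individual_id,tag_id,window_index,rmssd_ms\n")
            for w in retained_windows:
                r = "" if w.rmssd_ms is None else repr(w.rmssd_ms)
                fh.write(f"{w.individual_id},{w.tag_id},{w.window_index},{r}\n")
        with open(out / "qc_log.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(log) + ("\n" if log else ""))
    return PipelineResult(
        traces=results, pooled_flat_matrix=pooled_flat,
        pooled_stair_matrix=pooled_stair, qc_log=log,
    )
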