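"""rMSSD, artefact-vs-flats/stairs classification matrices and Bland-Altman
agreement between paired IBI streams.

rMSSD (root mean square of successive differences) is the time-domain
resting-HRV statistic::

    rMSSD = sqrt( (1 / (N-1)) * sum_{j=1}^{N-1} (IBI_{j+1} - IBI_j)^2 )

Out-of-bounds beats are excluded *before* differencing and the difference
chain splits at each exclusion: no difference is ever taken across an
excluded beat, which would otherwise manufacture spurious large jumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .trace import IBITrace


def rmssd(ibis: np.ndarray, exclude: np.ndarray | None = None) -> float:
    """Root mean square of successive IBI differences, in ms.

    ``exclude`` marks beats (e.g. out-of-bounds) removed before
    differencing; exclusion splits the chain, so differences are only taken
    between beats that were adjacent and both retained.  Raises
    :class:`InsufficientDataError` when fewer than two usable adjacent
    beats remain.
    """
    ibis = np.asarray(ibis, dtype=float)
    if exclude is None:
        keep_diff = np.ones(max(ibis.size - 1, 0), dtype=bool)
    else:
        exclude = np.asarray(exclude, dtype=bool)
        keep = ~exclude
        keep_diff = keep[1:] & keep[:-1]
    if ibis.size < 2 or not keep_diff.any():
        raise InsufficientDataError("need at least 2 usable adjacent beats for rMSSD")
    d = np.diff(ibis)[keep_diff]
    return float(np.sqrt(np.mean(d**2)))


def rmssd_of_trace(trace: IBITrace) -> float:
    """rMSSD of a trace, excluding out-of-bounds beats."""
    return rmssd(trace.ibi_ms, exclude=trace.out_of_bounds)


# -- classification matrices (device-corrected vs flats/stairs) ------------

def _report_round(pct: float) -> float:
    """Reporting convention: 1 decimal, 2 decimals below 0.1%."""
    if pct < 0.1:
        return float(np.round(pct, 2))
    return float(np.round(pct, 1))


@dataclass(frozen=True)
class ClassificationMatrix:
    """2x2 cross-tabulation of device-corrected flags against flat (or
    stair) flags over all beats.

    Cells: ``a`` flagged & corrected, ``b`` flagged & not corrected,
    ``c`` not flagged & corrected, ``d`` neither.
    """

    kind: str  # "flat" or "stair"
    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_flagged(self) -> int:
        """Row total: beats identified as flats (or stairs)."""
        return self.a + self.b

    @property
    def n_corrected(self) -> int:
        """Column total: beats corrected by the device software."""
        return self.a + self.c

    @property
    def pct_of_corrected_flagged(self) -> float | None:
        """Of device-corrected beats, the percent also flagged (100*a/(a+c))."""
        return None if self.a + self.c == 0 else 100.0 * self.a / (self.a + self.c)

    @property
    def pct_of_noncorrected_flagged(self) -> float | None:
        """Of non-corrected beats, the percent flagged (100*b/(b+d))."""
        return None if self.b + self.d == 0 else 100.0 * self.b / (self.b + self.d)

    @property
    def pct_of_flagged_corrected(self) -> float | None:
        """Of flagged beats, the percent that were corrected (100*a/(a+b))."""
        return None if self.a + self.b == 0 else 100.0 * self.a / (self.a + self.b)

    def reported(self) -> dict:
        """Percentages under the reporting rounding convention."""
        out = {}
        for name in (
            "pct_of_corrected_flagged",
            "pct_of_noncorrected_flagged",
            "pct_of_flagged_corrected",
        ):
            v = getattr(self, name)
            out[name] = None if v is None else _report_round(v)
        return out

    @classmethod
    def from_trace(cls, trace: IBITrace, kind: str) -> "ClassificationMatrix":
        if kind not in ("flat", "stair"):
            raise ValueError("kind must be 'flat' or 'stair'")
        flagged = trace.flat if kind == "flat" else trace.stair
        corrected = trace.corrected
        return cls(
            kind=kind,
            a=int((flagged & corrected).sum()),
            b=int((flagged & ~corrected).sum()),
            c=int((~flagged & corrected).sum()),
            d=int((~flagged & ~corrected).sum()),
        )

    @classmethod
    def from_counts(cls, kind: str, a: int, b: int, c: int, d: int) -> "ClassificationMatrix":
        if min(a, b, c, d) < 0:
            raise ValueError("cell counts must be non-negative")
        return cls(kind=kind, a=a, b=b, c=c, d=d)

    def __add__(self, other: "ClassificationMatrix") -> "ClassificationMatrix":
        if self.kind != other.kind:
            raise ValueError("cannot pool matrices of different kinds")
        return ClassificationMatrix(
            self.kind, self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )


# -- beat matching between concurrent streams ------------------------------

def match_beats(
    test: IBITrace, reference: IBITrace, max_offset_s: float = 0.25
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair beats of two time-synchronised streams by nearest beat time.

    Greedy one-to-one matching: candidate pairs are ranked by |time
    difference| and accepted while both beats are unused and the offset is
    within ``max_offset_s``.  Returns (test_ibis, reference_ibis) for the
    accepted pairs plus the count of unmatched beats across both streams.
    """
    t_test = test.beat_time_s
    t_ref = reference.beat_time_s
    if t_test.size == 0 or t_ref.size == 0:
        return np.empty(0), np.empty(0), t_test.size + t_ref.size

    # candidates: each test beat against its two nearest reference beats
    idx = np.searchsorted(t_ref, t_test)
    cand = []
    for j in (idx - 1, idx):
        jj = np.clip(j, 0, t_ref.size - 1)
        cand.append(np.stack([np.arange(t_test.size), jj], axis=1))
    pairs = np.unique(np.concatenate(cand), axis=0)
    offsets = np.abs(t_test[pairs[:, 0]] - t_ref[pairs[:, 1]])
    ok = offsets <= max_offset_s
    pairs, offsets = pairs[ok], offsets[ok]
    order = np.argsort(offsets, kind="stable")

    used_test = np.zeros(t_test.size, dtype=bool)
    used_ref = np.zeros(t_ref.size, dtype=bool)
    sel_test, sel_ref = [], []
    for k in order:
        i, j = pairs[k]
        if not used_test[i] and not used_ref[j]:
            used_test[i] = used_ref[j] = True
            sel_test.append(i)
            sel_ref.append(j)
    sel_test = np.array(sorted(sel_test), dtype=int)
    sel_ref = np.array(sorted(sel_ref), dtype=int)
    n_unmatched = int((~used_test).sum() + (~used_ref).sum())
    return test.ibi_ms[sel_test], reference.ibi_ms[sel_ref], n_unmatched


# -- Bland-Altman agreement -------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement between paired IBI measurements."""

    n_pairs: int
    bias_ms: float
    sd_diff_ms: float
    loa_lower_ms: float
    loa_upper_ms: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]


def bland_altman(test_ibis: np.ndarray, reference_ibis: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement on paired IBIs (differences test - reference).

    Limits of agreement are bias +/- 1.96 sd; their confidence intervals use
    the classic approximation var(LoA) = 3 s^2 / n, and the bias CI uses the
    exact t interval.
    """
    d = np.asarray(test_ibis, dtype=float) - np.asarray(reference_ibis, dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs (sd undefined below)")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lo = bias - 1.96 * sd
    loa_hi = bias + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    half_bias = tcrit * sd / np.sqrt(n)
    half_loa = tcrit * sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        n_pairs=n, bias_ms=bias, sd_diff_ms=sd,
        loa_lower_ms=loa_lo, loa_upper_ms=loa_hi,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_lower=(loa_lo - half_loa, loa_lo + half_loa),
        ci_loa_upper=(loa_hi - half_loa, loa_hi + half_loa),
    )
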