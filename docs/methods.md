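# Methods

This note documents the models, defaults and numerical choices behind
`ibiqc`, and what the synthetic-data experiments do and do not establish
about real field recordings.

## Data model

A trace is an ordered IBI sequence in milliseconds; beat times are the
cumulative IBI sum from session start, so beat *k*'s IBI is the interval
ending at its R peak and the first beat's time equals its own IBI. Device
streams carry integer-ms IBIs (1000 Hz sampling); synthetic intermediates
may be real-valued. Per-beat flags record, separately, device-style
correction (`corrected`), the uncorrectable interpolation artefacts
(`flat`, `stair`), physiological-limit violations (`out_of_bounds`) and the
matched behavioural state (`Inactive`/`Active`/`Unknown`). Flats and
stairs are annotations only — they are never altered, merely counted and
filtered on.

## Synthetic trace generator

Clean resting traces are modelled as

    IBI(k) = mu + RSA(k) + X(k),    X(k) = phi * X(k-1) + eps(k)

with `eps ~ N(0, sigma_eps^2)` and an optional sinusoidal
respiratory-sinus-arrhythmia term `RSA(k) = A * sin(2*pi*t_k / P)`. The
innovation variance is solved in closed form so the AR(1) component's
rMSSD, `sqrt(2 * var(X) * (1 - phi))`, equals the requested target when
`A = 0`; the AR state starts at stationarity. IBIs are rounded to integer
ms and clipped below at 300 ms.

Defaults: mean IBI 1000 ms (60 bpm — inside the 41–124 bpm range of
resting grey-seal windows), target rMSSD 90 ms (inside the 69–108 ms range
spanned by the exemplar resting traces), `phi = 0.5` and RSA period 10 s.
The lag-1 coefficient and RSA parameters are plausible placeholders, not
field estimates: the downstream methods consume only the IBI sequence, so
cardiac realism beyond a tunable rMSSD, autocorrelation and a periodic
component is deliberately out of scope. No dive bradycardia or activity
coupling is modelled.

Corruption emulates three field error processes, each preserving total
elapsed time: *missed beats* (per-beat probability; the IBI merges into
its successor), *spurious beats* (per-beat probability; the IBI splits at
a uniform fraction in (0.2, 0.8), keeping both halves individually
detectable as short), and *dropout bursts* (Poisson arrivals in time,
exponential lengths; all beats inside the burst vanish and the receiver
sees one long spanning IBI — the input that forces multi-beat
interpolation downstream). A per-beat provenance record
(genuine/merged/split/gap) supports oracle checks. Reference pairs for
agreement studies perturb each beat time with independent Gaussian jitter
and recompute IBIs, so consecutive paired differences share an endpoint
and have SD `sqrt(2) * jitter`; a constant IBI bias is available (note it
accumulates into clock drift over long streams, as it would for a real
instrument whose intervals are systematically long).

Activity series alternate exponential Inactive/Active bouts with the
Active bout mean scaled to hit the requested long-run Active fraction.

## Artefact-correction emulator

The vendor algorithm is proprietary; the emulator implements its
documented behaviour — detect extreme values, delete spurious extra beats,
interpolate for missing beats, and flag every corrected IBI. An IBI is
extreme when it deviates from the running median of 7 raw IBIs by more
than 25% of that median (a Kubios-style "strong" threshold; both
parameters configurable), or breaches the absolute 300/3000 ms backstop
used when the local median itself is corrupt.

* **Extreme short runs** of up to 3 consecutive IBIs whose sum lands back
  within the threshold of the local median are merged into one corrected
  beat (the spurious detection deleted). Lone shorts whose sum rule fails
  pass through unflagged — there is nothing defensible to repair.
* **Extreme long IBIs** of duration `D` imply `m = round(D / local
  median)` beats (round half to even). For `m <= 1` the value is left in
  place and only flagged — no missing beat is implied, which keeps benign
  false alarms value-neutral. For `m >= 2` the gap is filled with `m`
  integer-ms beats running linearly from the preceding to the following
  IBI value — constant when those anchors are equal. The rounding residual
  is assigned to the final fill beat, so total duration is conserved
  exactly while the leading fill beats keep an exactly constant value
  (producing a flat) or an exactly constant step (producing a stair).
  Linear/constant interpolation is chosen precisely because the observed
  artefact classes are those two shapes.

No attempt is made at bit-exact vendor replication: the analysis layer
depends only on which beats are flagged, not on vendor-exact values.

## Flats, stairs and limits

A flat is a maximal run of >= 2 consecutive identical IBIs; a stair is a
maximal run of >= 3 identical non-zero successive differences (>= 4
beats). "Identical" defaults to exact equality (device IBIs are integer
ms); a tolerance is available for real-valued synthetic data, applied as
chained pairwise agreement. All beats of a run are flagged, including the
run head (both the head flagging and the >= 3-differences reading are
configurable, since the original analysis scripts are unpublished and the
boundary conventions are not stated). Physiological limits flag beats
outside 20–200 bpm, i.e. IBIs above 3000 ms or below 300 ms, with the
boundary values acceptable.

## Windowing and retention

Windows are fixed half-open clock intervals `[k*w, (k+1)*w)` with
`w = 300 s`; a beat belongs to the window containing its beat time, the
trailing partial window is discarded, and a beat exactly on a boundary
opens the next window. Activity is matched per beat from the label of the
integer second containing its beat time, `Unknown` where the label series
has a gap; the Active percentage is computed over beats with known labels
(absent when none). Retention defaults: at most 5% flats-or-stairs beats
(boundary inclusive) and 0% Active beats. The zero-activity default is the
strictest reading of "resting"; the study itself states no numeric
activity threshold, so the policy is fully configurable. Rejections carry
the first failed criterion in a fixed evaluation order (beat count,
flats/stairs, activity, artefacts).

## rMSSD and agreement

rMSSD follows the defining formula over successive differences.
Out-of-bounds beats are excluded *before* differencing and the chain
splits at each exclusion — bridging differences across a removed beat
would manufacture spurious large jumps. Fewer than two usable adjacent
beats raises an explicit error rather than returning a default.

Beat matching between concurrent streams is greedy nearest-neighbour on
beat times: candidate pairs ranked by |Δt|, accepted one-to-one within a
0.25 s tolerance (configurable; the streams are assumed synchronised to
within a second). Bland–Altman agreement reports bias, sample SD of the
differences, LoA = bias ± 1.96 sd, a t-based bias CI and LoA CIs using the
classic `var(LoA) ≈ 3 s^2 / n` approximation; two pairs are the minimum
(one degree of freedom for the SD). Classification matrices cross-tabulate
`corrected` against `flat` (or `stair`) over all beats; derived
percentages are reported to one decimal, two decimals below 0.1%.

## Injection study

Each run injects errors into a fresh copy of a clean trace and records
(contamination, rMSSD) after every step; samples pool across runs into
left-open bins of width 0.01 over (0, 1] with means and 2.5/97.5
percentile bands (percentiles from a 512-sample-per-bin reservoir).

Contamination is measured on the *detected state* as the fraction of
successive differences inside detected runs — zero differences for flats,
ramp-covered differences for stairs. This scale is used because it is the
one on which full contamination coincides with the degenerate endpoints
(a fully flat trace has rMSSD exactly 0; a single full-trace ramp has
rMSSD equal to its tiny step), whereas a beat-membership fraction reaches
1.0 while plateau junctions still carry large differences, so the curve
could never reach zero there. On an AR(1) trace the expected squared-
difference loss is `2*sigma_x^2*(1-phi)^2` per flat difference versus
`2*sigma_x^2*(1-phi)` per stair-covered difference, so stairs depress
rMSSD about `1/(1-phi)` times faster — a factor 2 at the default
`phi = 0.5`, matching the roughly twofold difference seen in the study's
simulations.

Flat runs iterate the copy-next step until the trace is completely flat
(the running sum of squared differences is exact integer arithmetic, so
absorption is detected as exactly zero); the quadratic-length tail is
handled by a compiled kernel. Stair runs default to a single random block
per simulated trace, which spans the whole contamination range across
runs; the fully contaminated endpoint is the computed full-span ramp. A
cumulative-block schedule is available but degenerates late in a run
(anchors converge, blocks become flat fills and detected stair coverage
collapses), which is why it is not the default.

## Problem sizes and numerical choices

The test and acceptance experiments use a ~600-beat (600 s) trace with
target rMSSD 108 ms for the injection studies (1000 runs), 2500-pair
agreement replicates (100 replicates), and three 3000-beat traces (target
rMSSD 70/90/110 ms) for end-to-end recovery with light corruption
(missed/spurious probability 0.002 per beat, 0.05 dropout bursts per
minute of mean length 4 s). These sizes give Monte-Carlo standard errors
well inside the asserted tolerances while keeping the full suite fast.
Every stochastic component takes an explicit seed and is bit-reproducible
given it.

## What the synthetic experiments do and do not show

Passing tests establish that the pipeline's mechanics are correct on data
whose generative truth is known: detectors match brute-force oracles,
duration is conserved through corruption and correction, gap interpolation
produces exactly the two artefact shapes, agreement analysis recovers an
injected bias, and the retention policy's 5% boundary costs at most a few
ms of rMSSD. They do not validate the emulator against the actual vendor
algorithm (proprietary), nor the AR(1)+RSA process against real seal
cardiac dynamics, nor behaviour classification (labels are consumed, not
produced). Determinant modelling of error counts (e.g. GAMM fits on the
exported covariate table) is intentionally outside the package: the
covariate table is the interface to it.
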