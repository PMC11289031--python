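# Methods

## The measurement model

A driving-simulator hazard scene is observed through three streams on one
clock (milliseconds from recording start):

- **detections** — per-frame axis-aligned person bounding boxes with a
  confidence score, from an external object detector (960×540 px scene
  frames by default). Detections are plain data; the detector is consumed
  behind an adapter (CSV in the reference path, or any callable that yields
  the same dialect from video).
- **gaze** — scene-camera gaze points at a nominal 50 Hz, each flagged
  valid/invalid. Invalid samples are retained (quality control needs the
  missing-data ratio) but can never certify a fixation.
- **simulator log** — ego speed (km/h), distance to the pedestrians (m),
  brake pedal force (N), stop-sign stimulus state.

Gaze-to-frame alignment maps a timestamp to the video frame whose half-open
interval `[i/fps, (i+1)/fps)` contains it. Half-open intervals avoid
double-assignment of boundary samples; with both rates at 50 Hz a gaze
sample aligns to the frame that starts at the same instant.

### Time to fixate

`t1` is the start time of the earliest frame, inside the configured scene
segment, holding a person detection at or above the confidence floor
(default 0.25, the common detector default) — after manual corrections are
applied, and never an interpolated box (interpolation infers presence, it
does not observe it). `t2` is the timestamp of the first valid gaze sample
at or after `t1` whose point lies inside **any** person track's box on the
sample's frame; the scene has two children and nothing privileges one of
them, so the union of person boxes ends the search. The hit test is a
closed rectangle: a gaze point on the edge counts as inside, the
conservative reading of "gaze falls within the box". A single sample
suffices — no dwell criterion — because the endpoint is the arrival of
gaze on the object, not a filtered fixation event.

TTF = `t2 − t1`. Flags: `anticipatory` iff TTF = 0 (gaze already on the
hazard at onset; excluded from analysis), `sub_saccade` iff
0 < TTF < 120 ms (faster than a visually guided saccade; flagged but kept),
`miss` iff gaze never enters a box before the segment ends. The three are
mutually exclusive by construction.

Tracks are taken from detector track ids when present; otherwise greedy
IoU ≥ 0.3 linking between consecutive frames (a plumbing default,
config-exposed). Gaps of at most 5 frames are filled by per-coordinate
linear interpolation of (x, y, w, h); interpolated boxes count for `t2`
(the object was there; the detector blinked) but not for `t1`.

### Auxiliary features

- **IGD** — Euclidean distance from the gaze point nearest `t1` (valid,
  within ±100 ms) to the centre of the onset box, rounded to the nearest
  integer pixel, then scaled by deg/px. The pixel-to-angle factor defaults
  to `horizontal_fov_deg / width_px` with an 82° scene-camera field of
  view; both are configurable because the factor depends on the exact
  camera revision.
- **TTC** — `distance_m / (speed_kmh / 3.6)` at onset; undefined (flagged)
  at zero speed.
- **speed at onset** — the log sample nearest `t1`, ties to the earlier
  sample; nearest-sample rather than interpolation because the log is dense
  relative to speed dynamics.
- **PRT** — per stop-sign repetition, the time from the trigger to the
  first log sample *strictly after* it with brake force ≥ 75 N (a pedal
  already down at the trigger is not a response), searched up to the next
  trigger so one braking event cannot satisfy two stimuli. Repetitions
  outside 0.5–4 s are discarded; the subject's PRT is the mean of the
  survivors, absent if none survive.
- **type-B uncertainty** — an event time read off a clock of resolution r
  carries a uniform error over ±r/2, hence standard uncertainty
  `r / (2√3)`; 5.77 ms at the 20 ms frame period. No second uncertainty
  component is quantified, so no combined uncertainty is reported.

### Screening

Session QC (the automated counterpart of manual session review): frozen
gaze = zero coordinate variance across the segment; missing gaze = invalid
fraction above 0.5; recording pause = any inter-sample gap above 3 nominal
periods (60 ms). The thresholds are package choices, config-exposed —
the physical-setup faults they stand in for were originally judged by eye.

Cohort screening, computed in one pass on the original cohort (never on an
already-filtered one): TTF ≥ 500 ms → `ttf_over_max` (pointwise);
TTF > Q3 + 3·IQR of the pooled TTF sample → `ttf_iqr_outlier` (one-sided,
above only, exactly as stated; quartiles by linear interpolation between
order statistics, matching the R default). The removal set is the union of
the flags, which makes the outcome independent of rule order. Pooled
rather than per-group, since the rule is stated for the TTF sample as a
whole. With fewer than 4 values the IQR rule is skipped with a warning.
PRTs: the 0.5–4 s window applies per repetition before averaging; the IQR
rule then applies to the averaged values.

### Statistics

- **Welch's ANOVA** for TTF (and PRT) across the three fitness-to-drive
  groups — computed from the Welch (1951) formula with fractional
  Welch–Satterthwaite df2, p from the F distribution. Authored directly:
  scipy has no Welch ANOVA, and the test suite cross-checks against
  pingouin's implementation and against the squared Welch t at k = 2
  (an exact identity).
- **Tukey HSD** at 0.95 family-wise confidence, Tukey–Kramer standard
  errors for unequal n, p-values and critical points from
  `scipy.stats.studentized_range` (numerically integrated, so the k = 2
  equal-n identity with the pooled t-test holds to ~1e-12; the interpolated
  q-tables used by some libraries do not reach that). Intervals are
  symmetric about the mean difference by construction. The pairing of a
  heteroscedasticity-robust omnibus with a classical pooled-variance post
  hoc mirrors the original analysis deliberately — fidelity over
  orthodoxy; Games–Howell would be the orthodox companion.
- **Linear model** `TTF ~ fitness + speed + IGD + TTC + fitness:IGD:TTC`,
  sequential (Type I) sums of squares in that order, significance at
  α = 0.001 (the stringent level compensating for variance heterogeneity).
  The exact original model formula is not published; main effects plus the
  named three-way interaction with sequential SS is this package's declared
  convention. Fitted via statsmodels OLS/anova_lm; constant covariates are
  dropped with a warning, rank deficiency raises.
- **Shapiro–Wilk** on the model residuals (scipy, AS R94 approximation)
  and **Pearson correlations** of TTF with speed, IGD, TTC and PRT
  (two-sided p via the t transform).
- PRT analyses use subjects with a usable TTF, since response times are
  reported for the participants in whom the fixation was measured.
- A `--include-outliers` switch re-runs the battery without the TTF
  screens (the robustness check).

## The synthetic generator

`generate_session` emulates the hazard scene: a person track entering at a
scripted frame with a linear trajectory; gaze holding a road-centre
fixation, then stepping onto the box centre after a scripted latency (the
ground-truth TTF) with Gaussian noise, optional linear slippage drift
(device moving on the head) and uniformly missing samples; a simulator log
with constant speed, linearly shrinking distance, stop-sign triggers and
step brake responses (0 → 150 N) after scripted delays. The gaze model is
deliberately kinematics-free — a fixation and a single step, no saccade
velocity profile — because the gaze-in-box event depends on timing, not on
eye-movement realism. Specs whose box leaves the frame before gaze
arrival, or whose braking window would bleed into the next stop sign, are
rejected at generation time.

`generate_cohort` draws per-group feature records: TTF and PRT from
truncated normals inside their validity windows — truncation guarantees
un-injected records survive the screens, at the cost of slightly shifting
the realised mean relative to the location parameter (tests compare
against the truncated-population mean) — and lognormal speed/IGD/TTC by
moment matching, since those covariates' reported ranges are far too wide
for normality. Cohort defaults are the study-like group sizes and moments:
n = (20, 17, 19); TTF mean (SD) 163 (47) / 293 (95) / 262 (99) ms; PRT
1241 (475) / 1215.98 (358) / 1696 (449) ms for fit / conditionally-fit /
unfit. Deliberate outliers (> 500 ms) can be injected for screening tests.
Everything is bit-reproducible given the seed.

What passing the synthetic tests does **not** show: robustness to detector
mislocalisation patterns of real scenes (the manual-corrections path is
exercised only with scripted edits), to non-linear slippage, to saccade
kinematics, or to covariate structure beyond independent lognormals. The
generator certifies the event logic and the statistics, not the detector.

An optional rendering path rasterises a session into RGB frames and a
trivial colour-threshold detector recovers the detection table (±1 px),
closing the loop on the detector-adapter contract without any real video.

## Numerical choices and problem sizes

- Quantiles: linear interpolation (`numpy` default), config-relevant only
  through the screening fence.
- Studentized-range p-values: scipy's integrated distribution; values are
  clipped to [0, 1].
- Determinism: all generators take explicit seeds; `run_pipeline` is a
  pure function of (session, config).
- Test/acceptance problem sizes — 500–1000 random sessions of 3 s for
  oracle equivalence, 200 sessions for latency recovery, 100 cohort
  replicates for power and false-positive rates — were chosen to keep the
  whole suite in the low minutes while leaving the binomial assertions
  (≥ 80 %, < 50 %, ≤ 1 %) comfortable margins.

## Known limitations

- `t1` is defined by detector output, so a late first detection biases TTF
  downward symmetric manual corrections can fix this only where a human
  re-annotates the entry frame.
- No saccade/fixation classification: a single gaze sample inside the box
  ends the search, so a fast pass-through glance counts as a fixation.
- The scene segment must be supplied (or is derived from the detection
  span); there is no content-based scene recognition.
- Only the type-B timing component of measurement uncertainty is modelled.
- The IoU track linker is greedy and single-hypothesis; crossing
  pedestrians can swap identities. TTF is insensitive to identity swaps
  (union-of-boxes rule), but per-track analyses would not be.
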