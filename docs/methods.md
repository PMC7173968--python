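# Methods

This note documents the models and numerical choices behind `dtsleep`: the
spectral features, the five-state scoring rules and their thresholds, the
semi-Markov synthetic-recording generator and its calibration, and the
limits of what the synthetic validation demonstrates.

## Signal conditioning and epoch features

Recordings are two channels (EEG, EMG) in µV, nominally 128 Hz. Both are
band-passed with a zero-phase 4th-order Butterworth filter applied
forward–backward (no group delay, so epoch boundaries stay aligned across
channels): EEG 1.5–30 Hz, EMG 15–300 Hz. A digital band cannot exceed
Nyquist, so the EMG band is capped at 0.98 × fs/2 (15–62.7 Hz at 128 Hz);
the 15–300 Hz figure describes the analog front-end this cap emulates. The
run log records the effective bands. Because the EEG high-pass sits at
1.5 Hz, spectral bins below 1.5 Hz are attenuated; this affects the absolute
δ power (band starts at 1 Hz) but not the scoring rules, which only use δ
*ratios* between states scored with the same filter.

Epochs are 4 s, anchored at sample 0, half-open windows `[kL, (k+1)L)`;
a trailing remainder is dropped and logged. Per epoch we compute a single
Hann-windowed periodogram (no sub-epoch averaging — the epoch is the atomic
scoring unit). The window is RMS-normalized, so summed bin powers estimate
signal variance in µV² and the sum of native bins equals the mean square of
the windowed epoch (Parseval; asserted to 1e-6 in tests). Native 0.25-Hz
bins are summed into 1-Hz bins centered on integer frequencies (bin *k*
collects `[k−0.5, k+0.5)`); aggregation conserves total power exactly.

Band edges on that grid: δ = [1, 6), θ = [6, 11), α = [11, 16),
β = [16, 31) Hz. δ and θ are the standard rodent definitions used by the
scoring rules; α and β are the conventional continuation and exist only for
reporting (band fractions are normalized over these four bands and sum
to 1). The θ-fraction used by the REM/cataplexy rule is θ power over total
1–30 Hz power; the "over 50 % θ activity" convention does not pin down a
denominator, so this choice is explicit and configurable. The EMG integral
is mean rectified EMG × 4 s (µV·s). Epochs with zero total power get NaN
fractions and are flagged unscorable rather than silently classified.

## Threshold estimation

Commercial scoring pipelines hide their thresholds; ours are estimated from
the recording and logged.

* **EMG wake/atonia thresholds.** Log EMG integrals are split by exact
  two-class 1-D clustering (exhaustive split on sorted values — the global
  optimum, deterministic, no k-means iteration). The wake threshold is the
  midpoint of the cluster centers in log space (geometric mean scale); the
  atonia threshold is the 90th percentile of the low cluster. Bimodality is
  checked via the variance fraction the split explains: an optimal 2-split
  of a unimodal Gaussian explains exactly 2/π ≈ 0.64, while genuine
  wake/sleep EMG mixtures explain ≳ 0.8 (0.81–0.91 across our presets), so
  recordings below 0.72 raise a labeled error advising manual thresholds
  (e.g. an all-wake recording).
* **Spectral references.** Provisional NREM epochs (low EMG, δ the largest
  band fraction, θ-fraction ≤ 0.5) give the NREM δ reference as a *median*
  (robust to a few mislabeled epochs); provisional REM epochs (low EMG,
  θ-fraction > 0.5) give the REM θ reference, falling back to the NREM pool
  when a recording contains no REM.

All thresholds scale with the input signals, so scoring is equivariant to
gain changes.

## State rules

Base rules per epoch: W if EMG integral ≥ wake threshold (muscle activity
wins regardless of spectrum); else R if θ-fraction > 0.5; else NR. The
context detectors then relabel maximal runs:

* **Cataplexy**: runs of non-wake epochs with EMG below the atonia threshold
  and θ-fraction > 0.5, of length ≥ 3 epochs (the smallest run exceeding
  10 s on a 4-s grid), immediately preceded by ≥ 10 consecutive W epochs
  (40 s). The antecedent run must be strictly W — DT or sleep epochs reset
  the wake counter.
* **DT sleep**: after cataplexy (C has precedence; a run satisfying both is
  C, since cataplexy carries the stricter θ-dominance requirement), runs of
  non-wake, non-C atonia epochs with δ ≥ `dt_delta_ratio` × NREM δ reference
  and θ ≥ `dt_theta_ratio` × REM θ reference, preceded by ≥ 10 W epochs and
  immediately followed by W. The δ ratio defaults to 0.6, the permissive end
  of the 60–80 % range used for this state's definition, and is
  configurable; raising it can only shrink the set of D epochs (a monotone
  filter, tested). "Behavioral arrest" is operationalized purely as EMG
  atonia — video is outside this package's scope. A DT-like run cut off by
  the end of the recording cannot demonstrate its return to wakefulness and
  is conservatively left as NR/R, with a flag on the hypnogram.

No smoothing or majority filter is applied: manual visual correction of
automatic scores is inherently irreproducible, so the state machine's output
is the final answer. The context detectors are verified against brute-force
enumeration of every rule-satisfying interval on small feature tables.

## Synthetic recordings

The generator exists so every stage is testable without animal data. It has
two deterministic stages fed by independent streams spawned from one seed
(changing signal noise never perturbs the state sequence).

**State sequence.** A semi-Markov chain: dwell times are gamma (shape 2 —
positive, right-skewed, matching mean ± SEM reporting without over-fitting
an unknown shape) with configured means, rounded to whole epochs and
truncated below at 1 epoch (3 epochs for cataplexy, so every generated C
satisfies the > 10 s rule). Transitions: C and D are entered only from W; if
a sampled wake bout is shorter than 10 epochs the C/D exits are suppressed
and the bout continues into NREM (the paper's structural constraint,
enforced by construction); D exits only to W; R is entered only from NR. A
trailing truncated D (or too-short C) run is replaced by wake so every
emitted sequence passes the structural audit.

**Calibration.** Preset transition weights are *solved*, not hand-tuned:
given target per-12-h bout counts and mean durations per state, the expected
number of wake bouts is N_W = N_NR + N_C + N_D (each such bout is entered
from wake), the wake dwell mean is the occupancy remainder divided by N_W,
and the W→C/W→D probabilities are the target counts divided by the expected
number of *eligible* (≥ 40 s) wake bouts, computed from the discretized
dwell distribution. Targets are the published 4-week group means: for the
dual-ablated dark phase, NREM 90.5 min, REM 2.7 min, cataplexy 16.9 bouts ×
113.0 s, DT 98.3 bouts × 14.4 s, wake as remainder (≈ 571 min — the
published occupancies are self-consistent to within a minute). Values the
reports leave unconstrained (NREM/REM mean bout durations, intact-mouse
occupancies, the light-phase DT count) are fixed once at field-typical
values and marked "assumed" in `CONDITION_TARGETS`; the light-phase DT
count (51.3) is the occupancy remainder of the published light-phase
totals. Light-phase DT dwell is taken equal to the dark-phase 14.4 s,
consistent with the reported ~15 s plateau in both phases.

**Signals.** EEG is a sum over bands of unit-variance band-limited Gaussian
noise (white noise through a 4th-order Butterworth band-pass) scaled by the
state's per-band RMS amplitude in µV — controllable band powers without
committing to an autoregressive model. EMG is white noise with state
tone × √(π/2) as σ (so the mean rectified amplitude equals the configured
tone) times a slow multiplicative envelope with the configured CV. State
changes blend amplitudes with a raised-cosine crossfade, default 0.5 s
centered on the boundary. A whole-epoch crossfade would contaminate the
edge epochs of 1–4-epoch DT bouts enough to break the very criteria that
define them; 0.5 s keeps boundary epochs > 93 % pure while avoiding clicks.

Default state profiles follow the qualitative signatures — wake
low-amplitude mixed EEG with high tone; NREM δ-dominant; REM/cataplexy
θ-dominant with atonia; DT high δ *and* θ with low (not absent) tone. The
exact amplitudes were chosen once, by analysis of periodogram statistics
rather than against test outcomes: a 4-s epoch gives each 5-Hz band ~20
native bins, so band power estimates have a relative spread of ~25 %, and a
bout is detected only if *every* epoch passes its thresholds. Amplitudes
therefore place each defining contrast ≥ 3σ from its threshold (e.g. DT δ
power ≈ 3× its 0.6 × NREM-reference cut, DT θ ≈ 3× its cut, DT θ-fraction
0.35 — clear of the 0.5 cataplexy boundary), which keeps per-epoch rule
failures ≲ 10⁻³ and lets multi-epoch bouts survive intact. This is a
statement about the generator's SNR, not about real mice: see Limitations.

**What the generator does not emulate.** Circadian drift within a phase,
electrode/movement artifacts, the infrared locomotion channel (wake is
distinguishable by EMG alone here; the activity sensor is hardware-specific
and redundant for these rules), 1/f background structure, spindles, and
inter-animal variability. Passing tests therefore demonstrate correctness
of the *rules and statistics pipeline* and recoverability of the published
bout structure at realistic band-power contrasts — not field performance on
noisy recordings, which still warrants human review.

## Sleep-architecture statistics

Bouts are maximal same-label runs; they partition the hypnogram. Phase
totals are epoch-accurate (a bout spanning the light/dark boundary is
split), while bout counts and mean durations assign each bout to the phase
of its start epoch — both conventions are documented because the published
tables do not specify one; they agree except at the two boundary bouts per
day. Hourly summaries split totals at hour boundaries but count a spanning
bout once, in its start hour. Fold differences are second group over first
(the published tables' OXMC/OX convention), reported at 2 decimals with full
precision retained internally. Of the twelve printed fold ratios, eight are
exactly the ratio of the printed group means at 2-decimal rounding and are
asserted in tests; the remaining four were evidently computed from unrounded
per-animal means and cannot be recovered from the printed values.

NREM→REM transitions are the last 3 NREM epochs (12 s) immediately before a
REM bout; shorter NREM runs are skipped and logged. The DT-vs-transition
comparison reports mean band fractions and EMG integral per condition per
recording and a paired t-test per measure across recordings, with Bonferroni
adjustment over the measures (matching the one-test-per-band reporting
style while controlling the family error). Group tests are paired/unpaired
t-tests and one-way ANOVA with Bonferroni-adjusted pairwise post hocs
(Bonferroni, not Holm, to match the reporting convention). The null
calibration of the DT-vs-transition comparison is tested on a generator
config in which NREM and DT share one profile *with hard state switches*:
with a crossfade, transition epochs absorb a little REM and DT epochs a
little wake, a genuine systematic difference that a paired test correctly
flags — exchangeable epochs require exact switching.

## Problem sizes and determinism

Validation uses 12-h recordings (10,800 epochs) for parameter recovery
(10-seed ensembles), 1–3-h recordings for pipeline unit tests, and
100 × 6-recording batches of 30-min recordings for the null calibration;
these sizes give ensemble standard errors well below the published SEMs
while keeping the suite fast. Every stochastic component is seeded;
identical configs and seeds produce bit-identical hypnograms, signals and
scores.

## Known limitations

* DT-bout recovery has a small negative duration bias (~0.3–0.6 s on
  14.4 s): a bout whose edge epoch narrowly fails a band criterion is
  clipped or, if the antecedent-wake check then fails, dropped. This is the
  honest behavior of epoch-wise rules at bout edges.
* The 60–80 % δ range in the DT definition is treated as a configurable
  threshold with 0.6 as default; whether it describes an acceptance band or
  inter-animal variability is not stated in the source definition.
* EDF export quantizes to 16 bits over the per-channel amplitude range
  (round-trip error ≤ 2 quantization steps, tested); the raw-binary
  fallback (float32 + JSON sidecar) is lossless.
* `estimate_references` needs ≥ 500 epochs and a bimodal EMG distribution;
  recordings without sleep require manual thresholds.
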