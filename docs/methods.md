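# Methods

## Problem and model

The video head impulse test (vHIT) records paired head and eye angular
velocities (deg/s) while an examiner passively rotates the patient's head in
the plane of one semicircular canal (SCC) — about 5° in about 100 ms.  The
device reports a 0.7 s record per repeat with the rotation onset relocated to
0.1 s, so the impulse occupies 0.1–0.2 s and corrective saccades 0.2–0.7 s.
The classical summary is the vestibulo-ocular reflex (VOR) gain, the ratio of
eye to head response.  This package implements a time–frequency alternative:
the magnitude-squared wavelet coherence (MSWC) of head (X) and eye (Y)
velocity,

    R²_n(s) = |S(s⁻¹ Wⁿ_XY(s))|² / ( S(s⁻¹ |Wⁿ_X(s)|²) · S(s⁻¹ |Wⁿ_Y(s)|²) )

with W the analytic Morlet continuous wavelet transform (center frequency
ω₀ = 6), Wⁿ_XY = Wⁿ_X (Wⁿ_Y)* the cross-wavelet spectrum, and S a smoothing
operator applied in time then scale, S = S_scale(S_time(·)).  Without S the
ratio is identically 1; the smoothing is what turns it into a coherence
estimate, and a regression test asserts that degeneracy.

The scalar statistic of interest is the **coherent frequency**: scanning grid
frequencies upward from the lowest resolvable one, a frequency qualifies if
MSWC ≥ 0.9 at *every* time sample of the 0–0.7 s exam; the statistic is the
top of the contiguous qualifying band anchored at the lowest frequency (0 if
even that fails).  "Every time sample" and "contiguous band" are the two
interpretive choices; the alternative global-maximum rule is available via
`coherent_frequency(..., mode="global")`.

## Numerical choices

- **Scale grid**: geometric, 12 voices/octave; the frequency-scale map uses
  the Fourier factor λ = 4π/(ω₀ + √(2+ω₀²)).  The smallest scale is 2·dt/λ so
  the top grid frequency is exactly Nyquist; the grid extends down to 1.4 Hz
  (the full-record period).  One *voice* (2^(1/12) ≈ 5.9% in frequency) is the
  grid's resolution and the tolerance unit used throughout.
- **CWT**: Fourier-domain implementation with zero padding to ≥ 4n samples,
  so records are not treated as periodic.
- **Smoothing**: S_time is a per-scale Gaussian exp(−t²/(2s²)) truncated at
  ±4s, applied with reflection at the record edges; S_scale is a boxcar
  spanning 0.6 octave (the Morlet scale-decorrelation length) with fractional
  end weights, renormalized where the grid truncates it so constants are
  preserved exactly.
- **Division guard**: the smoothed ratio obeys Cauchy–Schwarz, so values
  cannot exceed 1 mathematically; division is masked where the denominator
  underflows to exactly zero (result 0) and the ratio is clipped to [0, 1]
  against rounding.
- **Cone of influence** is computed (e-folding time √2·s) and stored, but the
  coherent-frequency scan does not mask by it — the scan covers the entire
  exam window, edges included; masking is available behind a flag.

## Synthetic cohort generator

No public vHIT dataset with hearing-recovery labels exists, so the package
ships a generator whose defaults emulate a 64-patient sudden sensorineural
hearing loss with vertigo (SSNHLV) cohort: 20 complete-recovery (CR),
18 partial (PR), 26 no-recovery (NR) patients, three SCCs each, 10 repeats
per canal at 250 Hz (the device class's typical rate; the rate is
configurable and nowhere pinned by the analysis).

Each repeat is built as:

- **Head** = raised-cosine (Hann) velocity pulse — amplitude exactly the
  rotation angle (5° over 0.1 s), closed-form peak 2A/D — plus broadband
  "tremor" (sd 1.5 deg/s) modelling residual motion and sensor noise.  The
  tremor matters: it gives the coherence estimate support at every time of
  the record, not just during the impulse.
- **Eye** = gain · LP(head) (zero-phase order-4 Butterworth at the coupling
  corner, renormalized to preserve the impulse-window area) + independent
  above-corner noise matched to the head's broadband floor + Gaussian
  saccade pulses + a small measurement-noise floor (sd 0.15 deg/s).

Design rationale, in order of importance:

1. *Area-exact gain.*  Devices compute gain as the area ratio over the
   impulse window.  Low-passing the impulse smears its energy outside the
   window and would couple the gain estimate to the cutoff; the
   area-renormalization makes the noise-free area gain equal the generative
   gain exactly at any cutoff, so gain and coupling cutoff are independent
   dials, as they are in the clinical summary statistics.
2. *Scale-free coherence transition.*  Below the corner the eye tracks the
   head (pulse and tremor alike); above it the eye's content is independent
   noise of matched power.  Because every ingredient is spectrally flat, the
   0.9-crossing sits a fixed number of voices below the corner regardless of
   where the corner is.  That offset (measured ≈ 0.90 across corners 3–9 Hz
   and gains 0.6–1.0) is compensated by a single constant,
   `CUTOFF_CALIBRATION = 1.115`, applied to the filter corner: the nominal
   cutoff parameter is thereby expressed in recovered-coherent-frequency
   units.  After calibration, recovery is unbiased within one voice across
   the 3–9 Hz range.
3. *Saccades degrade coherence naturally.*  A saccade is eye-only content,
   so repeats with saccades tend to lower coherent frequencies — the same
   association the clinical correlations show.

**Class calibration.**  The incomplete-recovery (PR+NR) canal distributions
use the published subgroup statistics (posterior gain 0.83 ± 0.30, posterior
cutoff 4.94 ± 2.28 Hz, etc.); CR means are back-computed from the published
whole-cohort means and the 20/44 class split (posterior gain 0.99, posterior
cutoff 7.02 Hz), so the simulated cohort reproduces the cohort-level means by
construction.  CR standard deviations (1.0 Hz, 0.10) and the CR saccade
probabilities are not published and were fixed once at plausible values.
Patient-level draws come from these class distributions; repeats jitter
around the patient's values (gain sd 0.03, cutoff sd 0.2 Hz) to mimic
test–retest variability.  Cutoffs are clipped to [2, 10] Hz to stay on the
resolvable part of the grid.  All randomness descends from one seed through
per-patient spawned substreams, so cohorts are bitwise reproducible.

**What the generator does not model**: nystagmus, blinks, device tracking
artifacts and de-saturation, head bounce, bilateral ears, and any
inter-canal correlation beyond the shared class membership.  Passing tests
therefore demonstrate that the *pipeline* recovers what this generative
model encodes — not that the clinical effect sizes are reproducible from
real data, which are not public.

## Features

- **VOR gain**: area ratio of eye to head velocity over 0.1–0.2 s, with
  detected-saccade intervals (±12 ms padding) excised from both series; a
  peak-ratio option exists.  Per-patient gain is the *median* over repeats:
  a covert saccade overlapping the impulse can corrupt a single repeat's
  subset-area estimate when coupling is band-limited, and the median
  discards those repeats, as a clinician discards artifacted impulses.
- **Saccade detection**: threshold (60 deg/s, ≥ 10 ms) on the residual
  eye − gain·head; covert if onset ≤ 0.2 s, overt after.  Percentages are
  per-repeat shares (fraction of repeats containing ≥ 1 overt / any
  saccade), one of two readings of the clinical definition; the alternative
  (per-saccade counts) is not implemented.
- **Representative repeat**: the repeat whose coherent frequency is the
  lower median of the exam set (ties: earliest repeat).  It is the patient's
  reported coherent frequency and the trace used for imaging.

## Imaging and classification

Coherence maps are rendered with a fixed viridis [0, 1] color scale (a
bijection up to 8-bit rounding; the decoder recovers values within 1/255),
linear time axis, log₂ frequency axis, no annotations.  Three crop styles —
horizontal 0.1–0.35 s × 4–8 Hz, vertical 0.1–0.2 s × 0–12 Hz, subtotal
0.1–0.3 s × 0–125 Hz — are rasterized at 224² per tile and tiled per patient
in the fixed order horizontal, anterior, posterior (left-to-right, or
top-to-bottom for the vertical style), then resized to the backbone's input.
A log axis cannot reach 0 Hz, so windows quoted down to 0 Hz start at the
grid floor; sub-floor/super-Nyquist frequencies are painted with the
zero-coherence color to preserve window geometry.

The default **backbone is a fixture**: a two-stage random-weight
convolutional stack (seed-fixed; 3→8 5×5/4, 8→16 3×3/2, ReLU, 4×4 average
pooling → 256 features).  Random convolutional features preserve the spatial
layout of the crops — the height of the high-coherence band is the class
signal — and keep the pipeline deterministic with no downloaded artifacts.
Pretrained AlexNet/ResNet-50/VGG-19 plug in behind the same interface when
torchvision is present.  The classifier is a linear SVM (C = 1, z-scored
features, balanced class weights — the raw task is 20 vs 44).  Evaluation is
repeated stratified 5-fold cross-validation (10 repeats by default),
reporting mean [sd] accuracy over folds.

**Augmentation placement.**  By default augmentation (OS/EDE/ITS) is applied
inside each training fold only, so test folds contain only original
patients.  A `pre-split` placement balances the classes once before
splitting — the historically common order in small-cohort studies, kept for
faithful replication — but it lets copies/blends of one patient straddle the
train/test boundary and inflates accuracy accordingly, which is precisely
why augmented variants score at least as well as the raw variant there.

**Controls.**  The label-permutation control is run on the class-balanced
(over-sampled) set, whose chance level is 50%; on the imbalanced raw task
the null accuracy of any majority-leaning classifier is the majority rate
(~69%), which would make "0.5" the wrong reference point.

## Problem sizes

Defaults used by the test suite and the acceptance script: 64 patients × 3
canals × 10 repeats (1,920 coherence maps for a full-cohort analysis; the
acceptance script analyzes the posterior canal, 640 maps), 50 traces per
cutoff for recovery checks, and 5-fold × 10-repeat cross-validation.  These
match the study conditions while keeping a full run in the minutes range on
one CPU.

## Known limitations

- The coherent-frequency scan is grid-quantized (12 voices/octave); all
  recovery statements carry a one-voice tolerance.
- The cutoff calibration constant is tied to the default record geometry
  (0.7 s, onset 0.1 s, Hann pulse, ω₀ = 6, 0.9 threshold).  Changing those
  invalidates the constant, not the method.
- Saccade percentages and the covert/overt split depend on the 60 deg/s
  threshold; very small corrective saccades are invisible to it.
- `pre-split` cross-validation intentionally reproduces an optimistic
  protocol; use the default placement for honest generalization estimates.
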