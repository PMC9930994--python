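# vhitwave

Wavelet-coherence analysis of video head impulse test (vHIT) recordings,
for vestibular otoneurology research: given paired head and eye angular
velocity traces, the package computes the magnitude-squared wavelet
coherence (MSWC), extracts the **coherent frequency** — the highest
frequency at which head and eye stay coherently coupled throughout the exam
— and uses tiled coherence images to classify hearing-recovery outcomes in
sudden sensorineural hearing loss with vertigo (SSNHLV).

## The statistic

For head velocity X and eye velocity Y over a 0.7 s vHIT record (impulse at
0.1–0.2 s, saccades after), MSWC is

```
R²_n(s) = |S(s⁻¹ Wⁿ_XY(s))|² / ( S(s⁻¹|Wⁿ_X(s)|²) · S(s⁻¹|Wⁿ_Y(s)|²) )
```

with W the analytic Morlet CWT (ω₀ = 6), Wⁿ_XY the cross-wavelet spectrum,
and S a time-then-scale smoothing operator.  The coherent frequency scans
grid frequencies upward from the lowest: a frequency qualifies when
R² ≥ 0.9 at every time sample of the exam, and the statistic is the top of
the contiguous qualifying band (0 if none).  A high posterior-canal coherent
frequency indicates a well-synchronized vestibulo-ocular reflex (VOR) and is
associated with complete hearing recovery; it degrades with low VOR gain and
with corrective saccades.

Because no labelled clinical vHIT dataset is public, the package includes a
first-class synthetic cohort generator (`vhitwave.synthetic`) calibrated to
published group statistics: 64 patients (20 complete recovery, 18 partial,
26 none), three semicircular canals, 10 repeats each, with per-class VOR
gain and coupling-cutoff distributions.  See `docs/methods.md` for the
generative model and every numerical choice.

## Worked example

```python
import numpy as np
from vhitwave import simulate_head_impulse, simulate_eye_response, mswc, vor_gain
from vhitwave.traces import ImpulseTrace

rng = np.random.default_rng(42)
head = simulate_head_impulse(5.0, 0.1, 250.0) + 1.5 * rng.standard_normal(175)
eye = simulate_eye_response(head, gain=0.83, coupling_cutoff=5.0,
                            noise_sd=0.15, sampling_rate=250.0, seed=rng)
trace = ImpulseTrace(time=np.arange(175) / 250.0, head_velocity=head,
                     eye_velocity=eye, sampling_rate=250.0, scc="posterior")
cmap = mswc(head, eye, 250.0)
print(f"VOR gain:           {vor_gain(trace):.3f}")
print(f"coherent frequency: {cmap.coherent_frequency:.2f} Hz")
```

prints

```
VOR gain:           0.829
coherent frequency: 4.92 Hz
```

The estimated gain matches the generative gain (0.83), and the recovered
coherent frequency sits within one scale voice (2^(1/12) ≈ 6 %) of the
generated 5 Hz coupling cutoff — the eye tracks the head coherently below
that frequency and is dominated by independent noise above it.

## Command line

```
vhitwave simulate --out traces/ --seed 1          # synthetic cohort (CSV)
vhitwave analyze  --traces traces/ --out analysis/
vhitwave report   --traces traces/ --analysis analysis/ --out features.csv
vhitwave augment  --method its --traces traces/ --analysis analysis/ --out aug/
vhitwave render   --traces traces/ --analysis analysis/ --style horizontal --out img/
vhitwave classify --traces traces/ --style horizontal --augment os --out results.json
```

`classify` extracts features from the per-patient tiled coherence images
with a deterministic fixture backbone (pretrained AlexNet/ResNet-50/VGG-19
are optional torchvision plugins) and cross-validates a linear SVM
(repeated stratified 5-fold).  Minority-class augmentation supports simple
over-sampling (OS), extensive data extraction of extra real repeats (EDE)
and interpolation of time series between subjects (ITS); by default it is
applied inside training folds only.

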