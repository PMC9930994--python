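"""Synthetic vHIT cohort generator.

Emulates the structure of clinical video head impulse test recordings from a
sudden-sensorineural-hearing-loss-with-vertigo (SSNHLV) cohort: bell-shaped
passive head impulses (~5 deg rotation in ~100 ms, onset at 0.1 s of a 0.7 s
record), eye responses coupled to the head through a VOR gain and a
band-limited coupling cutoff, covert/overt corrective saccades, and additive
measurement noise.  Each patient carries exam sets for the three semicircular
canals (>= 10 repeats each) and a hearing-recovery label: complete recovery
(CR), partial (PR) or none (NR).

Class calibration: per-canal VOR-gain and coupling-cutoff distributions for
the incomplete-recovery group follow the printed clinical group statistics;
the CR group's means are back-computed from the whole-cohort means and the
class sizes (20 CR / 44 PR+NR of 64), so the simulated cohort reproduces the
published cohort-level means by construction.

The coupling cutoff is the generative counterpart of the coherent-frequency
statistic: the eye follows the head coherently below the cutoff, while above
it the eye's content is independent noise of matched power.  The head carries
a small broadband tremor so that head-eye coherence is defined at every time
of the record, not only during the impulse.  The eye's head-driven component
is a zero-phase Butterworth low pass of the head, renormalized to preserve
the impulse-window area, so the device-convention (area-ratio) VOR gain of a
noise-free trace equals the generative gain exactly whatever the cutoff.
``CUTOFF_CALIBRATION`` maps the nominal cutoff to the filter corner so that
the downstream wavelet-coherence scan recovers the nominal value without
systematic bias (one constant, fitted once on noise-calibrated traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .traces import (
    IMPULSE_END,
    ONSET_TIME,
    OUTCOMES,
    RECORD_DURATION,
    SCCS,
    ImpulseTrace,
    PatientRecord,
    SaccadeEvent,
)

#: multiplicative corner-frequency correction so that the recovered coherent
#: frequency is centred on the nominal coupling cutoff (see module docstring)
CUTOFF_CALIBRATION = 1.115
#: broadband head "tremor" (residual motion + sensor noise), deg/s; gives the
#: coherence scan something to hold on to outside the impulse
HEAD_TREMOR_SD = 1.5
#: order of the zero-phase Butterworth coupling filter
COUPLING_FILTER_ORDER = 4
#: start of the quiet (post-saccade-window onset) region used to estimate the
#: head's broadband floor when matching the above-cutoff eye noise
QUIET_START = 0.25


def hann_pulse_peak(rotation_amplitude: float, impulse_duration: float) -> float:
    """Closed-form peak velocity of the raised-cosine head profile (deg/s)."""
    return 2.0 * rotation_amplitude / impulse_duration


def simulate_head_impulse(
    rotation_amplitude: float = 5.0,
    impulse_duration: float = 0.1,
    sampling_rate: float = 250.0,
    seed: Optional[int] = None,
    amplitude_jitter: float = 0.0,
    record_duration: float = RECORD_DURATION,
    onset_time: float = ONSET_TIME,
) -> np.ndarray:
    """Raised-cosine (Hann-shaped) head velocity bump over a full record.

    The profile is ``v(t) = (A/D) * (1 - cos(2 pi (t - t0)/D))`` on
    ``[t0, t0 + D)`` and zero elsewhere; its time integral is exactly the
    rotation amplitude ``A`` (rectangle rule on an integer number of pulse
    samples is exact for the cosine term).  ``amplitude_jitter`` optionally
    scales the amplitude by ``N(1, jitter)``.
    """
    if rotation_amplitude <= 0:
        raise ValueError("rotation amplitude must be positive")
    if not (0.0 < impulse_duration <= 0.2):
        raise ValueError("impulse duration must lie in (0, 0.2] s")
    if sampling_rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")

    amp = rotation_amplitude
    if amplitude_jitter > 0:
        rng = np.random.default_rng(seed)
        amp = amp * max(0.1, 1.0 + amplitude_jitter * rng.standard_normal())

    dt = 1.0 / sampling_rate
    n = int(round(record_duration * sampling_rate))
    t = np.arange(n) * dt
    v = np.zeros(n)
    in_pulse = (t >= onset_time) & (t < onset_time + impulse_duration)
    tau = t[in_pulse] - onset_time
    v[in_pulse] = (amp / impulse_duration) * (
        1.0 - np.cos(2.0 * np.pi * tau / impulse_duration)
    )
    return v


def saccade_pulse(
    time: np.ndarray, event: SaccadeEvent
) -> np.ndarray:
    """Gaussian velocity pulse for one saccade (sigma = duration / 6)."""
    sigma = event.duration / 6.0
    center = event.onset + event.duration / 2.0
    return event.peak_velocity * np.exp(-((time - center) ** 2) / (2.0 * sigma**2))


def lowpass_zero_phase(
    signal: np.ndarray,
    cutoff: float,
    sampling_rate: float,
    order: int = COUPLING_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low pass (forward-backward filtering).

    Zero phase keeps eye aligned with head, so the coupling cutoff — not a
    lag — carries the class signal.  A cutoff at (or above) Nyquist is a
    pass-through.
    """
    nyq = sampling_rate / 2.0
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if cutoff >= nyq:
        return np.asarray(signal, dtype=float).copy()
    sos = butter(order, cutoff, fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def highpass_brickwall(
    signal: np.ndarray, cutoff: float, sampling_rate: float
) -> np.ndarray:
    """Zero all Fourier bins at or below ``cutoff`` (for stationary noise)."""
    spec = np.fft.rfft(signal)
    freqs = np.fft.rfftfreq(len(signal), d=1.0 / sampling_rate)
    spec[freqs <= cutoff] = 0.0
    return np.fft.irfft(spec, n=len(signal))


def simulate_eye_response(
    head: np.ndarray,
    gain: float,
    coupling_cutoff: float,
    saccades: Sequence[SaccadeEvent] = (),
    noise_sd: float = 0.0,
    sampling_rate: float = 250.0,
    seed: Optional[int | np.random.Generator] = None,
    onset_time: float = ONSET_TIME,
) -> np.ndarray:
    """Eye velocity coupled to the head below the coupling cutoff.

    eye = gain * LP(head, cutoff) * c  +  above-cutoff noise
          + saccade pulses + floor noise

    where LP is the zero-phase Butterworth coupling filter and ``c``
    renormalizes the impulse-window area lost to filtering, so the
    area-ratio VOR gain of a noise-free trace equals ``gain`` exactly.  The
    above-cutoff noise is white noise high-passed at the cutoff, scaled to
    the head's own broadband floor (estimated from the quiet part of the
    record), so the eye spectrum stays realistic while its content above the
    cutoff is independent of the head — that independence is what the
    coherence scan detects.  ``noise_sd`` adds a broadband measurement-noise
    floor on top.

    A cutoff at Nyquist disables both the filter and the replacement noise:
    the eye is then exactly ``gain * head`` plus saccades and floor noise.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    head = np.asarray(head, dtype=float)
    nyq = sampling_rate / 2.0
    if not (0.0 < coupling_cutoff <= nyq):
        raise ValueError(
            f"coupling cutoff {coupling_cutoff} Hz outside (0, Nyquist={nyq}]"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(len(head)) / sampling_rate

    if coupling_cutoff >= nyq:
        eye = gain * head
    else:
        corner = min(coupling_cutoff * CUTOFF_CALIBRATION, 0.99 * nyq)
        coupled = lowpass_zero_phase(head, corner, sampling_rate)
        window = (t >= onset_time) & (t <= IMPULSE_END)
        area = np.sum(coupled[window])
        if abs(area) > 1e-12:
            coupled = coupled * (np.sum(head[window]) / area)
        eye = gain * coupled
        # independent above-cutoff content, matched to the head's own
        # broadband floor outside the impulse
        floor_sd = float(np.std(head[t >= QUIET_START]))
        if floor_sd > 0:
            eye = eye + gain * floor_sd * highpass_brickwall(
                rng.standard_normal(len(head)), corner, sampling_rate
            )

    for ev in saccades:
        eye = eye + saccade_pulse(t, ev)
    if noise_sd > 0:
        eye = eye + noise_sd * rng.standard_normal(len(head))
    return eye


@dataclass(frozen=True)
class SccClassParams:
    """Per-canal, per-outcome-class generative distribution."""

    gain_mean: float
    gain_sd: float
    cutoff_mean: float          # Hz, between-patient mean of the coupling cutoff
    cutoff_sd: float            # Hz
    p_saccade: float = 0.0      # probability a repeat contains any saccade
    p_overt: float = 0.5        # overt share among saccade-bearing repeats
    saccade_peak_range: tuple[float, float] = (80.0, 250.0)   # deg/s
    noise_sd: float = 0.15      # deg/s, broadband eye measurement-noise floor

    def __post_init__(self) -> None:
        if self.gain_sd < 0 or self.cutoff_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for p in (self.p_saccade, self.p_overt):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout plus per-class, per-canal generative parameters."""

    n_patients: dict[str, int]                      # outcome -> count
    class_params: dict[str, dict[str, SccClassParams]]   # outcome -> scc -> params
    repeats: int = 10
    sampling_rate: float = 250.0
    rotation_amplitude: float = 5.0                 # deg
    impulse_duration: float = 0.1                   # s
    within_gain_sd: float = 0.03                    # repeat-to-repeat gain jitter
    within_cutoff_sd: float = 0.2                   # Hz, repeat-to-repeat jitter
    head_tremor_sd: float = HEAD_TREMOR_SD          # deg/s, broadband head floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for outcome, n in self.n_patients.items():
            if outcome not in OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r}")
            if n < 1:
                raise ValueError(f"class {outcome} has zero patients requested")


# Clinical calibration.  Incomplete-recovery (PR+NR) canal statistics are the
# printed subgroup values (mean +/- sd); CR means are back-computed from the
# whole-cohort means with class sizes 20 / 44.  Saccade probabilities are the
# printed per-repeat saccade percentages of the incomplete group; CR values
# are set lower, consistent with the negative saccade-coherence association.
_INCOMPLETE = {
    "horizontal": SccClassParams(0.96, 0.28, 5.21, 2.03, p_saccade=0.513, p_overt=0.91),
    "anterior":   SccClassParams(0.95, 0.20, 6.32, 1.57, p_saccade=0.114, p_overt=0.22),
    "posterior":  SccClassParams(0.83, 0.30, 4.94, 2.28, p_saccade=0.304, p_overt=0.72),
}
_CR = {
    "horizontal": SccClassParams(1.02, 0.10, 6.30, 1.00, p_saccade=0.20, p_overt=0.75),
    "anterior":   SccClassParams(0.98, 0.10, 6.96, 1.00, p_saccade=0.05, p_overt=0.40),
    "posterior":  SccClassParams(0.99, 0.10, 7.02, 1.00, p_saccade=0.10, p_overt=0.50),
}

#: hard range for realized coupling cutoffs (Hz); keeps draws on the
#: resolvable part of the coherence grid
CUTOFF_RANGE = (2.0, 10.0)
GAIN_FLOOR = 0.05


def default_config(seed: int = 0, repeats: int = 10) -> CohortConfig:
    """The calibrated 64-patient cohort: 20 CR, 18 PR, 26 NR."""
    return CohortConfig(
        n_patients={"CR": 20, "PR": 18, "NR": 26},
        class_params={
            "CR": dict(_CR),
            "PR": dict(_INCOMPLETE),
            "NR": dict(_INCOMPLETE),
        },
        repeats=repeats,
        seed=seed,
    )


def simulate_exam_set(
    scc: str,
    class_params: SccClassParams,
    repeats: int,
    seed: int | np.random.Generator,
    sampling_rate: float = 250.0,
    rotation_amplitude: float = 5.0,
    impulse_duration: float = 0.1,
    head_tremor_sd: float = HEAD_TREMOR_SD,
) -> list[ImpulseTrace]:
    """One canal's repeat set; per-repeat parameters drawn i.i.d. from the class.

    Every trace records its ground truth (gain, cutoff, saccades, noise sd)
    in ``true_params``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if scc not in SCCS:
        raise ValueError(f"unknown SCC {scc!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    traces = []
    for _ in range(repeats):
        gain = max(GAIN_FLOOR, rng.normal(class_params.gain_mean, class_params.gain_sd))
        cutoff = float(
            np.clip(
                rng.normal(class_params.cutoff_mean, class_params.cutoff_sd),
                *CUTOFF_RANGE,
            )
        )
        saccades = _draw_saccades(rng, class_params)
        head = simulate_head_impulse(
            rotation_amplitude, impulse_duration, sampling_rate
        )
        if head_tremor_sd > 0:
            head = head + head_tremor_sd * rng.standard_normal(len(head))
        eye = simulate_eye_response(
            head,
            gain=gain,
            coupling_cutoff=cutoff,
            saccades=saccades,
            noise_sd=class_params.noise_sd,
            sampling_rate=sampling_rate,
            seed=rng,
        )
        n = len(head)
        traces.append(
            ImpulseTrace(
                time=np.arange(n) / sampling_rate,
                head_velocity=head,
                eye_velocity=eye,
                sampling_rate=sampling_rate,
                scc=scc,
                true_params={
                    "gain": gain,
                    "coupling_cutoff_hz": cutoff,
                    "noise_sd": class_params.noise_sd,
                    "saccades": list(saccades),
                },
            )
        )
    return traces


def _draw_saccades(
    rng: np.random.Generator, params: SccClassParams
) -> list[SaccadeEvent]:
    if rng.random() >= params.p_saccade:
        return []
    lo, hi = params.saccade_peak_range
    events = []
    overt = rng.random() < params.p_overt
    if overt:
        onset = rng.uniform(0.22, 0.50)
        kind = "overt"
    else:
        onset = rng.uniform(0.12, 0.19)
        kind = "covert"
    events.append(
        SaccadeEvent(
            onset=onset,
            duration=rng.uniform(0.03, 0.06),
            peak_velocity=rng.uniform(lo, hi),
            kind=kind,
        )
    )
    # occasionally a second, later overt saccade
    if rng.random() < 0.25:
        events.append(
            SaccadeEvent(
                onset=rng.uniform(max(0.3, onset + 0.08), 0.6),
                duration=rng.uniform(0.03, 0.06),
                peak_velocity=rng.uniform(lo, hi),
                kind="overt",
            )
        )
    return sorted(events, key=lambda e: e.onset)


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the full cohort, deterministically from ``config.seed``.

    Patient-level gains and cutoffs are drawn from the class (between-patient)
    distributions; repeats within an exam then jitter around the patient's
    values with the small within-patient sds, mirroring test-retest
    variability of the instrument.
    """
    total = sum(config.n_patients.values())
    streams = np.random.SeedSequence(config.seed).spawn(total)
    patients: list[PatientRecord] = []
    idx = 0
    for outcome in ("CR", "PR", "NR"):
        if outcome not in config.n_patients:
            continue
        for _ in range(config.n_patients[outcome]):
            rng = np.random.default_rng(streams[idx])
            pid = f"P{idx:03d}"
            idx += 1
            exams: dict[str, list[ImpulseTrace]] = {}
            for scc in SCCS:
                cp = config.class_params[outcome][scc]
                patient_gain = max(GAIN_FLOOR, rng.normal(cp.gain_mean, cp.gain_sd))
                patient_cutoff = float(
                    np.clip(rng.normal(cp.cutoff_mean, cp.cutoff_sd), *CUTOFF_RANGE)
                )
                per_repeat = replace(
                    cp,
                    gain_mean=patient_gain,
                    gain_sd=config.within_gain_sd,
                    cutoff_mean=patient_cutoff,
                    cutoff_sd=config.within_cutoff_sd,
                )
                exams[scc] = simulate_exam_set(
                    scc,
                    per_repeat,
                    config.repeats,
                    seed=rng,
                    sampling_rate=config.sampling_rate,
                    rotation_amplitude=config.rotation_amplitude,
                    impulse_duration=config.impulse_duration,
                    head_tremor_sd=config.head_tremor_sd,
                )
            patients.append(PatientRecord(patient_id=pid, outcome=outcome, exams=exams))
    return patients
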