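"""Time-series vHIT features and the per-patient feature table.

VOR gain, saccade detection on the residual eye velocity, per-exam saccade
percentages, representative-repeat selection by median coherent frequency,
and Spearman rank correlation for the feature table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traces import IMPULSE_END, ImpulseTrace, PatientRecord, SaccadeEvent

#: residual-velocity threshold for saccade detection, deg/s
SACCADE_THRESHOLD = 60.0
#: minimum saccade duration, s
SACCADE_MIN_DURATION = 0.010


def vor_gain(
    trace: ImpulseTrace,
    method: str = "area",
    exclude_saccades: bool = True,
) -> float:
    """VOR gain: ratio of the eye response to the head impulse.

    ``method="area"`` (default) is the ratio of the areas under eye and head
    velocity over the impulse window [0.1, 0.2] s, with samples inside
    detected saccades excised from both series; this is the convention of
    clinical vHIT devices and is robust to single-sample peaks.
    ``method="peak"`` is the simple peak-velocity ratio.
    """
    mask = trace.impulse_mask()
    head = trace.head_velocity[mask]
    eye = trace.eye_velocity[mask]
    if np.max(np.abs(head)) <= 0:
        raise ValueError("flat head trace: no impulse to compute gain against")
    if method == "peak":
        return float(np.max(eye) / np.max(head))
    if method != "area":
        raise ValueError(f"unknown gain method {method!r}")

    if exclude_saccades:
        # provisional least-squares gain for the residual, then excise
        provisional = float(np.dot(eye, head) / np.dot(head, head))
        events = detect_saccades(trace, provisional)
        t = trace.time[mask]
        keep = np.ones(len(t), dtype=bool)
        pad = 0.012  # s; catches sub-threshold saccade tails
        for ev in events:
            keep &= ~((t >= ev.onset - pad) & (t <= ev.onset + ev.duration + pad))
        if keep.sum() >= 3 and np.sum(head[keep]) > 0:
            head, eye = head[keep], eye[keep]
    return float(np.sum(eye) / np.sum(head))


def detect_saccades(
    trace: ImpulseTrace,
    gain_estimate: float,
    threshold: float = SACCADE_THRESHOLD,
    min_duration: float = SACCADE_MIN_DURATION,
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection on the residual eye trace.

    The residual ``eye - gain * head`` removes the VOR-driven component;
    contiguous runs where its magnitude exceeds ``threshold`` for at least
    ``min_duration`` are saccades, labelled covert when they start during
    the impulse (onset <= 0.2 s) and overt after.
    """
    residual = trace.eye_velocity - gain_estimate * trace.head_velocity
    above = np.abs(residual) > threshold
    dt = 1.0 / trace.sampling_rate
    min_len = max(1, int(round(min_duration / dt)))

    events: list[SaccadeEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_len:
            continue
        onset = float(trace.time[start])
        duration = float((stop - start) * dt)
        peak = float(np.max(np.abs(residual[start:stop])))
        kind = "covert" if onset <= IMPULSE_END else "overt"
        events.append(
            SaccadeEvent(onset=onset, duration=duration, peak_velocity=peak, kind=kind)
        )
    return events


def saccade_percentages(exams: Sequence[ImpulseTrace]) -> tuple[float, float]:
    """(overt %, total %): share of repeats containing >= 1 overt / any saccade."""
    if not exams:
        raise ValueError("empty exam list")
    n = len(exams)
    n_overt = 0
    n_any = 0
    for tr in exams:
        g = vor_gain(tr, exclude_saccades=False)
        events = detect_saccades(tr, g)
        if events:
            n_any += 1
        if any(ev.kind == "overt" for ev in events):
            n_overt += 1
    return 100.0 * n_overt / n, 100.0 * n_any / n


def select_representative(
    repeats: Sequence[tuple[ImpulseTrace, float]]
) -> tuple[ImpulseTrace, float]:
    """The repeat whose coherent frequency is the (lower) median of the set.

    Even-sized sets take the lower median; ties take the earliest repeat.
    Returns the chosen (trace, coherent_frequency) pair.
    """
    if not repeats:
        raise ValueError("empty repeat list")
    freqs = [f for _, f in repeats]
    order = np.argsort(freqs, kind="stable")
    median_idx = order[(len(freqs) - 1) // 2]     # lower median
    target = freqs[median_idx]
    for tr, f in repeats:                          # earliest repeat on ties
        if f == target:
            return tr, f
    raise AssertionError("unreachable")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class FeatureRow:
    """One patient x canal entry of the feature table."""

    patient_id: str
    outcome: str
    scc: str
    vor_gain: float
    overt_saccade_pct: float
    total_saccade_pct: float
    coherent_freq_hz: float


def build_feature_table(
    cohort: Sequence[PatientRecord],
    coherent_freqs: dict[str, dict[str, list[float]]],
) -> pd.DataFrame:
    """Assemble the per-patient, per-canal feature table.

    ``coherent_freqs`` maps patient_id -> scc -> per-repeat coherent
    frequencies (aligned with the exam's repeat order).  The reported
    coherent frequency is the representative (lower-median) repeat's value;
    VOR gain is the median over repeats, which discards the occasional
    repeat whose gain estimate is contaminated by a covert saccade
    overlapping the impulse (the clinical analogue is operator rejection of
    artifacted impulses).
    """
    rows: list[FeatureRow] = []
    for patient in cohort:
        if patient.patient_id not in coherent_freqs:
            raise ValueError(f"missing coherence results for {patient.patient_id}")
        for scc, reps in patient.exams.items():
            try:
                freqs = coherent_freqs[patient.patient_id][scc]
            except KeyError:
                raise ValueError(
                    f"patient {patient.patient_id}: missing {scc} analysis"
                ) from None
            _, med_freq = select_representative(list(zip(reps, freqs)))
            gain = float(np.median([vor_gain(tr) for tr in reps]))
            overt_pct, total_pct = saccade_percentages(reps)
            rows.append(
                FeatureRow(
                    patient_id=patient.patient_id,
                    outcome=patient.outcome,
                    scc=scc,
                    vor_gain=gain,
                    overt_saccade_pct=overt_pct,
                    total_saccade_pct=total_pct,
                    coherent_freq_hz=med_freq,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
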