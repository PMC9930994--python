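"""Minority-class augmentation for the CR vs PR+NR classification task.

Three schemes balance the complete-recovery (CR) minority, each operating on
per-patient samples (one representative impulse trace per semicircular
canal):

* OS  — simple over-sampling: random copies of existing CR samples.
* EDE — extensive data extraction: extra *real* repeats, per canal the one
  whose coherent frequency is closest to the representative repeat's, cycled
  round-robin over patients.
* ITS — interpolation of time series: convex blends ``lam*a + (1-lam)*b``
  of two distinct CR subjects' traces, one shared weight per synthetic
  sample across all canals and both velocity channels.

Wavelet coherence is recomputed on every augmented sample downstream; the
augmenters only produce traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .traces import SCCS, ImpulseTrace, PatientRecord
from .features import select_representative


@dataclass
class Sample:
    """One classification sample: a per-patient triplet of canal traces."""

    key: str                              # unique id (cache key)
    patient_id: str
    label: str                            # "CR" | "PR+NR"
    traces: dict[str, ImpulseTrace]       # scc -> representative trace
    provenance: dict = field(default_factory=lambda: {"kind": "original"})

    def __post_init__(self) -> None:
        if set(self.traces) != set(SCCS):
            raise ValueError(f"sample {self.key}: needs all three SCC traces")

    @property
    def is_original(self) -> bool:
        return self.provenance.get("kind") == "original"


@dataclass
class AugmentedSet:
    """Minority samples brought up to the target size, with provenance."""

    samples: list[Sample]
    method: str

    def provenance_ledger(self) -> list[dict]:
        return [
            {"key": s.key, "patient_id": s.patient_id, **s.provenance}
            for s in self.samples
        ]


def augment_os(
    minority: Sequence[Sample], target_n: int, seed: int
) -> AugmentedSet:
    """Simple over-sampling: append random-with-replacement copies."""
    minority = list(minority)
    if not minority:
        raise ValueError("empty minority class")
    if target_n < len(minority):
        raise ValueError(
            f"target {target_n} below current size {len(minority)}"
        )
    rng = np.random.default_rng(seed)
    out = list(minority)
    for i in range(target_n - len(minority)):
        parent = minority[rng.integers(len(minority))]
        out.append(
            Sample(
                key=parent.key,          # identical data: share the cache key
                patient_id=parent.patient_id,
                label=parent.label,
                traces=parent.traces,
                provenance={"kind": "os-copy", "parents": [parent.key]},
            )
        )
    return AugmentedSet(samples=out, method="os")


def augment_ede(
    patients: Sequence[PatientRecord],
    coherent_freqs: dict[str, dict[str, list[float]]],
    target_n: int,
    labels: Optional[dict[str, str]] = None,
) -> AugmentedSet:
    """Extensive data extraction: extra samples are real non-representative
    repeats, per canal the one with coherent frequency closest to the
    representative's (ties: earliest repeat), patients cycled round-robin.

    ``coherent_freqs`` maps patient_id -> scc -> per-repeat coherent
    frequencies.  Deterministic: no randomness is involved.
    """
    patients = list(patients)
    if not patients:
        raise ValueError("empty minority class")

    # representative index and candidate ranking per patient and canal
    rep_samples: list[Sample] = []
    rankings: dict[str, dict[str, list[int]]] = {}
    for p in patients:
        traces = {}
        rankings[p.patient_id] = {}
        for scc in SCCS:
            freqs = coherent_freqs[p.patient_id][scc]
            reps = p.exams[scc]
            rep_trace, rep_freq = select_representative(list(zip(reps, freqs)))
            traces[scc] = rep_trace
            rep_idx = next(
                i for i, tr in enumerate(reps) if tr is rep_trace
            )
            others = [i for i in range(len(reps)) if i != rep_idx]
            # closest coherent frequency to the representative's; earliest on ties
            others.sort(key=lambda i: (abs(freqs[i] - rep_freq), i))
            rankings[p.patient_id][scc] = others
        label = labels[p.patient_id] if labels else (
            "CR" if p.outcome == "CR" else "PR+NR"
        )
        rep_samples.append(
            Sample(
                key=f"{p.patient_id}/rep",
                patient_id=p.patient_id,
                label=label,
                traces=traces,
            )
        )

    if target_n < len(rep_samples):
        raise ValueError(f"target {target_n} below current size {len(rep_samples)}")
    n_extra = target_n - len(rep_samples)
    max_spare = max(len(r["horizontal"]) for r in rankings.values())
    out = list(rep_samples)
    produced = 0
    for round_i in range(max_spare):
        if produced >= n_extra:
            break
        for p in patients:
            if produced >= n_extra:
                break
            ranks = rankings[p.patient_id]
            if any(round_i >= len(ranks[scc]) for scc in SCCS):
                continue      # patient exhausted: skip in this round
            traces = {
                scc: p.exams[scc][ranks[scc][round_i]] for scc in SCCS
            }
            out.append(
                Sample(
                    key=f"{p.patient_id}/ede{round_i}",
                    patient_id=p.patient_id,
                    label=out[0].label if labels is None else labels[p.patient_id],
                    traces=traces,
                    provenance={
                        "kind": "ede-extract",
                        "parents": [f"{p.patient_id}/rep"],
                        "round": round_i,
                    },
                )
            )
            produced += 1
    if produced < n_extra:
        raise ValueError(
            f"not enough spare repeats: produced {produced} of {n_extra} extras"
        )
    return AugmentedSet(samples=out, method="ede")


def blend_traces(a: ImpulseTrace, b: ImpulseTrace, lam: float) -> ImpulseTrace:
    """Pointwise convex combination of two repeats (head and eye channels)."""
    if a.scc != b.scc or len(a.time) != len(b.time):
        raise ValueError("can only blend traces of the same canal and length")
    return ImpulseTrace(
        time=a.time.copy(),
        head_velocity=lam * a.head_velocity + (1 - lam) * b.head_velocity,
        eye_velocity=lam * a.eye_velocity + (1 - lam) * b.eye_velocity,
        sampling_rate=a.sampling_rate,
        scc=a.scc,
        true_params={"blend_weight": lam},
    )


def augment_its(
    minority: Sequence[Sample], target_n: int, seed: int
) -> AugmentedSet:
    """Interpolation of time series between different subjects.

    Each synthetic sample blends two distinct subjects' trace triplets with
    one weight ``lam ~ Uniform(0, 1)`` shared across the three canals and
    both channels.  Parent pairs are drawn uniformly, avoiding drawing the
    same (unordered) pair twice in a row.
    """
    minority = list(minority)
    if len(minority) < 2:
        raise ValueError("ITS needs at least two minority subjects")
    if target_n < len(minority):
        raise ValueError(f"target {target_n} below current size {len(minority)}")
    rng = np.random.default_rng(seed)
    out = list(minority)
    last_pair: Optional[frozenset] = None
    for i in range(target_n - len(minority)):
        while True:
            ia, ib = rng.choice(len(minority), size=2, replace=False)
            pair = frozenset((int(ia), int(ib)))
            if pair != last_pair:
                break
        last_pair = pair
        a, b = minority[int(ia)], minority[int(ib)]
        lam = float(rng.uniform())
        traces = {scc: blend_traces(a.traces[scc], b.traces[scc], lam) for scc in SCCS}
        out.append(
            Sample(
                key=f"its{i}({a.key}|{b.key})",
                patient_id=f"its{i}",
                label=a.label,
                traces=traces,
                provenance={
                    "kind": "its-blend",
                    "parents": [a.key, b.key],
                    "weight": lam,
                },
            )
        )
    return AugmentedSet(samples=out, method="its")
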