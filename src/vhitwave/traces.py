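"""Domain containers for vHIT recordings.

A video head impulse test (vHIT) repeat is a 0.7 s record of paired head and
eye angular velocities (deg/s).  Device convention: the onset of the passive
head rotation is relocated to 0.1 s in the timeline, so the impulse occupies
0.1-0.2 s and corrective saccades the remaining 0.2-0.7 s.  Eye traces are
stored sign-rectified (the vestibulo-ocular reflex drives the eye opposite
the head; devices display both as positive), so VOR gain is a positive ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: canonical record length in seconds
RECORD_DURATION = 0.7
#: head-rotation onset in the device timeline, seconds
ONSET_TIME = 0.1
#: end of the impulse window in the device timeline, seconds
IMPULSE_END = 0.2

SCCS = ("horizontal", "anterior", "posterior")
OUTCOMES = ("CR", "PR", "NR")


@dataclass(frozen=True)
class SaccadeEvent:
    """A corrective saccade: covert if it starts during the impulse
    (onset in [0.1, 0.2] s), overt if after (onset in (0.2, 0.7] s)."""

    onset: float           # s
    duration: float        # s
    peak_velocity: float   # deg/s
    kind: str              # "covert" | "overt"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("saccade duration must be positive")
        if self.kind not in ("covert", "overt"):
            raise ValueError(f"unknown saccade kind {self.kind!r}")


@dataclass
class ImpulseTrace:
    """One vHIT repeat: paired head/eye angular-velocity series.

    ``true_params`` optionally carries generator ground truth (gain,
    saccades, coupling cutoff, noise sd) for synthetic traces.
    """

    time: np.ndarray             # s, uniform over [0, 0.7]
    head_velocity: np.ndarray    # deg/s
    eye_velocity: np.ndarray     # deg/s, sign-rectified
    sampling_rate: float         # Hz
    scc: str                     # "horizontal" | "anterior" | "posterior"
    onset_time: float = ONSET_TIME
    true_params: Optional[dict] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.head_velocity = np.asarray(self.head_velocity, dtype=float)
        self.eye_velocity = np.asarray(self.eye_velocity, dtype=float)
        n = len(self.time)
        if len(self.head_velocity) != n or len(self.eye_velocity) != n:
            raise ValueError("time, head and eye series must share length")
        if self.scc not in SCCS:
            raise ValueError(f"unknown SCC {self.scc!r}")
        dt = 1.0 / self.sampling_rate
        if abs(self.duration - RECORD_DURATION) > dt + 1e-12:
            raise ValueError(
                f"record spans {self.duration:.4f} s; expected "
                f"{RECORD_DURATION} s within one sample"
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def impulse_mask(self) -> np.ndarray:
        """Boolean mask of the impulse window [onset, onset+0.1] s."""
        return (self.time >= self.onset_time) & (self.time <= IMPULSE_END)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "head_velocity_dps": self.head_velocity,
                "eye_velocity_dps": self.eye_velocity,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        scc: str,
        sampling_rate: Optional[float] = None,
        true_params: Optional[dict] = None,
    ) -> "ImpulseTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if sampling_rate is None:
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(
            time=t,
            head_velocity=df["head_velocity_dps"].to_numpy(),
            eye_velocity=df["eye_velocity_dps"].to_numpy(),
            sampling_rate=sampling_rate,
            scc=scc,
            true_params=true_params,
        )


@dataclass
class PatientRecord:
    """Per-patient exam sets: one list of repeats per semicircular canal."""

    patient_id: str
    outcome: str                              # "CR" | "PR" | "NR"
    exams: dict[str, list[ImpulseTrace]]      # scc -> repeats
    derived: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if set(self.exams) != set(SCCS):
            raise ValueError(
                f"patient {self.patient_id}: exams must cover exactly "
                f"{SCCS}, got {sorted(self.exams)}"
            )
        for scc, reps in self.exams.items():
            if not reps:
                raise ValueError(
                    f"patient {self.patient_id}: empty repeat set for {scc}"
                )

    @property
    def binary_label(self) -> str:
        """Collapse outcomes to the classification target: CR vs PR+NR."""
        return "CR" if self.outcome == "CR" else "PR+NR"

    def save(self, directory: str | Path) -> None:
        """Write one CSV per repeat plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta: dict = {
            "patient_id": self.patient_id,
            "outcome": self.outcome,
            "sampling_rate": None,
            "repeats": {},
        }
        for scc, reps in self.exams.items():
            files = []
            for i, tr in enumerate(reps):
                fname = f"{self.patient_id}_{scc}_{i:02d}.csv"
                tr.to_csv(directory / fname)
                files.append(
                    {"file": fname, "true_params": _jsonable(tr.true_params)}
                )
                meta["sampling_rate"] = tr.sampling_rate
            meta["repeats"][scc] = files
        with open(directory / f"{self.patient_id}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory: str | Path, patient_id: str) -> "PatientRecord":
        directory = Path(directory)
        with open(directory / f"{patient_id}.json") as fh:
            meta = json.load(fh)
        exams: dict[str, list[ImpulseTrace]] = {}
        for scc, files in meta["repeats"].items():
            exams[scc] = [
                ImpulseTrace.from_csv(
                    directory / f["file"],
                    scc=scc,
                    sampling_rate=meta["sampling_rate"],
                    true_params=f.get("true_params"),
                )
                for f in files
            ]
        return cls(patient_id=meta["patient_id"], outcome=meta["outcome"], exams=exams)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and dataclasses for JSON."""
    if obj is None:
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, SaccadeEvent):
        return asdict(obj)
    return obj
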