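import numpy as np
import pytest

from vhitwave.synthetic import (
    CohortConfig,
    SccClassParams,
    simulate_cohort,
    simulate_head_impulse,
)
from vhitwave.traces import ImpulseTrace

FS = 250.0


def make_trace(
    head: np.ndarray,
    eye: np.ndarray,
    scc: str = "posterior",
    sampling_rate: float = FS,
    true_params=None,
) -> ImpulseTrace:
    n = len(head)
    return ImpulseTrace(
        time=np.arange(n) / sampling_rate,
        head_velocity=head,
        eye_velocity=eye,
        sampling_rate=sampling_rate,
        scc=scc,
        true_params=true_params,
    )


@pytest.fixture(scope="session")
def head_pulse() -> np.ndarray:
    return simulate_head_impulse(5.0, 0.1, FS)


def tiny_config(seed: int = 0, repeats: int = 3, n=(2, 2, 2)) -> CohortConfig:
    """A small cohort for structural tests (not calibrated)."""
    params = SccClassParams(0.9, 0.05, 6.0, 0.5, p_saccade=0.2)
    by_scc = {scc: params for scc in ("horizontal", "anterior", "posterior")}
    return CohortConfig(
        n_patients={"CR": n[0], "PR": n[1], "NR": n[2]},
        class_params={"CR": by_scc, "PR": by_scc, "NR": by_scc},
        repeats=repeats,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_config())
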