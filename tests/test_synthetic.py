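"""Generator contracts: impulse shape, eye coupling, exam sets, cohorts."""

import io

import numpy as np
import pytest

from vhitwave.coherence import mswc
from vhitwave.features import vor_gain
from vhitwave.synthetic import (
    SccClassParams,
    default_config,
    hann_pulse_peak,
    simulate_cohort,
    simulate_exam_set,
    simulate_eye_response,
    simulate_head_impulse,
)
from vhitwave.traces import RECORD_DURATION, SCCS

from conftest import FS, make_trace, tiny_config


class TestHeadImpulse:
    def test_integral_equals_rotation_amplitude(self):
        v = simulate_head_impulse(5.0, 0.1, FS)
        assert np.sum(v) / FS == pytest.approx(5.0, abs=0.25)

    @pytest.mark.parametrize("amp,dur,fs", [(3.0, 0.08, 250.0), (7.5, 0.15, 500.0)])
    def test_integral_exact_for_other_parameters(self, amp, dur, fs):
        v = simulate_head_impulse(amp, dur, fs)
        assert np.sum(v) / fs == pytest.approx(amp, rel=0.05)

    def test_peak_matches_closed_form(self):
        # at 500 Hz the 0.1 s pulse has an even number of samples, so the
        # profile is sampled exactly at its maximum
        v = simulate_head_impulse(5.0, 0.1, 500.0)
        assert v.max() == pytest.approx(hann_pulse_peak(5.0, 0.1), rel=1e-12)

    def test_zero_outside_pulse(self):
        v = simulate_head_impulse(5.0, 0.1, FS)
        t = np.arange(len(v)) / FS
        assert np.all(v[(t < 0.1) | (t >= 0.2)] == 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rotation_amplitude": 0.0},
            {"rotation_amplitude": -1.0},
            {"impulse_duration": 0.0},
            {"impulse_duration": 0.3},
            {"sampling_rate": 50.0},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            simulate_head_impulse(**{"rotation_amplitude": 5.0, **kwargs})


class TestEyeResponse:
    def test_identity_at_nyquist_unit_gain(self, head_pulse):
        eye = simulate_eye_response(head_pulse, 1.0, FS / 2, noise_sd=0.0, seed=0)
        np.testing.assert_array_equal(eye, head_pulse)

    def test_pure_scaling_at_nyquist(self, head_pulse):
        eye = simulate_eye_response(head_pulse, 0.8, FS / 2, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(eye, 0.8 * head_pulse, rtol=0, atol=1e-12)

    def test_cutoff_above_nyquist_raises(self, head_pulse):
        with pytest.raises(ValueError):
            simulate_eye_response(head_pulse, 1.0, FS, sampling_rate=FS)

    def test_negative_gain_raises(self, head_pulse):
        with pytest.raises(ValueError):
            simulate_eye_response(head_pulse, -0.1, 6.0)

    def test_coherent_frequency_tracks_cutoff(self, head_pulse):
        """Generated cutoff of 6 Hz is recovered within one scale voice
        (median over seeds) by the downstream coherence scan."""
        rec = []
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            head = head_pulse + 1.5 * rng.standard_normal(len(head_pulse))
            eye = simulate_eye_response(
                head, 0.8, 6.0, noise_sd=0.15, sampling_rate=FS, seed=rng
            )
            rec.append(mswc(head, eye, FS).coherent_frequency)
        med = np.median(rec)
        assert 6.0 * 2 ** (-1 / 12) <= med <= 6.0 * 2 ** (1 / 12)


class TestExamSet:
    PARAMS = SccClassParams(0.88, 0.05, 6.0, 0.5, p_saccade=0.3)

    def test_repeat_count_and_labels(self):
        traces = simulate_exam_set("anterior", self.PARAMS, 10, seed=1)
        assert len(traces) == 10
        for tr in traces:
            assert tr.scc == "anterior"
            assert tr.duration == pytest.approx(RECORD_DURATION, abs=1 / FS)

    def test_determinism_bitwise(self):
        a = simulate_exam_set("posterior", self.PARAMS, 5, seed=42)
        b = simulate_exam_set("posterior", self.PARAMS, 5, seed=42)
        for ta, tb in zip(a, b):
            bufs = []
            for tr in (ta, tb):
                buf = io.StringIO()
                tr.to_frame().to_csv(buf, index=False)
                bufs.append(buf.getvalue())
            assert bufs[0] == bufs[1]

    def test_true_gain_sample_mean(self):
        """Monte-Carlo: 500 repeats drawn from N(0.88, 0.05) recover the mean."""
        traces = simulate_exam_set("posterior", self.PARAMS, 500, seed=7)
        gains = [tr.true_params["gain"] for tr in traces]
        se = 0.05 / np.sqrt(500)
        assert np.mean(gains) == pytest.approx(0.88, abs=2 * se)

    def test_trace_invariants_across_random_configs(self):
        rng = np.random.default_rng(0)
        for i in range(100):
            params = SccClassParams(
                gain_mean=rng.uniform(0.3, 1.2),
                gain_sd=rng.uniform(0, 0.3),
                cutoff_mean=rng.uniform(2.5, 9.5),
                cutoff_sd=rng.uniform(0, 2.0),
                p_saccade=rng.uniform(0, 1),
                p_overt=rng.uniform(0, 1),
            )
            tr = simulate_exam_set("horizontal", params, 1, seed=i)[0]
            assert len(tr.head_velocity) == len(tr.eye_velocity) == len(tr.time)
            assert tr.onset_time == 0.1
            assert abs(tr.duration - RECORD_DURATION) <= 1 / FS
            # impulse-window integral ~ rotation amplitude (tremor is tiny there)
            win = tr.impulse_mask()
            assert np.sum(tr.head_velocity[win]) / FS == pytest.approx(5.0, rel=0.05)

    def test_gain_recovery_noise_free(self):
        """vor_gain returns the generative gain to 1e-6 on clean traces."""
        rng = np.random.default_rng(3)
        pulse = simulate_head_impulse(5.0, 0.1, FS)
        for _ in range(100):
            g = rng.uniform(0.2, 1.3)
            fc = rng.uniform(3.0, 100.0)
            eye = simulate_eye_response(pulse, g, fc, noise_sd=0.0, seed=0)
            tr = make_trace(pulse, eye)
            assert vor_gain(tr) == pytest.approx(g, abs=1e-6)


class TestCohort:
    def test_default_cohort_layout(self):
        cohort = simulate_cohort(default_config(seed=0))
        assert len(cohort) == 64
        counts = {o: sum(p.outcome == o for p in cohort) for o in ("CR", "PR", "NR")}
        assert counts == {"CR": 20, "PR": 18, "NR": 26}
        for p in cohort:
            assert set(p.exams) == set(SCCS)
            assert all(len(reps) == 10 for reps in p.exams.values())

    def test_one_patient_per_class(self):
        cohort = simulate_cohort(tiny_config(n=(1, 1, 1)))
        assert len(cohort) == 3

    def test_zero_patients_in_class_raises(self):
        with pytest.raises(ValueError):
            tiny_config(n=(0, 1, 1))

    def test_same_seed_identical_cohorts(self):
        a = simulate_cohort(tiny_config(seed=9))
        b = simulate_cohort(tiny_config(seed=9))
        for pa, pb in zip(a, b):
            assert pa.patient_id == pb.patient_id and pa.outcome == pb.outcome
            for scc in SCCS:
                for ta, tb in zip(pa.exams[scc], pb.exams[scc]):
                    np.testing.assert_array_equal(ta.head_velocity, tb.head_velocity)
                    np.testing.assert_array_equal(ta.eye_velocity, tb.eye_velocity)

    def test_class_conditional_cutoff_structure(self):
        """Posterior coupling cutoffs are lower in incomplete recovery than CR."""
        cohort = simulate_cohort(default_config(seed=5))
        cr, inc = [], []
        for p in cohort:
            cuts = [tr.true_params["coupling_cutoff_hz"] for tr in p.exams["posterior"]]
            (cr if p.outcome == "CR" else inc).append(np.mean(cuts))
        assert np.mean(inc) < np.mean(cr)

    def test_roundtrip_serialization(self, tiny_cohort, tmp_path):
        from vhitwave.traces import PatientRecord

        p = tiny_cohort[0]
        p.save(tmp_path)
        loaded = PatientRecord.load(tmp_path, p.patient_id)
        assert loaded.outcome == p.outcome
        for scc in SCCS:
            for ta, tb in zip(p.exams[scc], loaded.exams[scc]):
                np.testing.assert_allclose(ta.eye_velocity, tb.eye_velocity, rtol=1e-9)
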