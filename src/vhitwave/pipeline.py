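"""End-to-end glue: cohort -> coherence analysis -> samples -> images -> CV.

The expensive step is the per-repeat wavelet coherence (each patient has
three canals x >= 10 repeats).  ``analyze_cohort`` computes every repeat's
coherent frequency once; coherence maps for classification are computed
lazily per sample and memoized by sample key, so over-sampled copies reuse
their parent's features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentedSet, Sample, augment_ede, augment_its, augment_os
from .classify import CVConfig, CVResult, extract_features, get_backbone, repeated_stratified_cv
from .coherence import CoherenceMap, WaveletGrid, mswc
from .features import select_representative
from .imaging import CROP_STYLES, CropStyle, TiledImage, crop_and_tile
from .traces import SCCS, PatientRecord


@dataclass
class CohortAnalysis:
    """Per-repeat coherent frequencies for a whole cohort."""

    coherent_freqs: dict[str, dict[str, list[float]]]   # pid -> scc -> per-repeat
    threshold: float = 0.9

    def representative_freq(self, patient: PatientRecord, scc: str) -> float:
        reps = patient.exams[scc]
        freqs = self.coherent_freqs[patient.patient_id][scc]
        _, f = select_representative(list(zip(reps, freqs)))
        return f


def analyze_cohort(
    cohort: Sequence[PatientRecord],
    threshold: float = 0.9,
    grid: Optional[WaveletGrid] = None,
) -> CohortAnalysis:
    """Coherent frequency of every repeat of every canal of every patient."""
    out: dict[str, dict[str, list[float]]] = {}
    for patient in cohort:
        out[patient.patient_id] = {}
        for scc, reps in patient.exams.items():
            out[patient.patient_id][scc] = [
                mswc(
                    tr.head_velocity,
                    tr.eye_velocity,
                    tr.sampling_rate,
                    grid=grid,
                    threshold=threshold,
                ).coherent_frequency
                for tr in reps
            ]
    return CohortAnalysis(coherent_freqs=out, threshold=threshold)


def cohort_samples(
    cohort: Sequence[PatientRecord], analysis: CohortAnalysis
) -> list[Sample]:
    """One original sample per patient: the representative repeat per canal."""
    samples = []
    for patient in cohort:
        traces = {}
        for scc in SCCS:
            reps = patient.exams[scc]
            freqs = analysis.coherent_freqs[patient.patient_id][scc]
            tr, _ = select_representative(list(zip(reps, freqs)))
            traces[scc] = tr
        samples.append(
            Sample(
                key=f"{patient.patient_id}/rep",
                patient_id=patient.patient_id,
                label=patient.binary_label,
                traces=traces,
            )
        )
    return samples


def augment_minority(
    method: str,
    cohort: Sequence[PatientRecord],
    analysis: CohortAnalysis,
    samples: Sequence[Sample],
    seed: int = 0,
) -> AugmentedSet:
    """Bring the CR minority up to the PR+NR majority size by one scheme."""
    minority = [s for s in samples if s.label == "CR"]
    majority_n = sum(1 for s in samples if s.label != "CR")
    if method == "os":
        return augment_os(minority, majority_n, seed=seed)
    if method == "its":
        return augment_its(minority, majority_n, seed=seed)
    if method == "ede":
        cr_patients = [p for p in cohort if p.outcome == "CR"]
        return augment_ede(cr_patients, analysis.coherent_freqs, majority_n)
    raise ValueError(f"unknown augmentation method {method!r}")


class SampleFeaturizer:
    """Sample -> coherence maps -> tiled image -> backbone features, memoized.

    Coherence is recomputed for every augmented sample (blends and extracted
    repeats get their own maps); identical keys (over-sampled copies) share
    cached features.
    """

    def __init__(
        self,
        style: CropStyle | str,
        backbone=None,
        threshold: float = 0.9,
        grid: Optional[WaveletGrid] = None,
    ):
        self.style = CROP_STYLES[style] if isinstance(style, str) else style
        self.backbone = backbone if backbone is not None else get_backbone("fixture")
        self.threshold = threshold
        self.grid = grid
        self._cache: dict[str, np.ndarray] = {}

    def maps_for(self, sample: Sample) -> dict[str, CoherenceMap]:
        return {
            scc: mswc(
                tr.head_velocity,
                tr.eye_velocity,
                tr.sampling_rate,
                grid=self.grid,
                threshold=self.threshold,
            )
            for scc, tr in sample.traces.items()
        }

    def image_for(self, sample: Sample) -> TiledImage:
        return crop_and_tile(
            self.maps_for(sample),
            self.style,
            patient_id=sample.patient_id,
            output_size=self.backbone.spec.input_size,
        )

    def __call__(self, samples: Sequence[Sample]) -> np.ndarray:
        rows = []
        for s in samples:
            if s.key not in self._cache:
                self._cache[s.key] = extract_features(
                    self.image_for(s), self.backbone
                )
            rows.append(self._cache[s.key])
        return np.asarray(rows)


def run_experiment(
    cohort: Sequence[PatientRecord],
    style: str = "horizontal",
    method: str = "none",
    config: CVConfig = CVConfig(),
    backbone_name: str = "fixture",
    analysis: Optional[CohortAnalysis] = None,
) -> CVResult:
    """One dataset-variant x crop-style x backbone cross-validation run.

    ``method`` is the augmentation variant: none | os | ede | its.  In
    ``within-folds`` placement augmentation happens inside each training
    fold; in ``pre-split`` the balanced set is built once, before
    splitting.
    """
    if analysis is None:
        analysis = analyze_cohort(cohort)
    samples = cohort_samples(cohort, analysis)
    featurizer = SampleFeaturizer(style, backbone=get_backbone(backbone_name))

    if method == "none":
        labels = [s.label for s in samples]
        return repeated_stratified_cv(samples, labels, featurizer, config)

    if config.placement == "pre-split":
        augset = augment_minority(method, cohort, analysis, samples, seed=config.seed)
        full = [s for s in samples if s.label != "CR"] + augset.samples
        labels = [s.label for s in full]
        return repeated_stratified_cv(full, labels, featurizer, config)

    # within-folds: augment the training portion of each fold only
    by_id = {p.patient_id: p for p in cohort}

    def fold_augment(train_samples, train_labels, rng):
        minority = [s for s in train_samples if s.label == "CR"]
        majority_n = sum(1 for lab in train_labels if lab != "CR")
        seed = int(rng.integers(2**31 - 1))
        if method == "os":
            augset = augment_os(minority, majority_n, seed=seed)
        elif method == "its":
            augset = augment_its(minority, majority_n, seed=seed)
        else:
            cr_patients = [by_id[s.patient_id] for s in minority]
            augset = augment_ede(cr_patients, analysis.coherent_freqs, majority_n)
        out = [s for s in train_samples if s.label != "CR"] + augset.samples
        return out, [s.label for s in out]

    labels = [s.label for s in samples]
    return repeated_stratified_cv(samples, labels, featurizer, config, augment=fold_augment)
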