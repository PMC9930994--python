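"""Outcome classification: backbone features + linear SVM under repeated
stratified k-fold cross-validation.

The default backbone is a *fixture*: a small convolutional stack with
seed-fixed random weights used purely as a feature extractor
(random-projection features).  Random convolutional features preserve the
spatial layout of the coherence crops — which is where the class signal
lives — and make the whole pipeline deterministic and dependency-free.
Pretrained AlexNet / ResNet-50 / VGG-19 can be plugged in behind the same
interface when torchvision is available; their weights are external
artifacts and are never required.

A small trainable multilayer perceptron on downsampled pixels is included
as the "pure network" arm for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .imaging import TiledImage


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_size: int
    feature_dim: int
    source: str                  # "fixture" | "pretrained"
    weight_seed: int = 0


class FixtureBackbone:
    """Seed-deterministic random convolutional feature extractor.

    Two valid-mode convolution + ReLU stages with stride subsampling
    (3->8 channels, 5x5/4; 8->16 channels, 3x3/2), followed by 4x4 spatial
    average pooling per channel: 256 features for a 224x224x3 input.
    """

    def __init__(self, input_size: int = 224, weight_seed: int = 0):
        rng = np.random.default_rng(weight_seed)
        self.spec = BackboneSpec(
            name="fixture",
            input_size=input_size,
            feature_dim=256,
            source="fixture",
            weight_seed=weight_seed,
        )
        self.w1 = rng.standard_normal((8, 3, 5, 5)) * np.sqrt(2.0 / (3 * 25))
        self.w2 = rng.standard_normal((16, 8, 3, 3)) * np.sqrt(2.0 / (8 * 9))

    @staticmethod
    def _conv_layer(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
        n_out = w.shape[0]
        maps = []
        for o in range(n_out):
            acc = None
            for i in range(x.shape[0]):
                c = fftconvolve(x[i], w[o, i], mode="valid")
                acc = c if acc is None else acc + c
            maps.append(acc[::stride, ::stride])
        return np.maximum(np.stack(maps), 0.0)

    @staticmethod
    def _pool_grid(x: np.ndarray, grid: int = 4) -> np.ndarray:
        n_ch, h, w = x.shape
        hb = np.array_split(np.arange(h), grid)
        wb = np.array_split(np.arange(w), grid)
        out = np.empty((n_ch, grid, grid))
        for i, hi in enumerate(hb):
            for j, wj in enumerate(wb):
                out[:, i, j] = x[:, hi[0] : hi[-1] + 1, wj[0] : wj[-1] + 1].mean(
                    axis=(1, 2)
                )
        return out.reshape(n_ch * grid * grid)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        x = pixels.astype(np.float64).transpose(2, 0, 1) / 255.0
        x = self._conv_layer(x, self.w1, stride=4)
        x = self._conv_layer(x, self.w2, stride=2)
        return self._pool_grid(x)


def get_backbone(name: str, input_size: int = 224):
    """Backbone registry.  Pretrained entries require torchvision."""
    if name == "fixture":
        return FixtureBackbone(input_size=input_size)
    if name in ("alexnet", "resnet50", "vgg19"):
        try:
            from .pretrained import PretrainedBackbone
        except ImportError as exc:          # pragma: no cover
            raise ImportError(
                f"backbone {name!r} needs the optional torchvision plugin"
            ) from exc
        return PretrainedBackbone(name, input_size=input_size)
    raise ValueError(f"unknown backbone {name!r}")


def extract_features(image: TiledImage | np.ndarray, backbone) -> np.ndarray:
    """Fixed-length feature vector for one tiled image."""
    pixels = image.pixels if isinstance(image, TiledImage) else np.asarray(image)
    size = backbone.spec.input_size
    if pixels.shape[:2] != (size, size):
        raise ValueError(
            f"image is {pixels.shape[:2]}, backbone expects {(size, size)}"
        )
    return np.asarray(backbone(pixels), dtype=float)


def train_svm(features: np.ndarray, labels: Sequence[str]) -> Pipeline:
    """Linear SVM (C = 1, balanced class weights) on z-scored features."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to train the SVM")
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=1.0, class_weight="balanced")),
        ]
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    repeats: int = 10
    stratified: bool = True              # always; kept for the record
    seed: int = 0
    placement: str = "within-folds"      # "within-folds" | "pre-split"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.placement not in ("within-folds", "pre-split"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class CVResult:
    fold_accuracies: list[float]         # %
    mean_accuracy: float                 # %
    std_accuracy: float                  # %, sample std over folds
    confusion: dict[str, dict[str, int]]
    config: CVConfig
    fold_test_counts: list[dict[str, int]] = field(default_factory=list)

    @classmethod
    def from_folds(
        cls,
        fold_accuracies: Sequence[float],
        confusion,
        config: CVConfig,
        fold_test_counts: Optional[list[dict[str, int]]] = None,
    ) -> "CVResult":
        accs = [float(a) for a in fold_accuracies]
        return cls(
            fold_accuracies=accs,
            mean_accuracy=float(np.mean(accs)),
            std_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            confusion=confusion,
            config=config,
            fold_test_counts=fold_test_counts or [],
        )


def repeated_stratified_cv(
    samples: Sequence,
    labels: Sequence[str],
    featurize: Callable[[Sequence], np.ndarray],
    config: CVConfig,
    augment: Optional[Callable] = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the featurize -> SVM pipeline.

    In ``within-folds`` placement, ``augment(train_samples, train_labels,
    rng)`` is applied to the training portion of each fold only, so held-out
    scoring always happens on original samples.  In ``pre-split`` placement
    the caller balances the classes once before splitting and passes
    ``augment=None``; synthetic samples may then straddle the train/test
    boundary (the historically common, leakage-prone order).
    """
    samples = list(samples)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < config.k):
        small = classes[counts < config.k]
        raise ValueError(f"class(es) {list(small)} have fewer than k={config.k} members")
    if config.placement == "pre-split" and augment is not None:
        raise ValueError("pre-split placement expects pre-augmented samples (augment=None)")

    splitter = RepeatedStratifiedKFold(
        n_splits=config.k, n_repeats=config.repeats, random_state=config.seed
    )
    rng = np.random.default_rng(config.seed)
    fold_accs: list[float] = []
    fold_test_counts: list[dict[str, int]] = []
    confusion = {c: {c2: 0 for c2 in classes} for c in classes}
    idx = np.arange(len(samples))
    for train_idx, test_idx in splitter.split(idx, labels):
        train_samples = [samples[i] for i in train_idx]
        train_labels = list(labels[train_idx])
        if augment is not None:
            train_samples, train_labels = augment(train_samples, train_labels, rng)
        x_train = featurize(train_samples)
        x_test = featurize([samples[i] for i in test_idx])
        clf = train_svm(x_train, train_labels)
        pred = clf.predict(x_test)
        truth = labels[test_idx]
        fold_accs.append(100.0 * float(np.mean(pred == truth)))
        fold_test_counts.append(
            {c: int(np.sum(truth == c)) for c in classes}
        )
        for t, p in zip(truth, pred):
            confusion[t][p] += 1
    return CVResult.from_folds(fold_accs, confusion, config, fold_test_counts)


def summarize(results: dict[tuple[str, str, str], CVResult]) -> pd.DataFrame:
    """Comparison table over (style, dataset variant, backbone) combinations."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for (variant, style, backbone), res in results.items():
        rows.append(
            {
                "style": style,
                "variant": variant,
                "backbone": backbone,
                "mean_accuracy_pct": res.mean_accuracy,
                "std_pct": res.std_accuracy,
                "display": f"{res.mean_accuracy:.1f} [{res.std_accuracy:.1f}]",
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["style", "variant", "backbone"], kind="stable")
        .reset_index(drop=True)
    )


def train_small_network(features_or_pixels: np.ndarray, labels: Sequence[str]):
    """The "pure network" arm: a small MLP trained end to end on downsampled
    pixels.  Provided for comparison experiments; the feature + SVM path is
    the primary classifier."""
    from sklearn.neural_network import MLPClassifier

    x = np.asarray(features_or_pixels, dtype=float)
    if x.ndim > 2:
        x = x.reshape(len(x), -1)
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(64,), max_iter=500, random_state=0
                ),
            ),
        ]
    )
    clf.fit(x, np.asarray(labels))
    return clf
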