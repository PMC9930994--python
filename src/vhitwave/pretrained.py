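"""Optional torchvision backbones (AlexNet, ResNet-50, VGG-19).

These require torch/torchvision and downloaded weights; they are plugins
behind the same interface as the fixture backbone and are never needed for
the core pipeline or its tests.
"""

from __future__ import annotations

import numpy as np
import torch                      # noqa: F401  (hard requirement of this plugin)
import torchvision

from .classify import BackboneSpec

_FEATURE_DIMS = {"alexnet": 4096, "resnet50": 2048, "vgg19": 4096}


class PretrainedBackbone:
    """Feature extraction from the penultimate layer of a pretrained CNN."""

    def __init__(self, name: str, input_size: int = 224):
        if name not in _FEATURE_DIMS:
            raise ValueError(f"unsupported pretrained backbone {name!r}")
        self.spec = BackboneSpec(
            name=name,
            input_size=input_size,
            feature_dim=_FEATURE_DIMS[name],
            source="pretrained",
        )
        if name == "alexnet":
            m = torchvision.models.alexnet(weights="DEFAULT")
            m.classifier = torch.nn.Sequential(*list(m.classifier.children())[:-1])
        elif name == "vgg19":
            m = torchvision.models.vgg19(weights="DEFAULT")
            m.classifier = torch.nn.Sequential(*list(m.classifier.children())[:-1])
        else:
            m = torchvision.models.resnet50(weights="DEFAULT")
            m.fc = torch.nn.Identity()
        self.model = m.eval()

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        x = torch.from_numpy(pixels.astype(np.float32) / 255.0).permute(2, 0, 1)
        mean = torch.tensor([0.485, 0.456, 0.406]).view(3, 1, 1)
        std = torch.tensor([0.229, 0.224, 0.225]).view(3, 1, 1)
        x = (x - mean) / std
        with torch.no_grad():
            return self.model(x.unsqueeze(0)).squeeze(0).numpy()
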