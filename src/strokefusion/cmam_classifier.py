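"""Cross-modal attention fusion and the prognosis classifier.

The image vector F1 and metadata vector F2 are concatenated into the
joint feature F; a sigmoid attention mask

    A = sigmoid(FC2(ReLU(BN(FC1(F)))))

gates the joint feature elementwise (Fo = A o F), and a linear head over
Fo yields the two-class logits.  Disabling the gate (A identically 1)
reduces the model to plain concatenation fusion, which is the ablation
baseline for the module's effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm1d, Linear, Module, Tensor, concat

__all__ = ["FusionState", "Prediction", "concat_features", "apply_mask",
           "CrossModalAttention", "FusionClassifier", "classify_logits"]


@dataclass
class FusionState:
    """One forward pass's fusion intermediates (single sample)."""

    image_feature: np.ndarray
    metadata_feature: np.ndarray
    joint: np.ndarray
    mask: np.ndarray
    gated: np.ndarray

    def validate(self) -> None:
        n1, n2 = self.image_feature.size, self.metadata_feature.size
        if self.joint.size != n1 + n2:
            raise ValueError("|F| must equal |F1| + |F2|")
        if self.mask.shape != self.joint.shape or self.gated.shape != self.joint.shape:
            raise ValueError("mask and gated feature must match joint length")
        if not (np.all(self.mask > 0) and np.all(self.mask < 1)):
            raise ValueError("attention mask entries must lie strictly in (0,1)")
        if not np.allclose(self.gated, self.mask * self.joint):
            raise ValueError("gated feature must equal mask * joint elementwise")


@dataclass
class Prediction:
    prob_poor: float
    label_hat: int
    logits: np.ndarray


def concat_features(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Joint feature: F1 followed by F2. An empty f2 (image-only
    ablation) degenerates to F1."""
    f1 = np.asarray(f1, dtype=float).ravel()
    f2 = np.asarray(f2, dtype=float).ravel()
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
        raise ValueError("features must be finite")
    return np.concatenate([f1, f2])


def apply_mask(mask: np.ndarray, joint: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=float)
    joint = np.asarray(joint, dtype=float)
    if mask.shape != joint.shape:
        raise ValueError(
            f"mask length {mask.shape} != joint length {joint.shape}")
    return mask * joint


class CrossModalAttention(Module):
    """Sigmoid gating of the joint feature vector."""

    def __init__(self, feature_dim: int, rng: np.random.Generator,
                 bottleneck: int | None = None):
        super().__init__()
        hidden = bottleneck if bottleneck is not None else max(feature_dim // 4, 1)
        self.fc1 = Linear(feature_dim, hidden, rng)
        self.bn = BatchNorm1d(hidden)
        self.fc2 = Linear(hidden, feature_dim, rng)

    def mask(self, joint: Tensor) -> Tensor:
        return self.fc2(self.bn(self.fc1(joint)).relu()).sigmoid()

    def forward(self, joint: Tensor) -> tuple[Tensor, Tensor]:
        a = self.mask(joint)
        return a * joint, a


def classify_logits(logits: np.ndarray, threshold: float = 0.5) -> Prediction:
    """Softmax over 2 logits; ties at the threshold predict poor
    prognosis (class 1) by design."""
    z = np.asarray(logits, dtype=float).ravel()
    e = np.exp(z - z.max())
    probs = e / e.sum()
    p = float(probs[1])
    return Prediction(prob_poor=p, label_hat=int(p >= threshold), logits=z)


class FusionClassifier(Module):
    """CMAM gate + linear 2-class head over the gated joint feature."""

    def __init__(self, feature_dim: int, rng: np.random.Generator,
                 bottleneck: int | None = None, gate_enabled: bool = True):
        super().__init__()
        self.cmam = CrossModalAttention(feature_dim, rng, bottleneck)
        self.head = Linear(feature_dim, 2, rng)
        self.gate_enabled = gate_enabled
        self._last: dict[str, Tensor] = {}

    def forward(self, joint: Tensor) -> Tensor:
        if self.gate_enabled:
            gated, mask = self.cmam(joint)
        else:
            mask = Tensor(np.ones_like(joint.data))
            gated = joint
        self._last = {"joint": joint, "mask": mask, "gated": gated}
        return self.head(gated)

    def last_state(self, f1_len: int, index: int = 0) -> FusionState:
        """FusionState of sample `index` from the most recent forward."""
        joint = self._last["joint"].data[index]
        return FusionState(
            image_feature=joint[:f1_len],
            metadata_feature=joint[f1_len:],
            joint=joint,
            mask=self._last["mask"].data[index],
            gated=self._last["gated"].data[index])
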