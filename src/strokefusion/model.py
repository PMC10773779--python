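"""Assembly of the full prognosis model and its ablation arms.

Arm flags (nested, mirroring the ablation table):

  arm 1: single-scale VGG-style backbone, no attention, image only
  arm 2: + multi-scale feature fusion (MS)
  arm 3: + global-local attention at each scale (GLAM)
  arm 4: + metadata encoder and cross-modal attention fusion (MLP)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alam import ImageBranchConfig, MultiScaleImageBranch
from .cmam_classifier import FusionClassifier
from .metadata_encoder import MetadataEncoder
from .nn import Module, Tensor, concat

__all__ = ["ArmFlags", "PrognosisModel", "build_model", "DESK_BRANCH",
           "PAPER_BRANCH"]


@dataclass(frozen=True)
class ArmFlags:
    ms: bool = True
    glam: bool = True
    mlp: bool = True

    @staticmethod
    def for_arm(no: int) -> "ArmFlags":
        return {1: ArmFlags(False, False, False),
                2: ArmFlags(True, False, False),
                3: ArmFlags(True, True, False),
                4: ArmFlags(True, True, True)}[no]


#: Reduced-width profile for CPU-scale runs.
DESK_BRANCH = ImageBranchConfig(
    image_size=64, stage_widths=(8, 16, 24, 32, 48), convs_per_stage=1,
    embed_dim=32, heads=2)

#: Published-scale profile (224 px, full VGG16 widths).
PAPER_BRANCH = ImageBranchConfig()


class PrognosisModel(Module):
    """Image branch (+ optional metadata branch + CMAM gate) + head."""

    def __init__(self, branch_config: ImageBranchConfig, flags: ArmFlags,
                 meta_dim: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        cfg = replace(branch_config, multiscale=flags.ms, glam=flags.glam)
        self.flags = flags
        self.branch_config = cfg
        self.image_branch = MultiScaleImageBranch(cfg, rng)
        self.f1_len = cfg.feature_dim
        if flags.mlp:
            self.meta_encoder = MetadataEncoder(meta_dim, rng)
            fused = self.f1_len + self.meta_encoder.width
        else:
            self.meta_encoder = None
            fused = self.f1_len
        self.fusion = FusionClassifier(fused, rng,
                                       gate_enabled=flags.mlp)

    def forward(self, images: Tensor, meta: Tensor | None = None) -> Tensor:
        f1 = self.image_branch(images)
        if self.flags.mlp:
            if meta is None:
                raise ValueError("this arm requires metadata input")
            f2 = self.meta_encoder(meta)
            joint = concat([f1, f2], axis=1)
        else:
            joint = f1
        return self.fusion(joint)

    def predict_proba(self, images: np.ndarray,
                      meta: np.ndarray | None = None,
                      batch_size: int = 32) -> np.ndarray:
        """Inference-mode P(poor prognosis) for a batch of samples."""
        self.eval()
        probs = []
        for lo in range(0, len(images), batch_size):
            hi = lo + batch_size
            m = Tensor(meta[lo:hi]) if meta is not None else None
            logits = self.forward(Tensor(images[lo:hi]), m).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs.append((e / e.sum(axis=1, keepdims=True))[:, 1])
        return np.concatenate(probs)


def build_model(profile: str, arm: int | ArmFlags, meta_dim: int,
                seed: int = 0, image_size: int | None = None) -> PrognosisModel:
    base = DESK_BRANCH if profile == "desk" else PAPER_BRANCH
    if image_size is not None:
        base = replace(base, image_size=image_size)
    flags = arm if isinstance(arm, ArmFlags) else ArmFlags.for_arm(arm)
    return PrognosisModel(base, flags, meta_dim, seed=seed)
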