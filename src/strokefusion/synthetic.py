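"""Seeded synthetic cohorts: lesion-bearing brain-like slices with
ground-truth masks plus label-correlated clinical metadata.

The generator stands in for a private clinical cohort.  It produces
2-D grayscale slices (smooth elliptical "brain" silhouette + textured
noise) carrying one or more irregular bright lesion blobs, and one
metadata record per patient whose fields are statistically associated
with the binary prognosis label.  Poor-prognosis patients carry a larger
lesion burden on average; a configurable fraction of them instead carry
several small lesions (the hard-to-spot subpopulation).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .schema import DEFAULT_SCHEMA, MetadataSchema

__all__ = [
    "LesionSpec", "ImageSample", "MetadataRecord", "CohortSample",
    "LabelModel", "render_slice", "sample_metadata", "generate_cohort",
    "DEFAULT_EFFECT_SIZES",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class LesionSpec:
    """One lesion: centre (row, col), radius in pixels, added contrast,
    and boundary irregularity amplitude in [0, 1]."""

    center: tuple[float, float]
    radius: float
    intensity_delta: float = 0.3
    shape_irregularity: float = 0.3

    def validate(self, image_size: int) -> None:
        if self.radius < 0:
            raise ValueError(f"lesion radius must be >= 0, got {self.radius}")
        r, c = self.center
        if not (0 <= r < image_size and 0 <= c < image_size):
            raise ValueError(
                f"lesion center {self.center} outside image bounds "
                f"[0, {image_size})")
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must lie in [0, 1]")


@dataclass
class ImageSample:
    """One 2-D slice with optional ground-truth lesion mask."""

    pixels: np.ndarray            # (H, W) float in [0, 1]
    patient_id: str
    slice_index: int = 0
    lesion_mask: np.ndarray | None = None   # (H, W) uint8, or None

    def validate(self) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels outside [0, 1]")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        if self.lesion_mask is not None and self.lesion_mask.shape != self.pixels.shape:
            raise ValueError("lesion mask shape differs from pixel shape")


@dataclass
class MetadataRecord:
    """One patient's clinical fields (see :mod:`strokefusion.schema`)."""

    hospital: str
    gender: int
    age: float
    disorder: int
    consciousness: int
    hemiplegia: int
    pneumonia: int
    aphasia: int
    swallowing_disorder: int
    facial_paralysis: int
    dementia: int
    cognitive_impairment: int
    depression: int
    first_ability_score: float
    hypertension: int
    diabetes: int
    atrial_fibrillation: int
    coronary_heart_disease: int
    hyperlipidemia: int
    hyperhomocysteinemia: int

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in DEFAULT_SCHEMA.fields}

    def validate(self, schema: MetadataSchema = DEFAULT_SCHEMA) -> None:
        for f in schema.fields:
            v = getattr(self, f)
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                raise ValueError(f"metadata field {f!r} missing or non-finite")
        if self.age <= 0:
            raise ValueError("age must be positive")
        lo, hi = schema.ability_score_range
        if not lo <= self.first_ability_score <= hi:
            raise ValueError(
                f"first_ability_score {self.first_ability_score} outside "
                f"[{lo}, {hi}]")
        if self.hospital not in schema.hospital_levels:
            raise ValueError(f"unknown hospital level {self.hospital!r}")
        if not 0 <= self.consciousness < schema.consciousness_levels:
            raise ValueError("consciousness level out of range")
        for f in schema.binary_fields:
            if getattr(self, f) not in (0, 1):
                raise ValueError(f"binary field {f!r} must be 0/1")


@dataclass
class CohortSample:
    image: ImageSample
    metadata: MetadataRecord
    label: int                    # 0 = eusemia (good), 1 = poor prognosis

    def validate(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        self.image.validate()
        self.metadata.validate()


# ---------------------------------------------------------------------------
# slice rendering

def _brain_background(image_size: int, noise_sd: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical brain silhouette with smooth interior shading and
    Gaussian-smoothed texture noise. Returns (image, inside-brain mask)."""
    n = image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy = cx = (n - 1) / 2.0
    ay, ax = 0.46 * n, 0.38 * n
    rr2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    inside = rr2 <= 1.0
    img = np.zeros((n, n))
    img[inside] = 0.35 + 0.2 * (1.0 - rr2[inside])
    if noise_sd > 0:
        tex = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=1.5)
        img[inside] += noise_sd * tex[inside]
    return np.clip(img, 0.0, 1.0), inside


def _lesion_mask(spec: LesionSpec, image_size: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Rasterize one irregular blob: radius modulated by low-order random
    harmonics of the polar angle around the centre."""
    n = image_size
    if spec.radius == 0:
        return np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - spec.center[0], xx - spec.center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    wobble = np.zeros_like(theta)
    if spec.shape_irregularity > 0:
        amps = rng.uniform(-1.0, 1.0, size=3)
        phases = rng.uniform(0.0, 2 * np.pi, size=3)
        for k, (a, ph) in enumerate(zip(amps, phases), start=2):
            wobble += a * np.cos(k * theta + ph)
        wobble *= spec.shape_irregularity / 3.0
    r_theta = spec.radius * (1.0 + wobble)
    return dist <= r_theta


def render_slice(spec: LesionSpec, image_size: int = 64,
                 noise_sd: float = 0.02, seed: int = 0) -> ImageSample:
    """Render one slice containing a single lesion (or none if radius 0).

    Deterministic given ``(spec, image_size, noise_sd, seed)``.
    """
    if image_size < 16:
        raise ValueError(f"image_size must be >= 16, got {image_size}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spec.validate(image_size)
    return compose_slice([spec], image_size, noise_sd, seed)


def compose_slice(specs: list[LesionSpec], image_size: int,
                  noise_sd: float, seed: int,
                  patient_id: str = "synthetic", slice_index: int = 0
                  ) -> ImageSample:
    """Render a slice with zero or more lesions on one background."""
    rng = np.random.default_rng(seed)
    img, inside = _brain_background(image_size, noise_sd, rng)
    mask = np.zeros((image_size, image_size), dtype=bool)
    for spec in specs:
        spec.validate(image_size)
        blob = _lesion_mask(spec, image_size, rng) & inside
        soft = gaussian_filter(blob.astype(float), sigma=0.8)
        img += spec.intensity_delta * soft
        mask |= blob
    return ImageSample(pixels=np.clip(img, 0.0, 1.0),
                       patient_id=patient_id, slice_index=slice_index,
                       lesion_mask=mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# metadata sampling

#: Baseline P(field = 1) for an eusemia (label 0) patient.
_BASE_PROBS = {
    "gender": 0.5, "disorder": 0.15, "hemiplegia": 0.25, "pneumonia": 0.15,
    "aphasia": 0.15, "swallowing_disorder": 0.12, "facial_paralysis": 0.15,
    "dementia": 0.08, "cognitive_impairment": 0.12, "depression": 0.10,
    "hypertension": 0.55, "diabetes": 0.25, "atrial_fibrillation": 0.12,
    "coronary_heart_disease": 0.18, "hyperlipidemia": 0.30,
    "hyperhomocysteinemia": 0.15,
}

#: Default label-conditional log-odds shifts (binary fields) and mean
#: shifts in native units (age, first_ability_score).
DEFAULT_EFFECT_SIZES = {
    "hemiplegia": 1.6, "pneumonia": 1.2, "swallowing_disorder": 1.2,
    "consciousness": 1.0, "dementia": 0.8, "cognitive_impairment": 0.8,
    "atrial_fibrillation": 0.7, "age": 6.0, "first_ability_score": -25.0,
}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def sample_metadata(label: int, effect_sizes: dict[str, float] | None = None,
                    seed: int = 0,
                    schema: MetadataSchema = DEFAULT_SCHEMA) -> MetadataRecord:
    """Draw one clinical record conditioned on the prognosis label.

    Binary fields follow ``P(1 | label) = sigmoid(logit(base) +
    label * effect)``; ``age`` and ``first_ability_score`` are normal
    draws whose means shift with the label by their effect sizes;
    ``consciousness`` is an ordinal draw whose distribution tilts toward
    worse levels with a positive effect.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    effects = dict(effect_sizes) if effect_sizes is not None else {}
    schema.validate_field_names(effects)
    rng = np.random.default_rng(seed)

    values: dict[str, object] = {}
    values["hospital"] = schema.hospital_levels[
        rng.integers(len(schema.hospital_levels))]
    for f in schema.binary_fields:
        base = _BASE_PROBS[f]
        logit = math.log(base / (1 - base)) + label * effects.get(f, 0.0)
        values[f] = int(rng.random() < _sigmoid(logit))
    # ordinal consciousness: geometric-ish decay, tilted by effect
    k = schema.consciousness_levels
    tilt = label * effects.get("consciousness", 0.0)
    logits = -1.2 * np.arange(k) + tilt * np.arange(k) / (k - 1)
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    values["consciousness"] = int(rng.choice(k, p=probs))

    age = rng.normal(66.0 + label * effects.get("age", 0.0), 11.0)
    values["age"] = float(np.clip(age, *schema.age_range))
    lo, hi = schema.ability_score_range
    fas = rng.normal(72.0 + label * effects.get("first_ability_score", 0.0),
                     14.0)
    values["first_ability_score"] = float(np.clip(fas, lo, hi))
    return MetadataRecord(**values)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class LabelModel:
    """Label-conditional lesion-burden model.

    Labels are drawn first (Bernoulli with ``class_balance``); lesion
    count and radius are then drawn from per-label distributions so the
    total lesion area carries the label signal by construction.
    """

    neg_count_probs: tuple[float, ...] = (0.35, 0.45, 0.20)   # 0, 1, 2 lesions
    neg_radius_range: tuple[float, float] = (2.0, 4.0)
    pos_count_range: tuple[int, int] = (1, 3)
    pos_radius_range: tuple[float, float] = (6.0, 11.0)
    small_count_range: tuple[int, int] = (3, 4)
    small_radius_range: tuple[float, float] = (2.5, 4.5)
    #: radius below which a lesion counts as "mild"
    mild_threshold: float = 5.0
    #: image size the radius ranges above are calibrated for; radii are
    #: rescaled proportionally at other sizes
    reference_image_size: int = 64
    neg_intensity: tuple[float, float] = (0.15, 0.28)
    pos_intensity: tuple[float, float] = (0.25, 0.45)
    metadata_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))


def _patient_lesions(label: int, small: bool, model: LabelModel,
                     image_size: int, rng: np.random.Generator
                     ) -> list[LesionSpec]:
    if label == 0:
        count = int(rng.choice(len(model.neg_count_probs),
                               p=model.neg_count_probs))
        rlo, rhi = model.neg_radius_range
        ilo, ihi = model.neg_intensity
    elif small:
        count = int(rng.integers(model.small_count_range[0],
                                 model.small_count_range[1] + 1))
        rlo, rhi = model.small_radius_range
        ilo, ihi = model.pos_intensity
    else:
        count = int(rng.integers(model.pos_count_range[0],
                                 model.pos_count_range[1] + 1))
        rlo, rhi = model.pos_radius_range
        ilo, ihi = model.pos_intensity
    specs = []
    margin = 0.28 * image_size
    scale = image_size / model.reference_image_size
    for _ in range(count):
        center = (float(rng.uniform(margin, image_size - margin)),
                  float(rng.uniform(margin, image_size - margin)))
        specs.append(LesionSpec(
            center=center,
            radius=float(rng.uniform(rlo, rhi)) * scale,
            intensity_delta=float(rng.uniform(ilo, ihi)),
            shape_irregularity=float(rng.uniform(0.2, 0.6))))
    return specs


def _jitter(spec: LesionSpec, image_size: int,
            rng: np.random.Generator) -> LesionSpec:
    """Per-slice variation of a patient-level lesion."""
    dy, dx = rng.normal(0.0, 1.2, size=2)
    r, c = spec.center
    r = float(np.clip(r + dy, 1, image_size - 2))
    c = float(np.clip(c + dx, 1, image_size - 2))
    return replace(spec, center=(r, c),
                   radius=spec.radius * float(rng.uniform(0.88, 1.12)))


def generate_cohort(n_patients: int, slices_per_patient: int = 9,
                    class_balance: float = 0.5,
                    small_lesion_fraction: float = 0.25,
                    label_model: LabelModel | None = None,
                    seed: int = 0, image_size: int = 64,
                    noise_sd: float = 0.02) -> list[CohortSample]:
    """Generate a full cohort: ``n_patients * slices_per_patient`` samples.

    Labels are patient-level; all slices of a patient share its metadata
    record and a jittered rendition of its lesion set.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    if not 0.0 < class_balance < 1.0:
        raise ValueError(
            f"class_balance must lie strictly in (0, 1), got {class_balance}")
    if not 0.0 <= small_lesion_fraction <= 1.0:
        raise ValueError("small_lesion_fraction must lie in [0, 1]")
    model = label_model or LabelModel()

    root = np.random.SeedSequence(seed)
    pat_seeds = root.spawn(n_patients)
    samples: list[CohortSample] = []
    for i, pseq in enumerate(pat_seeds):
        rng = np.random.default_rng(pseq)
        pid = f"P{i:04d}"
        label = int(rng.random() < class_balance)
        small = label == 1 and rng.random() < small_lesion_fraction
        lesions = _patient_lesions(label, small, model, image_size, rng)
        meta_seed = int(rng.integers(2 ** 31))
        record = sample_metadata(label, model.metadata_effects,
                                 seed=meta_seed)
        slice_seeds = rng.integers(2 ** 31, size=slices_per_patient)
        for s in range(slices_per_patient):
            srng = np.random.default_rng(int(slice_seeds[s]))
            jittered = [_jitter(sp, image_size, srng) for sp in lesions]
            img = compose_slice(jittered, image_size, noise_sd,
                                seed=int(slice_seeds[s]),
                                patient_id=pid, slice_index=s)
            samples.append(CohortSample(image=img, metadata=record,
                                        label=label))
    return samples
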