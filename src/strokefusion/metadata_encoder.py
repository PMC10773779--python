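"""Clinical metadata vectorization and the MLP feature encoder (F2).

Encoding scheme (declared, auditable): binary fields map to {0,1};
hospital is one-hot over the schema's category levels; consciousness is
its ordinal level scaled to [0,1]; age and first_ability_score are
z-scored with statistics fitted on the *training* split only.

The encoder is two 256-wide dense layers, each followed by batch
normalization and ReLU, with 25% dropout after the first block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm1d, Dropout, Linear, Module, Tensor
from .schema import DEFAULT_SCHEMA, MetadataSchema
from .synthetic import MetadataRecord

__all__ = ["TrainStats", "MetadataVector", "vectorize_metadata",
           "vectorize_records", "fit_train_stats", "MetadataEncoder",
           "vector_length"]


@dataclass(frozen=True)
class TrainStats:
    """Standardization statistics for the continuous fields, fitted on
    the training split only (no test leakage by construction)."""

    age_mean: float
    age_std: float
    ability_mean: float
    ability_std: float

    @property
    def fitted(self) -> bool:
        return True


@dataclass
class MetadataVector:
    values: np.ndarray
    field_slices: dict[str, slice]


def fit_train_stats(records: list[MetadataRecord]) -> TrainStats:
    if not records:
        raise ValueError("cannot fit statistics on an empty training split")
    ages = np.array([r.age for r in records], dtype=float)
    fas = np.array([r.first_ability_score for r in records], dtype=float)
    return TrainStats(age_mean=float(ages.mean()),
                      age_std=float(max(ages.std(), 1e-8)),
                      ability_mean=float(fas.mean()),
                      ability_std=float(max(fas.std(), 1e-8)))


def vector_length(schema: MetadataSchema = DEFAULT_SCHEMA) -> int:
    return len(schema.hospital_levels) + len(schema.binary_fields) + 3


def vectorize_metadata(record: MetadataRecord | dict,
                       schema: MetadataSchema = DEFAULT_SCHEMA,
                       train_stats: TrainStats | None = None
                       ) -> MetadataVector:
    """Encode one record into a fixed-length numeric vector.

    Raises on a missing field or an unseen hospital category (there is
    deliberately no silent catch-all bucket).
    """
    if train_stats is None:
        raise ValueError("train_stats (fitted on the training split) required")
    get = (record.get if isinstance(record, dict)
           else lambda f, d=None: getattr(record, f, d))
    for f in schema.fields:
        if get(f, None) is None:
            raise ValueError(f"metadata record is missing field {f!r}")

    parts: list[np.ndarray] = []
    slices: dict[str, slice] = {}
    pos = 0

    def push(name: str, arr: np.ndarray):
        nonlocal pos
        parts.append(arr)
        slices[name] = slice(pos, pos + arr.size)
        pos += arr.size

    hosp = get("hospital")
    if hosp not in schema.hospital_levels:
        raise ValueError(
            f"unseen hospital category {hosp!r}; known levels: "
            f"{list(schema.hospital_levels)}")
    onehot = np.zeros(len(schema.hospital_levels))
    onehot[schema.hospital_levels.index(hosp)] = 1.0
    push("hospital", onehot)

    for f in schema.binary_fields:
        v = get(f)
        if v not in (0, 1):
            raise ValueError(f"binary field {f!r} must be 0/1, got {v!r}")
        push(f, np.array([float(v)]))

    push("consciousness", np.array(
        [float(get("consciousness")) / (schema.consciousness_levels - 1)]))
    push("age", np.array(
        [(float(get("age")) - train_stats.age_mean) / train_stats.age_std]))
    push("first_ability_score", np.array(
        [(float(get("first_ability_score")) - train_stats.ability_mean)
         / train_stats.ability_std]))

    return MetadataVector(values=np.concatenate(parts), field_slices=slices)


def vectorize_records(records: list[MetadataRecord],
                      schema: MetadataSchema = DEFAULT_SCHEMA,
                      train_stats: TrainStats | None = None) -> np.ndarray:
    return np.stack([vectorize_metadata(r, schema, train_stats).values
                     for r in records])


class MetadataEncoder(Module):
    """dense(256) -> BN -> ReLU -> dropout(0.25) -> dense(256) -> BN ->
    ReLU. Output F2 is 256-long and nonnegative (post-ReLU)."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 width: int = 256, dropout: float = 0.25):
        super().__init__()
        self.fc1 = Linear(in_features, width, rng)
        self.bn1 = BatchNorm1d(width)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(width, width, rng)
        self.bn2 = BatchNorm1d(width)
        self.width = width

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop(self.bn1(self.fc1(x)).relu())
        return self.bn2(self.fc2(h)).relu()
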