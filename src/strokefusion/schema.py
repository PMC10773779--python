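"""Clinical metadata schema shared by the synthetic generator, the
metadata encoder and the CSV readers.

The published field list enumerates 20 distinct names while the
surrounding text counts "19"; the enumerated names are authoritative here
and the schema is the single source of truth for field order, types and
category levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Binary comorbidity / complication flags, in canonical column order.
BINARY_FIELDS: tuple[str, ...] = (
    "gender", "disorder", "hemiplegia", "pneumonia", "aphasia",
    "swallowing_disorder", "facial_paralysis", "dementia",
    "cognitive_impairment", "depression", "hypertension", "diabetes",
    "atrial_fibrillation", "coronary_heart_disease", "hyperlipidemia",
    "hyperhomocysteinemia",
)

#: Full canonical field order (the clinical feature set).
METADATA_FIELDS: tuple[str, ...] = (
    "hospital", "gender", "age", "disorder", "consciousness",
    "hemiplegia", "pneumonia", "aphasia", "swallowing_disorder",
    "facial_paralysis", "dementia", "cognitive_impairment", "depression",
    "first_ability_score", "hypertension", "diabetes",
    "atrial_fibrillation", "coronary_heart_disease", "hyperlipidemia",
    "hyperhomocysteinemia",
)


@dataclass(frozen=True)
class MetadataSchema:
    """Types, category levels and ranges for the clinical fields."""

    fields: tuple[str, ...] = METADATA_FIELDS
    binary_fields: tuple[str, ...] = BINARY_FIELDS
    hospital_levels: tuple[str, ...] = ("site_a", "site_b", "site_c")
    #: ordinal consciousness levels: alert < drowsy < stupor < coma
    consciousness_levels: int = 4
    ability_score_range: tuple[float, float] = (0.0, 100.0)
    age_range: tuple[float, float] = (18.0, 105.0)

    def validate_field_names(self, names) -> None:
        unknown = set(names) - set(self.fields)
        if unknown:
            raise ValueError(
                f"unknown metadata field(s): {sorted(unknown)}; "
                f"valid fields are {list(self.fields)}")


DEFAULT_SCHEMA = MetadataSchema()
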