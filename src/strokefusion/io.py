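"""Readers and writers: slice images (PNG or NIfTI), metadata CSV,
manifests, metric reports.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .schema import DEFAULT_SCHEMA, MetadataSchema
from .synthetic import CohortSample, ImageSample, MetadataRecord

__all__ = ["load_image", "save_image", "load_metadata_csv",
           "write_metadata_csv", "write_cohort", "load_manifest",
           "atomic_write_bytes", "write_json", "write_csv"]


# ---------------------------------------------------------------------------
# atomic write helpers

def atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: Path, obj) -> None:
    atomic_write_bytes(path, json.dumps(obj, indent=2).encode())


def write_csv(path: Path, df: pd.DataFrame) -> None:
    atomic_write_bytes(path, df.to_csv(index=False).encode())


# ---------------------------------------------------------------------------
# images

def _resize_bilinear(arr: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(img.resize((size, size), Image.BILINEAR), dtype=float)


def load_image(path: str | Path, target_size: int | None = None,
               patient_id: str = "", slice_index: int = 0) -> ImageSample:
    """Read a grayscale PNG or 2-D NIfTI slice, min-max scale to [0,1],
    optionally bilinearly resize to ``target_size``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        arr = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ValueError(
                f"{path}: expected a 2-D slice, got shape {arr.shape}")
    else:
        try:
            arr = np.asarray(Image.open(path).convert("F"), dtype=float)
        except Exception as exc:
            raise ValueError(f"{path}: unreadable image ({exc})") from exc
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if target_size is not None and arr.shape != (target_size, target_size):
        arr = np.clip(_resize_bilinear(arr, target_size), 0.0, 1.0)
    return ImageSample(pixels=arr, patient_id=patient_id,
                       slice_index=slice_index)


def save_image(path: str | Path, pixels: np.ndarray,
               fmt: str = "png") -> None:
    """Write a [0,1] array as 8-bit PNG or float NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        data = (np.clip(pixels, 0, 1) * 255).round().astype(np.uint8)
        img = Image.fromarray(data, mode="L")
        import io as _io
        buf = _io.BytesIO()
        img.save(buf, format="PNG")
        atomic_write_bytes(path, buf.getvalue())
    elif fmt == "nifti":
        nib.save(nib.Nifti1Image(pixels.astype(np.float32), np.eye(4)),
                 str(path))
    else:
        raise ValueError(f"unknown image format {fmt!r}")


# ---------------------------------------------------------------------------
# metadata CSV

def load_metadata_csv(path: str | Path,
                      schema: MetadataSchema = DEFAULT_SCHEMA
                      ) -> dict[str, MetadataRecord]:
    """Read one-row-per-patient metadata; returns patient_id -> record.

    Fails hard on missing columns or missing values.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", *schema.fields)
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records: dict[str, MetadataRecord] = {}
    for i, row in df.iterrows():
        if row[list(schema.fields)].isna().any():
            bad = [f for f in schema.fields if pd.isna(row[f])]
            raise ValueError(f"{path}: row {i}: missing value(s) in {bad}")
        try:
            rec = MetadataRecord(
                hospital=str(row["hospital"]),
                age=float(row["age"]),
                consciousness=int(row["consciousness"]),
                first_ability_score=float(row["first_ability_score"]),
                **{f: int(row[f]) for f in schema.binary_fields})
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        records[str(row["patient_id"])] = rec
    return records


def write_metadata_csv(path: str | Path,
                       records: dict[str, MetadataRecord],
                       labels: dict[str, int] | None = None,
                       schema: MetadataSchema = DEFAULT_SCHEMA) -> None:
    rows = []
    for pid in sorted(records):
        row = {"patient_id": pid, **records[pid].as_dict()}
        if labels is not None:
            row["label"] = labels[pid]
        rows.append(row)
    write_csv(Path(path), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort + manifest

def write_cohort(samples: list[CohortSample], out_dir: str | Path,
                 fmt: str = "png", test_fraction: float = 0.3,
                 split_seed: int = 0) -> Path:
    """Write slices, masks, metadata CSV and a manifest CSV.

    Returns the manifest path. The split column is a patient-level
    stratified train/test assignment.
    """
    from .train_eval import split_cohort   # local import: avoids cycle

    out = Path(out_dir)
    (out / "slices").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    ext = "png" if fmt == "png" else "nii"
    _, test = split_cohort(samples, test_fraction, seed=split_seed)
    test_pids = {s.image.patient_id for s in test}

    rows = []
    records: dict[str, MetadataRecord] = {}
    labels: dict[str, int] = {}
    for s in samples:
        pid, si = s.image.patient_id, s.image.slice_index
        slice_path = out / "slices" / f"{pid}_s{si:02d}.{ext}"
        mask_path = out / "masks" / f"{pid}_s{si:02d}.{ext}"
        save_image(slice_path, s.image.pixels, fmt)
        save_image(mask_path, s.image.lesion_mask.astype(float), fmt)
        records[pid] = s.metadata
        labels[pid] = s.label
        rows.append({"slice_path": str(slice_path.relative_to(out)),
                     "mask_path": str(mask_path.relative_to(out)),
                     "patient_id": pid,
                     "split": "test" if pid in test_pids else "train",
                     "label": s.label})
    write_metadata_csv(out / "metadata.csv", records, labels)
    manifest = out / "manifest.csv"
    write_csv(manifest, pd.DataFrame(rows))
    return manifest


def load_manifest(path: str | Path, image_size: int | None = None
                  ) -> list[CohortSample]:
    """Load a cohort from a manifest CSV (+ sibling metadata.csv)."""
    path = Path(path)
    root = path.parent
    df = pd.read_csv(path)
    required = {"slice_path", "patient_id", "split", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = load_metadata_csv(root / "metadata.csv")
    # guard: splits must be patient-disjoint
    split_of: dict[str, str] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in split_of and split_of[pid] != row["split"]:
            raise ValueError(
                f"patient {pid} appears in both train and test splits")
        split_of[pid] = row["split"]
    samples = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        img = load_image(root / row["slice_path"], image_size, patient_id=pid)
        if "mask_path" in df.columns and not pd.isna(row.get("mask_path")):
            mask_img = load_image(root / row["mask_path"], image_size)
            img.lesion_mask = (mask_img.pixels > 0.5).astype(np.uint8)
        img.split = row["split"]          # annotation used by the CLI
        samples.append(CohortSample(image=img, metadata=records[pid],
                                    label=int(row["label"])))
    return samples
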