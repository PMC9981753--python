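"""Readers and writers for the formats the tool exchanges.

* instance annotations: 16-bit label TIFF (0 = background) and
  COCO-style JSON with uncompressed column-major RLE masks (the
  canonical format, since predicted instances may overlap — a label
  TIFF can only hold a partition);
* LOIs: CSV with header ``row,col`` and JSON lists;
* image-level masks: binary PNG/TIFF;
* dataset manifests: JSON records of image/annotation paths per split.

Readers are strict: shape mismatches, NaNs, malformed rows, and
out-of-bounds LOIs are rejected with errors naming the offending file
and row.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .types import InstanceSet, WeakAnnotation, as_loi_array

__all__ = [
    "rle_encode",
    "rle_decode",
    "write_instance_labels",
    "read_instance_labels",
    "write_instances_coco",
    "read_instances_coco",
    "write_lois_csv",
    "read_lois_csv",
    "write_mask",
    "read_mask",
    "write_image",
    "read_image",
    "read_weak_annotation",
    "DatasetManifest",
]


# ---------------------------------------------------------------------------
# RLE (COCO convention: column-major, counts start with background run)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Encode a binary mask as uncompressed column-major RLE."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel(order="F").astype(np.int8)
    changes = np.nonzero(np.diff(flat))[0] + 1
    boundaries = np.concatenate([[0], changes, [flat.size]])
    counts = np.diff(boundaries).tolist()
    if flat.size and flat[0] == 1:  # counts must start with a zero-run
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    """Decode an uncompressed column-major RLE into a binary mask."""
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = True
        pos += count
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE length {pos} does not match mask size {h * w}")
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# instances
# ---------------------------------------------------------------------------

def write_instance_labels(path, instances: InstanceSet, shape=None) -> None:
    """Lossy label-TIFF export: overlaps resolved by draw order."""
    lab = instances.label_map(shape)
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot fit a 16-bit label TIFF")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def read_instance_labels(path) -> InstanceSet:
    """Read instances from a label TIFF or a COCO-style JSON (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_instances_coco(path)
    lab = tifffile.imread(str(path))
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError(f"{path}: label image must have an integer dtype, got {lab.dtype}")
    if lab.ndim != 2:
        raise ValueError(f"{path}: label image must be 2-D, got shape {lab.shape}")
    return InstanceSet.from_label_map(lab.astype(np.int64))


def write_instances_coco(path, instances: InstanceSet, scores=None) -> None:
    """Canonical overlap-capable export: COCO-style JSON with RLE masks."""
    shape = instances.shape
    anns = []
    for k, (mask, iid) in enumerate(zip(instances.masks, instances.ids)):
        ann = {
            "id": int(iid),
            "segmentation": rle_encode(mask),
            "area": int(mask.sum()),
        }
        if scores is not None:
            ann["score"] = float(scores[k])
        anns.append(ann)
    doc = {
        "height": int(shape[0]) if shape else 0,
        "width": int(shape[1]) if shape else 0,
        "annotations": anns,
    }
    Path(path).write_text(json.dumps(doc))


def read_instances_coco(path) -> InstanceSet:
    doc = json.loads(Path(path).read_text())
    masks, ids = [], []
    for ann in doc["annotations"]:
        masks.append(rle_decode(ann["segmentation"]))
        ids.append(int(ann["id"]))
    return InstanceSet(masks=masks, ids=ids)


# ---------------------------------------------------------------------------
# LOIs
# ---------------------------------------------------------------------------

def write_lois_csv(path, lois) -> None:
    lois = as_loi_array(lois)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        for r, c in lois:
            writer.writerow([repr(float(r)), repr(float(c))])


def read_lois_csv(path) -> np.ndarray:
    path = Path(path)
    lois = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["row", "col"]:
            raise ValueError(f"{path}: expected header 'row,col', got {header}")
        for lineno, rowvals in enumerate(reader, start=2):
            if not rowvals or all(not v.strip() for v in rowvals):
                continue
            try:
                r, c = float(rowvals[0]), float(rowvals[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed LOI at line {lineno}: {rowvals}") from exc
            if not (np.isfinite(r) and np.isfinite(c)):
                raise ValueError(f"{path}: non-finite LOI at line {lineno}")
            lois.append((r, c))
    return as_loi_array(lois)


def write_lois_json(path, lois) -> None:
    Path(path).write_text(json.dumps([[float(r), float(c)] for r, c in as_loi_array(lois)]))


def read_lois_json(path) -> np.ndarray:
    return as_loi_array(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# images & masks
# ---------------------------------------------------------------------------

def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), mask.astype(np.uint8) * 255)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), mask.astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.asarray(image))
    else:
        import imageio.v3 as iio

        img = np.asarray(image)
        if img.dtype in (np.float32, np.float64):
            img = np.clip(img, 0, 1)
            img = (img * 255).astype(np.uint8)
        iio.imwrite(str(path), img)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
        raise ValueError(f"{path}: image contains NaN/inf values")
    return arr


def read_weak_annotation(mask_path, loi_path) -> WeakAnnotation:
    """Validated weak annotation; out-of-bounds LOIs rejected with row numbers."""
    mask = read_mask(mask_path)
    lois = (
        read_lois_csv(loi_path)
        if str(loi_path).endswith(".csv")
        else read_lois_json(loi_path)
    )
    h, w = mask.shape
    for i, (r, c) in enumerate(lois):
        if not (-0.5 <= r <= h - 0.5 and -0.5 <= c <= w - 0.5):
            raise ValueError(
                f"{loi_path}: LOI row {i + 1} at ({r}, {c}) outside {h}x{w} mask"
            )
    return WeakAnnotation(image_mask=mask, lois=lois)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """File-backed dataset description: one record per image."""

    records: list[dict]  # {image, labels | (mask, lois), split}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({"records": self.records}, indent=2))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        doc = json.loads(Path(path).read_text())
        manifest = cls(records=doc["records"])
        root = Path(path).parent
        for i, rec in enumerate(manifest.records):
            for key in ("image", "labels", "mask", "lois"):
                if key in rec and not (root / rec[key]).exists():
                    raise FileNotFoundError(
                        f"manifest record {i}: missing {key} file {rec[key]}"
                    )
        return manifest

    def split(self, tag: str) -> list[dict]:
        return [r for r in self.records if r.get("split", "train") == tag]
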