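"""Dataset plumbing: images, ROI rectangles, manifests and feature tables.

Coordinates are 0-based and row-major; rectangle extents are half-open
(`x0..x0+w-1` inclusive).  Images are 2-D uint8 grids; labels are the
canonical strings ``"positive"`` / ``"negative"`` grouped by an opaque
``case_id`` (one patient may contribute several images, and every
train/test split downstream is done per case).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

POSITIVE = "positive"
NEGATIVE = "negative"

_POS_TOKENS = {"1", "pos", "positive", "p", "true", "cancer", "malignant"}
_NEG_TOKENS = {"0", "neg", "negative", "n", "false", "normal", "benign"}

# ITU-R 601 luma weights, fixed for determinism on any colour input.
_LUMA = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = ("image_path", "case_id", "label")
ROI_COLUMNS = ("x0", "y0", "w", "h")


def normalize_label(token: str) -> str:
    """Map a free-form label token to ``"positive"`` / ``"negative"``."""
    t = str(token).strip().lower()
    if t in _POS_TOKENS:
        return POSITIVE
    if t in _NEG_TOKENS:
        return NEGATIVE
    raise ValueError(f"unknown label token {token!r}")


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle: top-left (x0, y0), extent w x h pixels."""

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 3 or self.h < 3:
            raise ValueError(f"ROI extent must be >= 3x3, got {self.w}x{self.h}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.x0}, {self.y0})")


@dataclass(frozen=True)
class SampleRecord:
    image_path: str
    case_id: str
    label: str
    roi: RoiRect | None = None

    def __post_init__(self):
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.label not in (POSITIVE, NEGATIVE):
            object.__setattr__(self, "label", normalize_label(self.label))


@dataclass
class DatasetManifest:
    records: list[SampleRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def case_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.case_id, None)
        return list(seen)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]


def read_manifest(path) -> DatasetManifest:
    """Read a CSV manifest (image_path, case_id, label[, x0,y0,w,h])."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in MANIFEST_COLUMNS:
            if col not in header:
                raise ValueError(f"manifest {path} is missing required column {col!r}")
        has_roi = all(c in header for c in ROI_COLUMNS)
        records = []
        for i, row in enumerate(reader, start=2):
            try:
                label = normalize_label(row["label"])
            except ValueError as e:
                raise ValueError(f"{path} row {i}: {e}") from None
            roi = None
            if has_roi and row["x0"] not in ("", None):
                roi = RoiRect(*(int(row[c]) for c in ROI_COLUMNS))
            records.append(SampleRecord(row["image_path"], row["case_id"], label, roi))
    return DatasetManifest(records=records, provenance=str(path))


def write_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    has_roi = any(r.roi is not None for r in manifest.records)
    cols = list(MANIFEST_COLUMNS) + (list(ROI_COLUMNS) if has_roi else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in manifest.records:
            row = [r.image_path, r.case_id, r.label]
            if has_roi:
                row += ([r.roi.x0, r.roi.y0, r.roi.w, r.roi.h] if r.roi else ["", "", "", ""])
            w.writerow(row)


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF as a 2-D uint8 grid.

    Colour inputs are collapsed with fixed 0.299/0.587/0.114 luma
    weights; higher bit depths are rescaled by division by the dtype
    maximum.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as e:  # imageio plugins raise assorted exception types
        raise OSError(f"cannot read image {path}: {e}") from e
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(np.float64) @ _LUMA
        else:
            arr = arr[..., 0].astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.uint8:
        return arr
    info_max = np.iinfo(arr.dtype).max if np.issubdtype(arr.dtype, np.integer) else None
    scale = 255.0 / info_max if info_max and info_max > 255 else 1.0
    return np.rint(np.clip(arr.astype(np.float64) * scale, 0, 255)).astype(np.uint8)


def crop_roi(img: np.ndarray, roi: RoiRect) -> np.ndarray:
    """Crop; output pixel (0,0) is input pixel (roi.y0, roi.x0)."""
    h, w = img.shape[:2]
    if roi.x0 + roi.w > w:
        raise ValueError(f"ROI right edge x0+w={roi.x0 + roi.w} exceeds image width {w}")
    if roi.y0 + roi.h > h:
        raise ValueError(f"ROI bottom edge y0+h={roi.y0 + roi.h} exceeds image height {h}")
    return img[roi.y0 : roi.y0 + roi.h, roi.x0 : roi.x0 + roi.w]


def _vector_of(feats) -> np.ndarray:
    vals = getattr(feats, "values", feats)
    return np.asarray(vals, dtype=np.float64)


def write_features(table, path) -> None:
    """Write (record, features) pairs to CSV.

    Columns: image_path, case_id, label, f_0..f_{d-1}.  Floats are
    written with 17 significant digits so the round trip is exact to
    double precision.
    """
    path = Path(path)
    rows = [(rec, _vector_of(f)) for rec, f in table]
    if rows:
        d = len(rows[0][1])
        for rec, v in rows:
            if len(v) != d:
                raise ValueError(
                    f"ragged feature lengths: {rec.image_path} has {len(v)}, expected {d}"
                )
    else:
        d = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_path", "case_id", "label"] + [f"f_{j}" for j in range(d)])
        for rec, v in rows:
            w.writerow([rec.image_path, rec.case_id, rec.label] + [f"{x:.17g}" for x in v])


def read_features(path):
    """Read a feature CSV back to a list of (SampleRecord, ndarray) pairs."""
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for col in ("image_path", "case_id", "label"):
            if col not in header:
                raise ValueError(f"feature table {path} is missing column {col!r}")
        n_meta = 3
        for row in reader:
            rec = SampleRecord(row[0], row[1], row[2])
            out.append((rec, np.array([float(x) for x in row[n_meta:]])))
    return out


def compose_roi(outer: RoiRect, inner: RoiRect) -> RoiRect:
    """ROI of `inner` taken inside the crop defined by `outer`, in parent coordinates."""
    return replace(inner, x0=outer.x0 + inner.x0, y0=outer.y0 + inner.y0)
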