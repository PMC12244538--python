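"""Histology tile container and image IO.

A :class:`HistologyTile` bundles an 8-bit RGB image with an optional binary
ground-truth mask (1 = mitotic-figure foreground) and provenance fields.
PNG/TIFF are first-class formats; DICOM is a thin optional adapter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

__all__ = [
    "HistologyTile",
    "read_tile",
    "write_tile",
    "read_manifest",
]


@dataclass
class HistologyTile:
    """An RGB histology tile with optional mitosis mask.

    Parameters
    ----------
    pixels : (H, W, 3) uint8
        RGB image, row-major, origin top-left.
    mask : (H, W) uint8, optional
        Binary mask, 1 marks mitotic-figure foreground.
    id : str
        Stable identifier used in manifests and reports.
    split_tag : {"train", "val", "test"}, optional
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    id: str = ""
    split_tag: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"tile pixels must be HxWx3 RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match pixels "
                    f"{self.pixels.shape[:2]}"
                )
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("mask values must be in {0, 1}")
            self.mask = self.mask.astype(np.uint8)
        if self.split_tag not in (None, "train", "val", "test"):
            raise ValueError(f"invalid split_tag {self.split_tag!r}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, mask=None) -> "HistologyTile":
        """Copy of this tile with new pixel (and optionally mask) data."""
        return replace(self, pixels=pixels, mask=self.mask if mask is None else mask)


def read_tile(path, id: Optional[str] = None, mask_path=None) -> HistologyTile:
    """Read a PNG/TIFF (or DICOM, if pydicom is installed) tile from disk."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        pixels = _read_dicom_rgb(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    mask = None
    if mask_path is not None:
        m = np.asarray(Image.open(mask_path).convert("L"))
        mask = (m > 127).astype(np.uint8)
    return HistologyTile(pixels=pixels, mask=mask, id=id or path.stem)


def _read_dicom_rgb(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM tiles requires the optional 'pydicom' dependency "
            "(pip install mitodet[dicom])"
        ) from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 2:  # monochrome payload -> replicate channels
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def write_tile(tile: HistologyTile, path, mask_path=None) -> None:
    """Write tile pixels (and optionally its mask) as PNG."""
    Image.fromarray(tile.pixels).save(path)
    if mask_path is not None and tile.mask is not None:
        Image.fromarray((tile.mask * 255).astype(np.uint8)).save(mask_path)


def read_manifest(path) -> list:
    """Read a tile manifest CSV with columns id, path, label[, mask_path]."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "path", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            rows.append(
                {
                    "id": row["id"],
                    "path": row["path"],
                    "label": int(row["label"]),
                    "mask_path": row.get("mask_path") or None,
                }
            )
    return rows
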