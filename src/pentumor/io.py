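"""Reading and writing images and manifests."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from .phantoms import GrayImage, LabeledDataset


def load_image(path: str | Path, levels: int = 256) -> GrayImage:
    """Load a grayscale image from PNG/TIFF (via Pillow) or DICOM (.dcm).

    DICOM pixel data is min-max rescaled to ``[0, levels - 1]``; other
    formats are converted to 8-bit grayscale.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo) * (levels - 1)
        else:
            arr = np.zeros_like(arr)
        return GrayImage(np.rint(arr).astype(np.int64), levels=levels)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int64)
    return GrayImage(arr, levels=256)


def save_label_map(label_map: np.ndarray, path: str | Path) -> None:
    """Write a class label map as an 8-bit PNG, stretched for visibility."""
    label_map = np.asarray(label_map)
    k = max(int(label_map.max()), 1)
    arr = (label_map * (255 // k)).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_manifest(manifest_path: str | Path) -> LabeledDataset:
    """Load a (filename, label) manifest CSV into a labeled image dataset.

    Filenames are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    items = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            items.append((load_image(base / row["filename"]), int(row["label"])))
    return LabeledDataset(items)
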