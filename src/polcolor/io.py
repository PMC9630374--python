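"""File formats: Mueller TIFF/NPZ stacks, observable stacks, PNG, class JSON.

Canonical on-disk Mueller layout is a multi-page 32-bit float TIFF with
exactly 16 pages in row-major element order m00, m01, ..., m33, or an NPZ
archive holding one array named "mueller" of shape (H, W, 4, 4).  Observable
stacks are 8-page float TIFFs in :data:`polcolor.observables.CHANNEL_NAMES`
order with a JSON sidecar naming the channels.  RGB output is 8-bit PNG with
the exact quantization round(255 * c).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .observables import CHANNEL_NAMES, MuellerImage, ObservableStack
from .pseudocolor import ClassModel, ROISpec

__all__ = [
    "read_mueller",
    "write_mueller",
    "write_observables",
    "read_observables",
    "write_png",
    "read_png",
    "write_label_map",
    "load_class_spec",
    "load_stats",
    "write_metadata",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


class FormatError(ValueError):
    """Input file does not match a supported Mueller-image layout."""


def read_mueller(path: str | Path) -> MuellerImage:
    """Read a Mueller image from a 16-page TIFF or an NPZ archive."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npz":
        with np.load(path) as archive:
            if "mueller" not in archive:
                raise FormatError(
                    f"{path}: archive must contain an array named 'mueller'"
                )
            arr = archive["mueller"]
        if arr.ndim != 4 or arr.shape[-2:] != (4, 4):
            raise FormatError(
                f"{path}: expected array of shape (H, W, 4, 4), got {arr.shape}"
            )
        return MuellerImage(elements=arr.astype(float))
    if path.suffix.lower() in _TIFF_SUFFIXES:
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] != 16:
            raise FormatError(
                f"{path}: expected 16 pages (m00..m33 row-major), got shape {pages.shape}"
            )
        h, w = pages.shape[1:]
        elements = np.moveaxis(pages, 0, -1).reshape(h, w, 4, 4)
        return MuellerImage(elements=elements.astype(float))
    raise FormatError(f"{path}: unsupported format (expected .tif/.tiff or .npz)")


def write_mueller(path: str | Path, image: MuellerImage | np.ndarray) -> None:
    """Write a Mueller image as 16-page float32 TIFF or NPZ, by suffix."""
    path = Path(path)
    elements = image.elements if isinstance(image, MuellerImage) else np.asarray(image)
    if path.suffix.lower() == ".npz":
        np.savez(path, mueller=elements.astype(np.float32))
        return
    if path.suffix.lower() in _TIFF_SUFFIXES:
        h, w = elements.shape[:2]
        pages = np.moveaxis(elements.reshape(h, w, 16), -1, 0)
        tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
        return
    raise FormatError(f"{path}: unsupported output format (expected .tif/.tiff or .npz)")


def write_observables(path: str | Path, stack: ObservableStack) -> Path:
    """Write the 8-channel observable stack as float32 TIFF plus a JSON
    sidecar listing the channel names.  Returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(path, stack.to_array().astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".channels.json")
    sidecar.write_text(json.dumps({"channels": list(CHANNEL_NAMES)}, indent=2))
    return sidecar


def read_observables(path: str | Path) -> ObservableStack:
    """Read an observable stack written by :func:`write_observables`."""
    pages = tifffile.imread(path).astype(float)
    if pages.ndim != 3 or pages.shape[0] != len(CHANNEL_NAMES):
        raise FormatError(
            f"{path}: expected {len(CHANNEL_NAMES)} pages, got shape {pages.shape}"
        )
    channels = dict(zip(CHANNEL_NAMES, pages))
    return ObservableStack(mask=channels["m00"] > 0, **channels)


def write_png(path: str | Path, rgb: np.ndarray) -> None:
    """8-bit PNG with bit-exact quantization round(255 * c)."""
    rgb = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(255.0 * rgb).astype(np.uint8))


def read_png(path: str | Path) -> np.ndarray:
    """PNG back to float RGB in [0, 1]."""
    return iio.imread(Path(path)).astype(float) / 255.0


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Label map as 8-bit grayscale PNG: 0 = unassigned/masked, i+1 = class i."""
    labels = np.asarray(labels)
    if labels.max() > 254:
        raise ValueError("label map supports at most 255 classes")
    iio.imwrite(Path(path), (labels + 1).clip(0, 255).astype(np.uint8))


def load_class_spec(path: str | Path) -> tuple[str, list[dict]]:
    """Parse the ROI/class JSON.

    Schema::

        {"triplet": "ipp" | "cp",
         "classes": [{"name": str, "color": [r, g, b],
                      "rois": [{"x0": int, "y0": int, "x1": int, "y1": int}, ...]},
                     ...]}

    Coordinates are 0-based and half-open.  Returns the triplet name and a
    list of ``{"roi": ROISpec, "color": ndarray}`` entries in file order.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    triplet = spec.get("triplet", "ipp")
    if triplet not in ("ipp", "cp"):
        raise FormatError(f"{path}: triplet must be 'ipp' or 'cp', got {triplet!r}")
    classes = spec.get("classes")
    if not classes:
        raise FormatError(f"{path}: at least one class is required")
    out = []
    for entry in classes:
        color = np.asarray(entry["color"], dtype=float)
        if color.shape != (3,) or color.min() < 0 or color.max() > 1:
            raise FormatError(
                f"{path}: class {entry.get('name')!r} color must be 3 values in [0, 1]"
            )
        rois = entry.get("rois")
        if not rois:
            raise FormatError(f"{path}: class {entry.get('name')!r} has no ROIs")
        roi = ROISpec(
            name=str(entry["name"]),
            rectangles=[(r["x0"], r["y0"], r["x1"], r["y1"]) for r in rois],
        )
        out.append({"roi": roi, "color": color})
    return triplet, out


def load_stats(path: str | Path) -> tuple[str, list[ClassModel]]:
    """Rebuild class models from a run-metadata JSON (see write_metadata)."""
    meta = json.loads(Path(path).read_text())
    models = [
        ClassModel(
            name=c["name"],
            means=np.asarray(c["means"], float),
            stds=np.asarray(c["stds"], float),
            color=np.asarray(c["color"], float),
        )
        for c in meta["classes"]
    ]
    return meta["triplet"], models


def write_metadata(
    path: str | Path,
    triplet: str,
    classes: list[ClassModel],
    config: dict | None = None,
) -> None:
    """Run metadata: config, class statistics and software version.

    Re-running the renderer from these statistics (``--stats-from``)
    reproduces the identical RGB image.
    """
    from . import __version__

    meta = {
        "software": {"name": "polcolor", "version": __version__},
        "triplet": triplet,
        "std_definition": "sample (ddof=1)",
        "classes": [
            {
                "name": c.name,
                "means": c.means.tolist(),
                "stds": c.stds.tolist(),
                "color": c.color.tolist(),
            }
            for c in classes
        ],
    }
    if config:
        meta["config"] = config
    Path(path).write_text(json.dumps(meta, indent=2))
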