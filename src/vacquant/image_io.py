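"""Raster I/O: section images, exclusion masks, class maps and results tables.

Conventions fixed here and used everywhere else in the package:

* images are ``(H, W, 3)`` uint8 arrays, channel order R, G, B, 0-based
  row-major coordinates with pixel ``(0, 0)`` at the top-left;
* exclusion masks are ``(H, W)`` boolean arrays where ``True`` means the pixel
  participates in classification and counting (an all-true mask is the
  identity, equivalent to no cropping);
* class maps are ``(H, W)`` uint8 arrays over ``{0, 1, 2}`` =
  {background, brain tissue, vacuole}, written to disk with the fixed palette
  purple / red / green.
"""

from __future__ import annotations

import csv
import os
from typing import TYPE_CHECKING, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from vacquant.quantify import SectionResult

#: Fixed class -> RGB palette for saved class maps:
#: 0 background -> purple, 1 brain tissue -> red, 2 vacuole -> green.
CLASS_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (128, 0, 128),
    1: (255, 0, 0),
    2: (0, 255, 0),
}

N_CLASSES = 3

RESULTS_HEADER = (
    "image",
    "background_px",
    "tissue_px",
    "vacuole_px",
    "percent_vacuolation",
)


class ImageFormatError(ValueError):
    """Raised when a raster file cannot be read or has an unsupported layout."""


class MaskShapeError(ValueError):
    """Raised when a mask raster does not match its paired image shape."""


def _read_raster(path: str | os.PathLike) -> np.ndarray:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ImageFormatError(f"no such image file: {path!r}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"cannot read raster file {path!r}: {exc}") from exc
    return np.asarray(arr)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a TIFF or PNG section image as an ``(H, W, 3)`` uint8 RGB array.

    Grayscale sources are replicated across the three channels; an alpha
    channel, if present, is dropped. 16-bit sources are rescaled to 8-bit.
    """
    arr = _read_raster(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = arr[:, :, :3]
    else:
        raise ImageFormatError(
            f"unsupported raster layout {arr.shape} in {os.fspath(path)!r}; "
            "expected HxW grayscale or HxWx3/4 color"
        )
    if arr.dtype == np.uint8:
        pass
    elif arr.dtype == np.uint16:
        arr = (arr / 257.0).round().astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.round(arr * 255.0 if arr.max() <= 1.0 else arr), 0, 255)
        arr = arr.astype(np.uint8)
    else:
        raise ImageFormatError(
            f"unsupported pixel dtype {arr.dtype} in {os.fspath(path)!r}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ImageFormatError(f"empty raster in {os.fspath(path)!r}")
    return arr


def load_mask(
    path: str | os.PathLike | None, image: np.ndarray
) -> np.ndarray:
    """Load a binary exclusion mask paired with ``image``.

    Nonzero mask pixels are included, zero pixels excluded. When ``path`` is
    None an all-true mask of the image shape is returned (no cropping). The
    mask is the programmatic stand-in for manually cropping away eyes, other
    stained structures and tissue rips before quantification.
    """
    shape = image.shape[:2]
    if path is None:
        return np.ones(shape, dtype=bool)
    arr = _read_raster(path)
    if arr.ndim == 3:
        arr = arr[:, :, :3].max(axis=2)
    if arr.shape != shape:
        raise MaskShapeError(
            f"mask shape {arr.shape} does not match image shape {shape}"
        )
    return arr != 0


def write_classmap(labels: np.ndarray, path: str | os.PathLike) -> str:
    """Write a class map as an RGB raster using the fixed palette.

    Round trip: :func:`read_classmap` on the written file recovers the
    identical label array.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"class map must be 2-D, got shape {labels.shape}")
    if not np.isin(labels, list(CLASS_PALETTE)).all():
        raise ValueError("class map contains labels outside {0, 1, 2}")
    lut = np.zeros((N_CLASSES, 3), dtype=np.uint8)
    for cls, rgb in CLASS_PALETTE.items():
        lut[cls] = rgb
    rgb = lut[labels.astype(np.intp)]
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, rgb)
    else:
        iio.imwrite(path, rgb)
    return path


def read_classmap(path: str | os.PathLike) -> np.ndarray:
    """Read a palette-coded class map back into a label array (inverse of write)."""
    rgb = read_image(path)
    labels = np.full(rgb.shape[:2], -1, dtype=np.int16)
    for cls, color in CLASS_PALETTE.items():
        labels[(rgb == np.array(color, dtype=np.uint8)).all(axis=2)] = cls
    if (labels < 0).any():
        raise ImageFormatError(
            f"{os.fspath(path)!r} contains colors outside the class palette"
        )
    return labels.astype(np.uint8)


def write_results_table(
    results: Sequence["SectionResult"], path: str | os.PathLike
) -> str:
    """Write per-section quantification results as a CSV table.

    One row per section in input order; percent vacuolation is written with
    six significant digits. Sections flagged as failed carry their image id
    and empty measurement fields.
    """
    path = os.fspath(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for res in results:
            if res.error is not None:
                writer.writerow([res.image_id, "", "", "", ""])
                continue
            c = res.counts
            writer.writerow(
                [
                    res.image_id,
                    c.background_px,
                    c.tissue_px,
                    c.vacuole_px,
                    format(res.percent_vacuolation, ".6g"),
                ]
            )
    return path
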