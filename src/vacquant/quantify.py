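"""Batch quantification: classify a folder of sections and tabulate vacuolation.

Percent vacuolation is defined as vacuole pixels over total brain area
(tissue + vacuole pixels), times 100. Background pixels are excluded from the
denominator so the metric does not depend on how the section was framed or
cropped.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from vacquant import image_io
from vacquant.features import build_feature_stack
from vacquant.segmentation import ClassifierModel, classify_image

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")


class EmptySectionError(ValueError):
    """Raised when a class map contains no brain pixels (tissue + vacuole = 0)."""


class EmptyInputError(ValueError):
    """Raised when the input folder contains no readable images."""


@dataclass(frozen=True)
class ClassCounts:
    """Exact pixel histogram of a class map."""

    background_px: int
    tissue_px: int
    vacuole_px: int

    @property
    def total(self) -> int:
        return self.background_px + self.tissue_px + self.vacuole_px


@dataclass(frozen=True)
class SectionResult:
    """Quantification of one section; ``error`` is set for flagged sections."""

    image_id: str
    counts: ClassCounts | None
    percent_vacuolation: float | None
    error: str | None = None


def count_classes(classmap: np.ndarray) -> ClassCounts:
    """Exact integer histogram of a class map over {0, 1, 2}."""
    classmap = np.asarray(classmap)
    counts = np.bincount(classmap.ravel(), minlength=3)
    if counts[3:].any():
        raise ValueError("class map contains labels outside {0, 1, 2}")
    return ClassCounts(int(counts[0]), int(counts[1]), int(counts[2]))


def percent_vacuolation(counts: ClassCounts) -> float:
    """``100 * vacuole_px / (tissue_px + vacuole_px)`` — percent of brain area.

    Raises :class:`EmptySectionError` when the section contains no brain
    pixels at all; such sections are flagged in the results table rather than
    silently reported as zero.
    """
    brain = counts.tissue_px + counts.vacuole_px
    if brain == 0:
        raise EmptySectionError(
            "section has no tissue or vacuole pixels; percent vacuolation "
            "is undefined"
        )
    return 100.0 * counts.vacuole_px / brain


def quantify_classmap(image_id: str, classmap: np.ndarray) -> SectionResult:
    """Counts and percent vacuolation for one already-classified section."""
    counts = count_classes(classmap)
    return SectionResult(image_id, counts, percent_vacuolation(counts))


def list_section_images(input_dir: str | os.PathLike) -> list[str]:
    """Image filenames in a folder, lexicographic order (the processing order)."""
    names = [
        n
        for n in sorted(os.listdir(input_dir))
        if n.lower().endswith(IMAGE_EXTENSIONS)
    ]
    return names


def batch_quantify(
    input_dir: str | os.PathLike,
    model: ClassifierModel,
    mask_dir: str | os.PathLike | None = None,
    output_dir: str | os.PathLike | None = None,
    results_name: str = "results.csv",
) -> list[SectionResult]:
    """Classify and quantify every section image in a folder.

    For each image, in lexicographic filename order: read, load its exclusion
    mask (``mask_dir/<same filename>`` if present, else no exclusion), build
    the feature stack, classify, save the colour-coded class map under the
    original image name in ``output_dir``, count class pixels and compute
    percent vacuolation. Per-image failures are logged and recorded as
    flagged rows rather than aborting the batch. The collated CSV is written
    to ``output_dir/results_name`` at the end.
    """
    names = list_section_images(input_dir)
    if not names:
        raise EmptyInputError(f"no section images found in {os.fspath(input_dir)!r}")
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        if not os.access(output_dir, os.W_OK):
            raise OSError(f"output directory {os.fspath(output_dir)!r} not writable")

    results: list[SectionResult] = []
    for name in names:
        image_id = os.path.splitext(name)[0]
        t0 = time.perf_counter()
        try:
            image = image_io.read_image(os.path.join(input_dir, name))
            mask_path = None
            if mask_dir is not None:
                candidate = os.path.join(mask_dir, name)
                if os.path.exists(candidate):
                    mask_path = candidate
            mask = image_io.load_mask(mask_path, image)
            stack = build_feature_stack(image, model.feature_config)
            classmap = classify_image(stack, model, mask)
            if output_dir is not None:
                image_io.write_classmap(
                    classmap, os.path.join(output_dir, image_id + "_classified.png")
                )
            res = quantify_classmap(image_id, classmap)
        except Exception as exc:  # noqa: BLE001 - per-image failure isolation
            logger.warning("section %s flagged: %s", image_id, exc)
            res = SectionResult(image_id, None, None, error=str(exc))
        else:
            logger.info(
                "section %s: bg=%d tissue=%d vacuole=%d percent=%.4g (%.2fs)",
                image_id,
                res.counts.background_px,
                res.counts.tissue_px,
                res.counts.vacuole_px,
                res.percent_vacuolation,
                time.perf_counter() - t0,
            )
        results.append(res)

    if output_dir is not None:
        image_io.write_results_table(results, os.path.join(output_dir, results_name))
    return results
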