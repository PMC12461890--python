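"""Train, persist and apply the random-forest pixel classifier.

The workflow mirrors interactive trainable segmentation: a user labels a
handful of scribbles per image (one or two examples of background, tissue and
vacuole on roughly ten images), a random forest is fitted to the feature
vectors of the labelled pixels, and the model is then applied to whole images
to produce full-resolution class maps. Everything is seeded and ordered so a
fixed set of inputs yields bit-identical class maps across runs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from skimage import draw
from sklearn.ensemble import RandomForestClassifier

from vacquant.features import FeatureConfig, FeatureStack
from vacquant.image_io import N_CLASSES

MODEL_FORMAT_VERSION = 1

CLASS_NAMES = {0: "background", 1: "tissue", 2: "vacuole"}


class TrainingCoverageError(ValueError):
    """Raised when some class has no training annotation."""


class LabelCoordinateError(ValueError):
    """Raised when an annotation falls outside its image bounds."""


class FeatureMismatchError(ValueError):
    """Raised when a stack's feature names differ from a model's."""


class ModelFormatError(ValueError):
    """Raised when a persisted model file is unreadable or incompatible."""


@dataclass(frozen=True)
class RandomForestConfig:
    """Random-forest hyperparameters.

    Defaults follow common trainable-segmentation practice: 200 trees,
    sqrt(F) candidate features per split. Classes are weighted inversely to
    their training frequency by default because with scribble annotation the
    per-class pixel counts reflect scribble lengths, not meaningful priors.
    """

    n_trees: int = 200
    max_features_per_split: str | int | float = "sqrt"
    min_samples_leaf: int = 1
    class_weight: str | None = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RandomForestConfig":
        return cls(**d)


@dataclass(frozen=True)
class Annotation:
    """One sparse label: a point, polyline scribble or polygon of one class.

    Coordinates are ``(row, col)`` pairs, 0-based. A polygon is rasterised to
    every pixel whose centre lies inside it; a polyline to the pixels it
    traverses; a point to a single pixel.
    """

    image_id: str
    cls: int
    geometry: str  # "point" | "polyline" | "polygon"
    coords: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.cls not in CLASS_NAMES:
            raise ValueError(f"class must be in {set(CLASS_NAMES)}, got {self.cls}")
        if self.geometry not in ("point", "polyline", "polygon"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not self.coords:
            raise ValueError("annotation has no coordinates")

    def rasterize(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Pixel (rows, cols) covered by the annotation within ``shape``."""
        pts = np.asarray(self.coords, dtype=float)
        if (pts < 0).any() or (pts[:, 0] > shape[0] - 1).any() or (
            pts[:, 1] > shape[1] - 1
        ).any():
            raise LabelCoordinateError(
                f"annotation on {self.image_id!r} has coordinates outside "
                f"the {shape[0]}x{shape[1]} image"
            )
        if self.geometry == "point":
            rr = np.round(pts[:, 0]).astype(np.intp)
            cc = np.round(pts[:, 1]).astype(np.intp)
        elif self.geometry == "polyline":
            rs, cs = [], []
            rounded = np.round(pts).astype(np.intp)
            if len(rounded) == 1:
                rs, cs = [rounded[:, 0]], [rounded[:, 1]]
            for (r0, c0), (r1, c1) in zip(rounded[:-1], rounded[1:]):
                rr_, cc_ = draw.line(r0, c0, r1, c1)
                rs.append(rr_)
                cs.append(cc_)
            rr = np.concatenate(rs)
            cc = np.concatenate(cs)
        else:
            rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
        # dedupe while keeping a deterministic row-major order
        flat = np.unique(rr.astype(np.intp) * shape[1] + cc.astype(np.intp))
        return flat // shape[1], flat % shape[1]


def load_annotations(path: str | os.PathLike) -> list[Annotation]:
    """Read sparse labels from a JSON annotation file.

    Schema: ``{"<image_id>": [{"class": 0|1|2, "type": "point"|"polyline"|
    "polygon", "coords": [[row, col], ...]}, ...], ...}``.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    out = []
    for image_id, entries in data.items():
        for e in entries:
            out.append(
                Annotation(
                    image_id=image_id,
                    cls=int(e["class"]),
                    geometry=e["type"],
                    coords=tuple((float(r), float(c)) for r, c in e["coords"]),
                )
            )
    return out


def annotations_from_label_image(
    image_id: str, label_raster: np.ndarray
) -> list[Annotation]:
    """Convert a label raster (0 = unlabelled, 1..3 = class + 1) to point labels."""
    label_raster = np.asarray(label_raster)
    out = []
    for cls in CLASS_NAMES:
        rr, cc = np.nonzero(label_raster == cls + 1)
        for r, c in zip(rr, cc):
            out.append(
                Annotation(image_id, cls, "point", ((float(r), float(c)),))
            )
    return out


def extract_training_set(
    stacks: Mapping[str, FeatureStack], labels: Iterable[Annotation]
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise sparse labels against their feature stacks.

    Returns ``(samples, targets)`` with one row per labelled pixel, ordered
    deterministically by image id then row-major pixel coordinate (ties
    between overlapping annotations of different classes on one pixel keep
    both rows, ordered by class).
    """
    labels = list(labels)
    per_image: dict[str, list[Annotation]] = {}
    for ann in labels:
        if ann.image_id not in stacks:
            raise KeyError(f"no feature stack provided for image {ann.image_id!r}")
        per_image.setdefault(ann.image_id, []).append(ann)

    rows_x: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    for image_id in sorted(per_image):
        stack = stacks[image_id]
        shape = stack.shape
        pix: list[tuple[int, int, int]] = []  # (flat index, class)
        for ann in per_image[image_id]:
            rr, cc = ann.rasterize(shape)
            flat = rr * shape[1] + cc
            pix.extend((int(f), ann.cls) for f in flat)
        pix.sort()
        flat_idx = np.array([p[0] for p in pix], dtype=np.intp)
        classes = np.array([p[1] for p in pix], dtype=np.int64)
        values = stack.values.reshape(-1, stack.values.shape[2])
        rows_x.append(values[flat_idx])
        rows_y.append(classes)

    if not rows_x:
        raise TrainingCoverageError("no annotations supplied")
    samples = np.concatenate(rows_x)
    targets = np.concatenate(rows_y)
    missing = set(CLASS_NAMES) - set(np.unique(targets).tolist())
    if missing:
        names = ", ".join(CLASS_NAMES[c] for c in sorted(missing))
        raise TrainingCoverageError(
            f"training labels missing class(es): {names}; every class needs "
            "at least one annotation"
        )
    return samples, targets


@dataclass
class ClassifierModel:
    """A trained pixel classifier plus everything needed to rebuild its inputs."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    feature_config: FeatureConfig
    forest_config: RandomForestConfig
    training_summary: dict[str, int] = field(default_factory=dict)


def train_classifier(
    samples: np.ndarray,
    targets: np.ndarray,
    forest_config: RandomForestConfig | None = None,
    feature_config: FeatureConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> ClassifierModel:
    """Fit the random forest on labelled pixel feature vectors.

    With a fixed seed, two trainings on identical inputs yield models with
    identical predictions. All three classes must be present in ``targets``.
    """
    if forest_config is None:
        forest_config = RandomForestConfig()
    if feature_config is None:
        feature_config = FeatureConfig()
    if feature_names is None:
        feature_names = feature_config.feature_names()
    samples = np.asarray(samples, dtype=np.float64)
    targets = np.asarray(targets)
    if samples.ndim != 2 or samples.shape[0] != targets.shape[0]:
        raise ValueError("samples must be (N, F) with one target per row")
    if samples.shape[1] != len(feature_names):
        raise FeatureMismatchError(
            f"samples have {samples.shape[1]} features but "
            f"{len(feature_names)} feature names were given"
        )
    present = set(np.unique(targets).tolist())
    missing = set(CLASS_NAMES) - present
    if missing:
        names = ", ".join(CLASS_NAMES[c] for c in sorted(missing))
        raise TrainingCoverageError(f"cannot train: no samples for class(es) {names}")

    forest = RandomForestClassifier(
        n_estimators=forest_config.n_trees,
        max_features=forest_config.max_features_per_split,
        min_samples_leaf=forest_config.min_samples_leaf,
        class_weight=forest_config.class_weight,
        random_state=forest_config.seed,
        n_jobs=1,
    )
    forest.fit(samples, targets)
    counts = {
        CLASS_NAMES[c]: int((targets == c).sum()) for c in sorted(CLASS_NAMES)
    }
    return ClassifierModel(
        forest=forest,
        feature_names=tuple(feature_names),
        feature_config=feature_config,
        forest_config=forest_config,
        training_summary=counts,
    )


def classify_image(
    stack: FeatureStack,
    model: ClassifierModel,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Assign every included pixel its forest-vote class; excluded pixels get 0.

    Votes are averaged class probabilities over the trees; ties break toward
    the lowest class index. Deterministic given model and stack.
    """
    if tuple(stack.feature_names) != tuple(model.feature_names):
        raise FeatureMismatchError(
            "feature stack is incompatible with the model:\n"
            f"  stack: {list(stack.feature_names)}\n"
            f"  model: {list(model.feature_names)}"
        )
    h, w = stack.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (h, w):
        raise ValueError(f"mask shape {mask.shape} does not match stack {(h, w)}")

    labels = np.zeros((h, w), dtype=np.uint8)
    flat_mask = mask.ravel()
    if flat_mask.any():
        values = stack.values.reshape(-1, stack.values.shape[2])[flat_mask]
        proba = model.forest.predict_proba(values)
        # argmax returns the first (lowest-index) class on ties
        pred = model.forest.classes_[np.argmax(proba, axis=1)]
        out = labels.ravel()
        out[flat_mask] = pred.astype(np.uint8)
        labels = out.reshape(h, w)
    return labels


def save_model(model: ClassifierModel, path: str | os.PathLike) -> str:
    """Persist a trained model (forest + feature/forest configs + names)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "feature_config": model.feature_config.to_dict(),
        "forest_config": model.forest_config.to_dict(),
        "training_summary": model.training_summary,
        "forest": model.forest,
    }
    joblib.dump(payload, os.fspath(path))
    return os.fspath(path)


def load_model(path: str | os.PathLike) -> ClassifierModel:
    """Load a persisted model; a reloaded model predicts identically.

    Raises :class:`ModelFormatError` when the file is missing fields, carries
    an unknown format version, or its feature names are inconsistent with its
    embedded feature configuration.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        payload = joblib.load(path)
        version = payload["format_version"]
        feature_names = tuple(payload["feature_names"])
        feature_config = FeatureConfig.from_dict(payload["feature_config"])
        forest_config = RandomForestConfig.from_dict(payload["forest_config"])
        forest = payload["forest"]
        summary = payload.get("training_summary", {})
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path!r}: {exc}") from exc
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {version} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    expected = tuple(feature_config.feature_names())
    if feature_names != expected:
        raise ModelFormatError(
            "model feature names are inconsistent with its feature "
            f"configuration:\n  stored: {list(feature_names)}\n"
            f"  config implies: {list(expected)}"
        )
    return ClassifierModel(
        forest=forest,
        feature_names=feature_names,
        feature_config=feature_config,
        forest_config=forest_config,
        training_summary=summary,
    )
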