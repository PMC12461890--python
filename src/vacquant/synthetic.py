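"""Seeded synthetic H&E-like brain sections with exact ground truth.

Real stained sections of fly brains are not distributable with the package,
so every other module is exercised on synthetic sections that emulate their
salient structure: an elliptical tissue region with pink eosin staining and
fine darker speckle (hematoxylin-stained nuclei), embedded white vacuoles
spanning a size range from a few pixels to large cavities, a white
background, and the two classic confounders — rips reaching the tissue edge
(white gashes that look like vacuoles) and stained non-brain structures such
as eyes sitting outside the tissue. Ground-truth class masks are exact by
construction: vacuoles are non-overlapping ellipses carved out of the tissue
ellipse.

The generator is fully deterministic under its seed: the same spec always
produces bit-identical images and masks.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from vacquant.segmentation import Annotation

DEFAULT_CANVAS = (192, 256)  # (H, W); a scaled-down 20x section capture

# stain absorbances per RGB channel (white - absorbance = rendered colour)
_EOSIN_ABSORB = np.array([0.12, 0.62, 0.40])  # pink tissue
_HEMATOXYLIN_ABSORB = np.array([0.45, 0.55, 0.15])  # purple nuclei speckle
_DISTRACTOR_ABSORB = np.array([0.40, 0.80, 0.55])  # densely stained eye/organ
_BACKGROUND_LEVEL = 0.98
_RENDER_BLUR_SIGMA = 0.5  # sub-pixel optical blur
_NUCLEI_DENSITY = 0.02


class FeasibilityError(RuntimeError):
    """Raised when a spec's vacuole fraction is unreachable by placement."""


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one synthetic section.

    ``target_vacuole_fraction`` is the desired vacuole area as a fraction of
    total brain area (tissue + vacuoles); the realised fraction is
    rejection-sampled to within ±20% relative of the target.
    ``vacuole_count_bias`` mixes the two phenotype regimes: it is the
    probability of drawing a vacuole radius from the upper (few-large) half
    of the size range rather than the lower (many-small) half.
    ``rip`` is an optional ``(width_px, orientation_deg)`` white tear running
    from outside the tissue edge toward its centre. ``distractors`` counts
    stained non-brain blobs placed outside the tissue.
    """

    canvas: tuple[int, int] = DEFAULT_CANVAS
    target_vacuole_fraction: float = 0.05
    vacuole_size_range: tuple[float, float] = (3.0, 20.0)
    vacuole_count_bias: float = 0.3
    stain_intensity: float = 0.65
    stain_noise_sd: float = 0.05
    rip: tuple[float, float] | None = None
    distractors: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_vacuole_fraction <= 0.5):
            raise ValueError("target_vacuole_fraction must be in [0, 0.5]")
        rmin, rmax = self.vacuole_size_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("vacuole radii must satisfy 1 <= min <= max")
        if not (0.0 <= self.vacuole_count_bias <= 1.0):
            raise ValueError("vacuole_count_bias must be in [0, 1]")
        if not (0.0 < self.stain_intensity <= 1.0):
            raise ValueError("stain_intensity must be in (0, 1]")
        if self.stain_noise_sd < 0:
            raise ValueError("stain_noise_sd must be >= 0")
        if self.distractors < 0:
            raise ValueError("distractors must be >= 0")
        if self.canvas[0] < 32 or self.canvas[1] < 32:
            raise ValueError("canvas must be at least 32x32")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-pixel truth for one synthetic section.

    ``mask`` holds classes {0 background, 1 tissue, 2 vacuole}; rips and
    distractors are class 0 (they are neither brain tissue nor vacuole).
    ``include_mask`` is the crop a careful user would draw before
    quantification: the brain region plus a small margin, with any rip cut
    out generously — everything else (far background, eyes and other stained
    structures) is excluded. ``artefact_mask`` marks the rip and distractor
    pixels themselves (slightly dilated), for placing annotations clear of
    them.
    """

    mask: np.ndarray
    true_vacuole_fraction: float
    include_mask: np.ndarray
    artefact_mask: np.ndarray


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation: float,
) -> np.ndarray:
    rr, cc = draw.ellipse(
        center[0], center[1], axes[0], axes[1], shape=shape, rotation=rotation
    )
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _place_vacuoles(
    rng: np.random.Generator,
    spec: SectionSpec,
    tissue: np.ndarray,
) -> np.ndarray:
    """Carve non-overlapping elliptical vacuoles until the target is reached."""
    shape = tissue.shape
    tissue_area = int(tissue.sum())
    target_area = spec.target_vacuole_fraction * tissue_area
    vac = np.zeros(shape, dtype=bool)
    if target_area <= 0:
        return vac

    rmin, rmax = spec.vacuole_size_range
    rmid = float(np.sqrt(rmin * rmax))
    inner = ndimage.binary_erosion(tissue, iterations=2)
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    area = 0.0
    attempts = 0
    max_attempts = 4000
    while area < 0.97 * target_area and attempts < max_attempts:
        attempts += 1
        # regime mixture: many small vs few large
        if rng.random() < spec.vacuole_count_bias:
            r = np.exp(rng.uniform(np.log(rmid), np.log(rmax)))
        else:
            r = np.exp(rng.uniform(np.log(rmin), np.log(rmid)))
        # never overshoot the +15% band around the target
        r_cap = np.sqrt(max(target_area * 1.15 - area, 0.0) / np.pi)
        if r_cap < rmin:
            break
        r = min(r, r_cap)
        aspect = rng.uniform(0.75, 1.33)
        ra, rb = r * aspect, r / aspect
        rot = rng.uniform(0, np.pi)
        bound = max(ra, rb)
        r0 = rng.uniform(bound, shape[0] - bound)
        c0 = rng.uniform(bound, shape[1] - bound)
        if any(
            np.hypot(r0 - pr, c0 - pc) < bound + pb + 2 for pr, pc, pb in placed
        ):
            continue
        rr, cc = draw.ellipse(r0, c0, ra, rb, shape=shape, rotation=rot)
        if rr.size == 0 or not inner[rr, cc].all():
            continue
        vac[rr, cc] = True
        placed.append((r0, c0, bound))
        area += rr.size
    if area < 0.8 * target_area:
        raise FeasibilityError(
            f"could not reach vacuole fraction {spec.target_vacuole_fraction:.3g} "
            f"with radii in {spec.vacuole_size_range} after {attempts} proposals"
        )
    return vac


def _rip_mask(
    rng: np.random.Generator,
    spec: SectionSpec,
    tissue: np.ndarray,
    center: tuple[float, float],
) -> np.ndarray:
    """A white tear of the given width running from outside the edge inward."""
    width, orientation_deg = spec.rip
    theta = np.deg2rad(orientation_deg)
    direction = np.array([np.cos(theta), np.sin(theta)])
    c = np.array(center)
    # walk outward from the centre to find the tissue boundary
    t = 0.0
    step = 1.0
    shape = tissue.shape
    while True:
        p = c + (t + step) * direction
        if (
            p[0] < 0
            or p[1] < 0
            or p[0] > shape[0] - 1
            or p[1] > shape[1] - 1
            or not tissue[int(round(p[0])), int(round(p[1]))]
        ):
            break
        t += step
    start = c + (t + 3.0) * direction  # just outside the edge
    end = c + 0.35 * t * direction  # deep into the tissue
    normal = np.array([-direction[1], direction[0]]) * (width / 2.0)
    corners = np.array([start + normal, start - normal, end - normal, end + normal])
    rr, cc = draw.polygon(corners[:, 0], corners[:, 1], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def generate_section(spec: SectionSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic section and its exact ground truth.

    Returns ``(image, truth)`` where image is ``(H, W, 3)`` uint8. The
    realised vacuole fraction is rejection-sampled (bounded retries with
    derived seeds) until it lies within ±20% relative of the target.
    """
    last_exc: FeasibilityError | None = None
    for retry in range(6):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) % (2**31), retry])
        )
        try:
            result = _generate_once(rng, spec)
        except FeasibilityError as exc:
            last_exc = exc
            continue
        image, truth = result
        if spec.target_vacuole_fraction == 0:
            return image, truth
        rel = abs(truth.true_vacuole_fraction - spec.target_vacuole_fraction)
        if rel <= 0.2 * spec.target_vacuole_fraction:
            return image, truth
        last_exc = FeasibilityError(
            f"realised fraction {truth.true_vacuole_fraction:.4g} outside ±20% of "
            f"target {spec.target_vacuole_fraction:.4g}"
        )
    raise last_exc


def _generate_once(
    rng: np.random.Generator, spec: SectionSpec
) -> tuple[np.ndarray, GroundTruth]:
    h, w = spec.canvas
    shape = (h, w)
    center = (
        h / 2 + rng.uniform(-0.02 * h, 0.02 * h),
        w / 2 + rng.uniform(-0.02 * w, 0.02 * w),
    )
    axes = (
        0.33 * h * rng.uniform(0.92, 1.08),
        0.38 * w * rng.uniform(0.92, 1.08),
    )
    rotation = rng.uniform(-0.25, 0.25)
    tissue = _ellipse_mask(shape, center, axes, rotation)

    vac = _place_vacuoles(rng, spec, tissue)
    rip = (
        _rip_mask(rng, spec, tissue, center)
        if spec.rip is not None
        else np.zeros(shape, dtype=bool)
    )

    distractor = np.zeros(shape, dtype=bool)
    outside = ~ndimage.binary_dilation(tissue, iterations=4)
    for _ in range(spec.distractors):
        for _attempt in range(200):
            r = rng.uniform(5, 10)
            r0 = rng.uniform(r + 1, h - r - 1)
            c0 = rng.uniform(r + 1, w - r - 1)
            rr, cc = draw.ellipse(
                r0, c0, r * rng.uniform(0.8, 1.2), r, shape=shape,
                rotation=rng.uniform(0, np.pi),
            )
            if rr.size and outside[rr, cc].all() and not distractor[rr, cc].any():
                distractor[rr, cc] = True
                break

    # ---- truth ----
    mask = np.zeros(shape, dtype=np.uint8)
    mask[tissue] = 1
    mask[vac & tissue] = 2
    mask[rip] = 0
    mask[distractor] = 0
    tissue_px = int((mask == 1).sum())
    vac_px = int((mask == 2).sum())
    if tissue_px + vac_px == 0:
        raise FeasibilityError("rip removed the entire tissue region")
    true_fraction = vac_px / (tissue_px + vac_px)
    artefacts = rip | distractor
    if artefacts.any():
        artefacts = ndimage.binary_dilation(artefacts, iterations=3)
    # paper-style crop: keep the brain plus a tight margin, cut rips out wide
    include = ndimage.binary_dilation(tissue, iterations=3)
    if rip.any():
        include &= ~ndimage.binary_dilation(rip, iterations=6)
    if distractor.any():
        include &= ~ndimage.binary_dilation(distractor, iterations=6)

    # ---- render ----
    absorb = np.zeros((h, w, 3))
    stained = (mask == 1) & ~rip
    absorb[stained] = spec.stain_intensity * _EOSIN_ABSORB
    # hematoxylin nuclei speckle inside tissue
    speckle = (rng.random(shape) < _NUCLEI_DENSITY) & stained
    absorb[speckle] += spec.stain_intensity * _HEMATOXYLIN_ABSORB
    absorb[distractor] = _DISTRACTOR_ABSORB
    # multiplicative staining-texture noise
    if spec.stain_noise_sd > 0:
        field = 1.0 + spec.stain_noise_sd * rng.standard_normal(shape)
        absorb *= np.clip(field, 0.0, 2.0)[:, :, None]
    img = _BACKGROUND_LEVEL - absorb
    img += 0.005 * rng.standard_normal((h, w, 3))  # sensor noise
    img = np.stack(
        [ndimage.gaussian_filter(img[:, :, c], _RENDER_BLUR_SIGMA) for c in range(3)],
        axis=-1,
    )
    image = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return image, GroundTruth(mask, true_fraction, include, artefacts)


def truth_percent(truth: GroundTruth) -> float:
    """Percent vacuolation implied by a ground-truth mask (exact)."""
    return 100.0 * truth.true_vacuole_fraction


def _scribble_in(
    image_id: str,
    cls: int,
    region: np.ndarray,
    rng: np.random.Generator,
    scribble_length: int,
) -> Annotation:
    """One short polyline fully inside ``region``.

    The scribble shrinks until it fits (a user draws as long a stroke as the
    region allows), degenerating to a single point in the smallest regions.
    """
    shape = region.shape
    rr, cc = np.nonzero(region)
    length = scribble_length
    while length >= 3:
        for _ in range(40):
            i = rng.integers(len(rr))
            r0, c0 = int(rr[i]), int(cc[i])
            theta = rng.uniform(0, 2 * np.pi)
            r1 = int(round(r0 + length * np.cos(theta)))
            c1 = int(round(c0 + length * np.sin(theta)))
            if not (0 <= r1 < shape[0] and 0 <= c1 < shape[1]):
                continue
            line_rr, line_cc = draw.line(r0, c0, r1, c1)
            if region[line_rr, line_cc].all():
                return Annotation(
                    image_id, cls, "polyline",
                    ((float(r0), float(c0)), (float(r1), float(c1))),
                )
        length -= 2
    i = rng.integers(len(rr))
    return Annotation(image_id, cls, "point", ((float(rr[i]), float(cc[i])),))


def _contour_trace(
    image_id: str,
    cls: int,
    region: np.ndarray,
    valid: np.ndarray,
    rng: np.random.Generator,
    offset: float = 3.0,
    n_vertices: int | None = None,
) -> Annotation | None:
    """A closed trace running around ``region`` at ``offset`` px outside it.

    Mirrors the way a user traces around a border — around the whole section
    to teach near-boundary white as background, or around a vacuole to teach
    the surrounding tissue. Every rasterised pixel must fall in ``valid``
    (truth pixels of ``cls``); returns None when no clean trace exists (e.g.
    a rip breaks the contour).
    """
    from skimage import measure

    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    centroid = np.array(ndimage.center_of_mass(region))
    shape = region.shape
    if n_vertices is None:
        n_vertices = max(8, len(contour) // 8)
    for _ in range(20):
        start = int(rng.integers(len(contour)))
        idx = [
            (start + (len(contour) * k) // n_vertices) % len(contour)
            for k in range(n_vertices)
        ]
        idx.append(idx[0])  # close the loop
        pts = contour[idx]
        radial = pts - centroid
        norms = np.linalg.norm(radial, axis=1, keepdims=True)
        if (norms < 1e-6).any():
            continue
        pts = pts + offset * radial / norms
        if (pts < 1).any() or (pts[:, 0] > shape[0] - 2).any() or (
            pts[:, 1] > shape[1] - 2
        ).any():
            continue
        ann = Annotation(
            image_id, cls, "polyline", tuple((float(r), float(c)) for r, c in pts)
        )
        rr, cc = ann.rasterize(shape)
        if valid[rr, cc].all():
            return ann
    return None


def _wandering_scribble(
    image_id: str,
    cls: int,
    region: np.ndarray,
    rng: np.random.Generator,
    n_segments: int = 5,
    step: float = 14.0,
) -> Annotation | None:
    """A long multi-segment scribble wandering through ``region``.

    Emulates the broad strokes a user drags across large uniform areas; the
    path covers a range of distances from the tissue in one annotation.
    """
    rr, cc = np.nonzero(region)
    shape = region.shape
    for _ in range(60):
        i = rng.integers(len(rr))
        pts = [(float(rr[i]), float(cc[i]))]
        ok = True
        for _seg in range(n_segments):
            for _try in range(20):
                theta = rng.uniform(0, 2 * np.pi)
                nr = pts[-1][0] + step * np.cos(theta)
                nc = pts[-1][1] + step * np.sin(theta)
                if not (0 <= nr <= shape[0] - 1 and 0 <= nc <= shape[1] - 1):
                    continue
                cand = pts + [(nr, nc)]
                ann = Annotation(image_id, cls, "polyline", tuple(cand))
                r_, c_ = ann.rasterize(shape)
                if region[r_, c_].all():
                    pts = cand
                    break
            else:
                ok = False
                break
        if ok and len(pts) >= 3:
            return Annotation(image_id, cls, "polyline", tuple(pts))
    return None


def _vacuole_fill(
    image_id: str, region: np.ndarray, shrink: float = 2.0
) -> Annotation | None:
    """A polygon filling a vacuole's interior, kept ``shrink`` px off the rim.

    Emulates a user flood-filling the obvious core of a cavity. Returns None
    when the component is too small for an interior polygon.
    """
    from skimage import measure

    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    centroid = np.array(ndimage.center_of_mass(region))
    idx = np.linspace(0, len(contour) - 1, min(12, len(contour)), dtype=int)
    pts = contour[idx]
    radial = pts - centroid
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    if (norms < 1e-6).any():
        return None
    pts = pts - shrink * radial / norms
    pts = np.clip(pts, 0, np.array(region.shape) - 1)
    ann = Annotation(
        image_id, 2, "polygon", tuple((float(r), float(c)) for r, c in pts)
    )
    rr, cc = ann.rasterize(region.shape)
    if len(rr) == 0 or not region[rr, cc].all():
        return None
    return ann


def _fill_stroke(image_id: str, region: np.ndarray) -> Annotation:
    """A boustrophedon stroke covering every pixel of a small convex region.

    Emulates brushing a small vacuole's interior completely: one polyline
    sweeping row by row.
    """
    rows = np.unique(np.nonzero(region)[0])
    pts: list[tuple[float, float]] = []
    flip = False
    for r in rows:
        cols = np.nonzero(region[r])[0]
        c0, c1 = int(cols.min()), int(cols.max())
        pair = (
            [(float(r), float(c1)), (float(r), float(c0))]
            if flip
            else [(float(r), float(c0)), (float(r), float(c1))]
        )
        pts.extend(pair)
        flip = not flip
    if len(pts) < 2:
        rr, cc = np.nonzero(region)
        return Annotation(image_id, 2, "point", ((float(rr[0]), float(cc[0])),))
    ann = Annotation(image_id, 2, "polyline", tuple(pts))
    rr, cc = ann.rasterize(region.shape)
    if not region[rr, cc].all():  # concave edge case: fall back to one pixel
        rr0, cc0 = np.nonzero(region)
        return Annotation(image_id, 2, "point", ((float(rr0[0]), float(cc0[0])),))
    return ann


def sample_scribbles(
    image_id: str,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_annotations: int = 6,
    scribble_length: int = 8,
) -> list[Annotation]:
    """Emulate a user's sparse labelling of one section.

    Draws up to ``n_annotations`` scribbles, at least one per class present
    in the truth. Placement mirrors how a user trains such a classifier in
    practice: one closed trace around the outside of the section outline
    (the white halo most easily confused with a vacuole) and one broad
    stroke wandering the open background; a closed tissue trace ringing a
    vacuole plus a stroke in the stained interior; and fills of individual
    vacuole interiors (a polygon kept ~2 px off the rim, or a row-by-row
    brush stroke for small cavities), choosing the component sometimes by
    area (the obvious large cavities a user labels first) and sometimes
    uniformly (so small vacuoles are represented too).
    """
    mask = truth.mask
    brain = mask >= 1
    background = (mask == 0) & ~truth.artefact_mask
    dist_out = ndimage.distance_transform_edt(~brain)
    bg_near = background & (dist_out >= 2) & (dist_out <= 12)
    bg_off = background & (dist_out >= 3)
    bg_far = background & (dist_out > 12)
    tissue_inner = ndimage.binary_erosion(mask == 1, iterations=2)
    if not tissue_inner.any():
        tissue_inner = mask == 1
    vac = mask == 2
    vac_labels, n_vac = ndimage.label(vac)

    # weighted cycle covering the informative zones
    pattern = [
        (0, "near"), (1, "ring"), (2, ""), (0, "wander"), (2, ""),
        (1, "interior"),
    ]
    plan: list[tuple[int, str]] = []
    k = 0
    while len(plan) < n_annotations:
        cls, flavour = pattern[k % len(pattern)]
        k += 1
        if cls == 0 and not background.any():
            continue
        if cls == 1 and not (mask == 1).any():
            continue
        if cls == 2 and n_vac == 0:
            continue
        plan.append((cls, flavour))

    areas = np.bincount(vac_labels.ravel())[1:].astype(float)

    def pick_component() -> np.ndarray:
        if rng.random() < 0.5:
            comp = int(rng.choice(n_vac, p=areas / areas.sum())) + 1
        else:
            comp = int(rng.integers(1, n_vac + 1))
        return vac_labels == comp

    annotations: list[Annotation] = []
    for cls, flavour in plan:
        ann: Annotation | None = None
        if cls == 0:
            if flavour == "near" and bg_near.any():
                ann = _contour_trace(
                    image_id, 0, brain, bg_near | bg_far, rng, offset=3.0
                )
                if ann is None:
                    ann = _scribble_in(image_id, 0, bg_near, rng, scribble_length)
            else:
                if bg_off.any():
                    ann = _wandering_scribble(image_id, 0, bg_off, rng)
                if ann is None:
                    region = bg_far if bg_far.any() else background
                    ann = _scribble_in(image_id, 0, region, rng, scribble_length)
        elif cls == 1:
            if flavour == "ring" and n_vac > 0:
                ann = _contour_trace(
                    image_id, 1, pick_component(), mask == 1, rng,
                    offset=3.0, n_vertices=12,
                )
            if ann is None:
                ann = _scribble_in(image_id, 1, tissue_inner, rng, scribble_length)
        else:
            region = pick_component()
            ann = _vacuole_fill(image_id, region)
            if ann is None:
                inner = ndimage.binary_erosion(region)
                if not inner.any():
                    inner = region
                ann = _fill_stroke(image_id, inner)
        annotations.append(ann)
    return annotations


def generate_cohort(
    genotype_params: Mapping[str, tuple[float, float]],
    n_flies: int,
    sections_per_fly: int,
    seed: int,
    spec_kwargs: dict | None = None,
) -> tuple[list[tuple[str, np.ndarray, GroundTruth]], pd.DataFrame]:
    """Generate a multi-genotype cohort of sections with a design table.

    ``genotype_params`` maps genotype name to ``(mean_fraction,
    concentration)`` of a Beta distribution from which each fly's mean
    vacuole fraction is drawn; the sections of one fly are drawn from a
    second, tighter Beta around the fly mean (concentration 300). The design
    emulates sampling several sections per fly from several flies per
    genotype. Returns ``(sections, design)`` where sections is a list of
    ``(image_id, image, truth)`` and design has columns image_id, genotype,
    fly_id.
    """
    if n_flies < 1 or sections_per_fly < 1:
        raise ValueError("n_flies and sections_per_fly must be >= 1")
    for g, (m, kappa) in genotype_params.items():
        if not (0.0 < m < 1.0) or kappa <= 0:
            raise ValueError(
                f"genotype {g!r}: mean must be in (0, 1) and concentration > 0"
            )
    spec_kwargs = dict(spec_kwargs or {})
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 777]))
    sections: list[tuple[str, np.ndarray, GroundTruth]] = []
    design_rows = []
    # keep targets inside the generator's feasible band: at least one
    # smallest-size vacuole must fit within the +-20% tolerance
    probe = SectionSpec(seed=0, **spec_kwargs)
    h, w = probe.canvas
    tissue_estimate = np.pi * 0.33 * h * 0.38 * w
    rmin = probe.vacuole_size_range[0]
    lo = max(0.004, 1.5 * np.pi * rmin**2 / tissue_estimate)
    hi = 0.45
    for genotype in genotype_params:
        m, kappa = genotype_params[genotype]
        for fly in range(n_flies):
            fly_mean = float(np.clip(rng.beta(m * kappa, (1 - m) * kappa), lo, hi))
            for sec in range(sections_per_fly):
                target = float(
                    np.clip(rng.beta(fly_mean * 300.0, (1 - fly_mean) * 300.0), lo, hi)
                )
                image_id = f"{genotype}_fly{fly:02d}_sec{sec:02d}"
                spec = SectionSpec(
                    target_vacuole_fraction=target,
                    seed=int(rng.integers(2**31)),
                    **spec_kwargs,
                )
                image, truth = generate_section(spec)
                sections.append((image_id, image, truth))
                design_rows.append(
                    {"image_id": image_id, "genotype": genotype, "fly_id": fly}
                )
    return sections, pd.DataFrame(design_rows)


def simulate_rater_table(
    sections: pd.DataFrame,
    n_human_raters: int = 5,
    rater_bias_sd: float = 0.0,
    noise_sd: float = 0.8,
    classifier_col: str | None = "classifier_percent",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate human raters re-scoring a set of sections.

    ``sections`` needs columns ``section_id``, ``genotype`` and
    ``true_percent``; if ``classifier_col`` names an additional column, its
    values are included as the rater ``"classifier"``. Each human rater
    scores ``true_percent`` plus a rater-specific additive bias (drawn once
    per rater from N(0, rater_bias_sd); zero bias gives a null rater effect)
    plus independent N(0, noise_sd) measurement noise, clipped to [0, 100].

    Returns a long-format rater table (section_id, genotype, rater_id,
    percent) suitable for the validation statistics.
    """
    required = {"section_id", "genotype", "true_percent"}
    missing = required - set(sections.columns)
    if missing:
        raise ValueError(f"sections table is missing columns: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 99]))
    rows = []
    truth = sections["true_percent"].to_numpy(dtype=float)
    for r in range(n_human_raters):
        bias = rng.normal(0.0, rater_bias_sd) if rater_bias_sd > 0 else 0.0
        scores = np.clip(
            truth + bias + rng.normal(0.0, noise_sd, len(truth)), 0.0, 100.0
        )
        for (_, row), score in zip(sections.iterrows(), scores):
            rows.append(
                {
                    "section_id": row["section_id"],
                    "genotype": row["genotype"],
                    "rater_id": f"volunteer{r + 1}",
                    "percent": float(score),
                }
            )
    if classifier_col is not None and classifier_col in sections.columns:
        for _, row in sections.iterrows():
            rows.append(
                {
                    "section_id": row["section_id"],
                    "genotype": row["genotype"],
                    "rater_id": "classifier",
                    "percent": float(row[classifier_col]),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(
    sections: list[tuple[str, np.ndarray, GroundTruth]],
    design: pd.DataFrame,
    output_dir: str | os.PathLike,
) -> None:
    """Write a cohort as PNG images, PNG truth masks and the design CSV."""
    import imageio.v3 as iio

    output_dir = os.fspath(output_dir)
    img_dir = os.path.join(output_dir, "images")
    truth_dir = os.path.join(output_dir, "truth")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(truth_dir, exist_ok=True)
    for image_id, image, truth in sections:
        iio.imwrite(os.path.join(img_dir, image_id + ".png"), image)
        iio.imwrite(
            os.path.join(truth_dir, image_id + "_truth.png"),
            truth.mask.astype(np.uint8),
        )
        iio.imwrite(
            os.path.join(truth_dir, image_id + "_include.png"),
            (truth.include_mask * np.uint8(255)),
        )
    design.to_csv(os.path.join(output_dir, "design.csv"), index=False)
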