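"""Per-pixel feature stacks for trainable segmentation.

Each pixel of a section image is described by a vector of filter responses:
the raw R/G/B values, luminance, and — over a geometric range of Gaussian
scales — Gaussian blur (noise removal), Sobel gradient magnitude and Hessian
eigenvalues (edges and ridges at the vacuole/tissue and tissue/background
borders), differences of Gaussians (blob contrast), and six "membrane
projection" aggregates of line-kernel convolutions at many rotations (thin
border structures). A random forest trained on sparse labels in this feature
space extends the labels to every pixel.

All filters use reflect boundary handling, so a constant image produces
constant (or zero) responses with no spurious border effects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, signal

#: Rec. 601 luma weights for the RGB -> luminance conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Perpendicular softness (in px) of the membrane line kernels. The line is
#: nominally one pixel wide; a fixed Gaussian cross-section of about one
#: pixel makes every rotation angle equally representable on the pixel grid
#: (no crisp/smeared asymmetry between grid-aligned and oblique angles) and
#: sets the angular selectivity so that 30 rotations over 180 degrees cover
#: orientation space with under 2% response ripple for thin borders.
MEMBRANE_PROFILE_SIGMA = 1.1

MEMBRANE_AGGREGATES = ("sum", "mean", "std", "median", "max", "min")


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the feature stack.

    Parameters
    ----------
    sigmas
        Strictly increasing Gaussian scales in pixels. The default
        ``(1, 2, 4, 8, 16, 32)`` spans vacuoles from a few pixels across up
        to large cavities; the top scale deliberately exceeds the largest
        expected vacuole radius so that an enclosed white cavity and the
        open white background beside the tissue edge remain distinguishable
        at some scale.
    membrane_kernel_size
        Odd side length in pixels of the membrane line kernels.
    membrane_rotations
        Number of evenly spaced kernel rotations over [0°, 180°).
    include_raw_channels
        Whether the raw R, G, B values are included as identity features
        (they retain hue information the scalar filters discard).
    """

    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    membrane_kernel_size: int = 19
    membrane_rotations: int = 30
    include_raw_channels: bool = True

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigmas)
        object.__setattr__(self, "sigmas", sig)
        if len(sig) < 1 or any(s <= 0 for s in sig):
            raise ValueError("sigmas must be positive")
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigmas must be strictly increasing")
        k = self.membrane_kernel_size
        if k < 3 or k % 2 == 0:
            raise ValueError("membrane_kernel_size must be an odd integer >= 3")
        if self.membrane_rotations < 2:
            raise ValueError("membrane_rotations must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        d["sigmas"] = tuple(d["sigmas"])
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "FeatureConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def feature_names(self) -> list[str]:
        """Ordered names of the stack's planes, fully determined by the config."""
        names: list[str] = []
        if self.include_raw_channels:
            names += ["raw_red", "raw_green", "raw_blue"]
        names.append("luminance")
        for s in self.sigmas:
            names += [
                f"gaussian_s{s:g}",
                f"sobel_s{s:g}",
                f"hessian_large_s{s:g}",
                f"hessian_small_s{s:g}",
            ]
        for i, s1 in enumerate(self.sigmas):
            for s2 in self.sigmas[i + 1 :]:
                names.append(f"dog_s{s1:g}_s{s2:g}")
        k, r = self.membrane_kernel_size, self.membrane_rotations
        names += [f"membrane_{agg}_k{k}_r{r}" for agg in MEMBRANE_AGGREGATES]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())


class FeatureStack(NamedTuple):
    """``(H, W, F)`` feature values plus the ordered names of the F planes."""

    values: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an ``(H, W, 3)`` uint8 image, scaled to [0, 1]."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {img.shape}")
    w = np.array(LUMA_WEIGHTS)
    return (img @ w) / 255.0


def gaussian_blur(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian convolution with reflect boundaries; sigma 0 is identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    channel = np.asarray(channel, dtype=np.float64)
    if sigma == 0:
        return channel.copy()
    return ndimage.gaussian_filter(channel, sigma, mode="reflect")


def sobel_magnitude(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient magnitude of the Sobel operator after Gaussian pre-smoothing."""
    smoothed = gaussian_blur(channel, sigma)
    gx = ndimage.sobel(smoothed, axis=1, mode="reflect")
    gy = ndimage.sobel(smoothed, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def hessian_features(channel: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the Gaussian-scale Hessian, ordered (larger, smaller).

    The Hessian is the 2x2 matrix of second derivatives of the channel
    smoothed at scale ``sigma``; its eigenvalues characterise local curvature
    (both strongly negative at the centre of a bright blob, one strongly
    negative along a bright ridge).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0 for Hessian features, got {sigma}")
    channel = np.asarray(channel, dtype=np.float64)
    hrr = ndimage.gaussian_filter(channel, sigma, order=(2, 0), mode="reflect")
    hcc = ndimage.gaussian_filter(channel, sigma, order=(0, 2), mode="reflect")
    hrc = ndimage.gaussian_filter(channel, sigma, order=(1, 1), mode="reflect")
    half_trace = 0.5 * (hrr + hcc)
    root = np.sqrt((0.5 * (hrr - hcc)) ** 2 + hrc**2)
    return half_trace + root, half_trace - root


def difference_of_gaussians(
    channel: np.ndarray, sigma_small: float, sigma_large: float
) -> np.ndarray:
    """``blur(x, sigma_small) - blur(x, sigma_large)``; a band-pass blob detector."""
    if sigma_small >= sigma_large:
        raise ValueError(
            f"require sigma_small < sigma_large, got {sigma_small} >= {sigma_large}"
        )
    if sigma_small < 0:
        raise ValueError(f"sigma_small must be >= 0, got {sigma_small}")
    return gaussian_blur(channel, sigma_small) - gaussian_blur(channel, sigma_large)


def membrane_kernels(kernel_size: int, n_rotations: int) -> np.ndarray:
    """Line kernels at ``n_rotations`` evenly spaced angles over [0°, 180°).

    Each kernel is a centred line segment of nominal width one pixel spanning
    the kernel, drawn analytically at its exact angle: a Gaussian perpendicular
    cross-section (sigma ``MEMBRANE_PROFILE_SIGMA``) with a trapezoidal
    fall-off at the segment ends, normalised so every kernel has total mass
    equal to ``kernel_size``. Drawing each angle analytically (rather than
    resampling a grid-aligned line) keeps the response to a thin border
    independent of its orientation. Angle 0 is a vertical line; kernels at
    angles 90° apart are exact transposes.

    Returns an ``(n_rotations, kernel_size, kernel_size)`` array.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd integer >= 3")
    if n_rotations < 2:
        raise ValueError("n_rotations must be >= 2")
    radius = (kernel_size - 1) // 2
    rows, cols = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    kernels = np.empty((n_rotations, kernel_size, kernel_size))
    for r in range(n_rotations):
        theta = np.pi * r / n_rotations
        along = rows * np.cos(theta) + cols * np.sin(theta)
        perp = -rows * np.sin(theta) + cols * np.cos(theta)
        profile = np.exp(-0.5 * (perp / MEMBRANE_PROFILE_SIGMA) ** 2)
        caps = np.clip(radius + 0.5 - np.abs(along), 0.0, 1.0)
        k = profile * caps
        kernels[r] = k * (kernel_size / k.sum())
    return kernels


def _convolve_reflect(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    radius = kernel.shape[0] // 2
    # same edge handling as scipy.ndimage's "reflect" (edge sample repeated)
    padded = np.pad(channel, radius, mode="symmetric")
    return signal.fftconvolve(padded, kernel, mode="valid")


def membrane_projections(
    channel: np.ndarray, kernel_size: int = 19, n_rotations: int = 30
) -> np.ndarray:
    """Six pixel-wise aggregates of rotated line-kernel convolutions.

    The channel is convolved with each rotated line kernel and the
    ``n_rotations`` response planes are reduced pixel-wise to sum, mean,
    standard deviation, median, maximum and minimum, in that order. The max
    projection lights up thin bright lines regardless of orientation; the std
    projection distinguishes oriented structure from isotropic texture.

    Returns an ``(H, W, 6)`` array ordered as ``MEMBRANE_AGGREGATES``.
    """
    channel = np.asarray(channel, dtype=np.float64)
    kernels = membrane_kernels(kernel_size, n_rotations)
    responses = np.stack([_convolve_reflect(channel, k) for k in kernels])
    return np.stack(
        [
            responses.sum(axis=0),
            responses.mean(axis=0),
            responses.std(axis=0),
            np.median(responses, axis=0),
            responses.max(axis=0),
            responses.min(axis=0),
        ],
        axis=-1,
    )


def build_feature_stack(
    image: np.ndarray, config: FeatureConfig | None = None
) -> FeatureStack:
    """Assemble the full per-pixel feature stack of an RGB section image.

    Plane order (fixed, mirrored by ``config.feature_names()``): raw R, G, B
    (if configured); luminance; per sigma the Gaussian blur, Sobel magnitude
    and both Hessian eigenplanes; all ordered-pair differences of Gaussians;
    the six membrane projections. All filters operate on the luminance
    channel. The result is deterministic: same pixels and config give a
    bit-identical stack.
    """
    if config is None:
        config = FeatureConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {image.shape}")
    lum = to_luminance(image)
    planes: list[np.ndarray] = []
    if config.include_raw_channels:
        rgb = image.astype(np.float64) / 255.0
        planes += [rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2]]
    planes.append(lum)

    blurred = {s: gaussian_blur(lum, s) for s in config.sigmas}
    for s in config.sigmas:
        hl, hs = hessian_features(lum, s)
        planes += [blurred[s], sobel_magnitude(lum, s), hl, hs]
    for i, s1 in enumerate(config.sigmas):
        for s2 in config.sigmas[i + 1 :]:
            planes.append(blurred[s1] - blurred[s2])
    proj = membrane_projections(
        lum, config.membrane_kernel_size, config.membrane_rotations
    )
    planes += [proj[:, :, i] for i in range(proj.shape[2])]

    values = np.stack(planes, axis=-1)
    names = tuple(config.feature_names())
    assert values.shape[2] == len(names)
    return FeatureStack(values=values, feature_names=names)
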