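"""Training-time geometric augmentation.

Four sequential layers: random perspective, random rotation, random
width-only (transversal) scaling, and a centered crop.  The width-only
scaling emulates the magnification change caused by table-height
variation between exams: the image width is rescaled while the height
magnification stays fixed.  Flips are deliberately never applied — a
mirrored trunk is a clinically meaningful (and wrong) image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, SimilarityTransform, resize, warp

from .io_preproc import crop_pad_array

__all__ = [
    "AugmentConfig",
    "random_transversal_scaling",
    "transversal_scale",
    "augment_pipeline",
]


@dataclass
class AugmentConfig:
    """Augmentation parameters.

    ``transversal_factor`` f bounds the width scale; with probability
    ``transversal_prob`` a scale is drawn from Uniform[1/f, f]
    (``transversal_sampling="reciprocal"``) or Uniform[2-f, f]
    (``"linear"``).  The reciprocal range is the default: table
    positions above and below the isocenter magnify and minify
    symmetrically in the multiplicative sense.
    """

    perspective_distortion: float = 0.1
    perspective_prob: float = 0.5
    rotation_degrees: float = 3.0
    rotation_prob: float = 0.5
    transversal_factor: float = 1.04
    transversal_prob: float = 0.25
    transversal_sampling: str = "reciprocal"
    crop_rows: int = 384
    crop_cols: int = 256

    def __post_init__(self):
        if self.transversal_factor < 1.0:
            raise ValueError(f"transversal_factor must be >= 1, got {self.transversal_factor}")
        if not 0.0 <= self.transversal_prob <= 1.0:
            raise ValueError(f"transversal_prob must be in [0, 1], got {self.transversal_prob}")
        if self.transversal_sampling not in ("reciprocal", "linear"):
            raise ValueError(f"unknown transversal_sampling {self.transversal_sampling!r}")


def transversal_scale(img: np.ndarray, s: float) -> np.ndarray:
    """Deterministically rescale width by ``s`` (bicubic), height fixed.

    The result is center-cropped / zero-padded back to the original
    width, so the output shape equals the input shape.
    """
    h, w = img.shape
    new_w = int(round(w * s))
    if new_w == w:
        return img.astype(np.float64, copy=True)
    out = resize(
        img.astype(np.float64),
        (h, new_w),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return crop_pad_array(out, h, w)


def _draw_scale(f: float, sampling: str, rng: np.random.Generator) -> float:
    if sampling == "reciprocal":
        return float(rng.uniform(1.0 / f, f))
    return float(rng.uniform(2.0 - f, f))


def random_transversal_scaling(
    img: np.ndarray,
    f: float = 1.04,
    p: float = 0.25,
    rng: np.random.Generator | None = None,
    sampling: str = "reciprocal",
) -> np.ndarray:
    """With probability ``p`` rescale width by s ~ Uniform over the factor range.

    With probability 1 - p (or when f == 1) the image passes through
    unchanged.
    """
    if f < 1.0:
        raise ValueError(f"transversal factor must be >= 1, got {f}")
    rng = rng or np.random.default_rng()
    if rng.random() >= p or f == 1.0:
        return img.astype(np.float64, copy=True)
    return transversal_scale(img, _draw_scale(f, sampling, rng))


def _perspective_transform(
    shape: tuple[int, int], distortion: float, rng: np.random.Generator
) -> ProjectiveTransform:
    """Projective map jittering the four corners inward by up to ``distortion``."""
    h, w = shape
    dr, dc = distortion * h / 2.0, distortion * w / 2.0
    src = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    jit = rng.uniform(0.0, 1.0, size=(4, 2)) * np.array([dc, dr])
    sign = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
    tf = ProjectiveTransform()
    tf.estimate(src, src + jit * sign)  # forward: corners move inward
    return tf


def _rotation_transform(shape: tuple[int, int], angle_deg: float) -> SimilarityTransform:
    """Rotation about the image center."""
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    a = np.deg2rad(angle_deg)
    shift = SimilarityTransform(translation=-center)
    rot = SimilarityTransform(rotation=a)
    back = SimilarityTransform(translation=center)
    return shift + rot + back


def augment_pipeline(
    img: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Perspective -> rotation -> transversal scaling -> center crop.

    The perspective and rotation layers are composed into a single warp
    (one resampling instead of two); bilinear interpolation is used for
    these small, unspecified distortions while the transversal scaling
    keeps bicubic.  Fully reproducible from the supplied generator;
    output shape is always ``(crop_rows, crop_cols)``.
    """
    out = img.astype(np.float32)
    tf = None
    if rng.random() < config.perspective_prob and config.perspective_distortion > 0:
        tf = _perspective_transform(out.shape, config.perspective_distortion, rng)
    if rng.random() < config.rotation_prob and config.rotation_degrees > 0:
        angle = float(rng.uniform(-config.rotation_degrees, config.rotation_degrees))
        rot = _rotation_transform(out.shape, angle)
        tf = rot if tf is None else tf + rot
    if tf is not None:
        out = warp(out, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True)
    out = random_transversal_scaling(
        out,
        config.transversal_factor,
        config.transversal_prob,
        rng,
        config.transversal_sampling,
    )
    return crop_pad_array(out, config.crop_rows, config.crop_cols)
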