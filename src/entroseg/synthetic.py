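"""Synthetic phantoms with known ground truth.

A phantom is assembled following the image model ``I = b·J + n``: a
piecewise-constant true image ``J`` with exactly two intensity values, a
smooth multiplicative bias field ``b`` of mean one, and additive zero-mean
Gaussian noise ``n`` whose level is expressed on the unit-normalized
intensity scale (the scale is 255 by default).  By default a level is the
noise standard deviation on that scale (level 0.05 → std 12.75 grey
levels); the variance convention of MATLAB-style noise utilities, under
which per-mille levels like 0.001–0.006 are natural, is available via
``semantics="variance"``.  Every generator is deterministic under its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

__all__ = ["Phantom", "make_shape", "make_bias", "add_noise", "compose", "make_phantom"]

#: default intensity scale of the 8-bit convention used across the package
INTENSITY_SCALE = 255.0


@dataclass
class Phantom:
    true_image: np.ndarray
    mask: np.ndarray | None
    bias: np.ndarray
    noise_level: float
    observed: np.ndarray
    seed: int | None


def _canvas(size) -> tuple[int, int]:
    if np.isscalar(size):
        return int(size), int(size)
    h, w = size
    return int(h), int(w)


def make_shape(
    shape_kind: str,
    size,
    fg_value: float = 120.0,
    bg_value: float = 40.0,
    **geometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-valued true image and its foreground mask.

    Kinds: ``disk`` (radius default 0.3·min side), ``star`` (n_points
    default 5, inner/outer radius ratio 0.5), ``two_objects`` (a disk and a
    square), ``cross`` (plus sign).  Geometry keywords: ``radius``,
    ``center``, ``n_points``, ``ratio``, ``arm_width``.
    """
    if fg_value == bg_value:
        raise ValueError("fg_value and bg_value must differ")
    h, w = _canvas(size)
    m = min(h, w)
    cy, cx = geometry.get("center", (h // 2, w // 2))
    mask = np.zeros((h, w), dtype=bool)

    if shape_kind == "disk":
        r = geometry.get("radius", round(0.3 * m))
        if r <= 0 or cy - r < 0 or cy + r >= h or cx - r < 0 or cx + r >= w:
            raise ValueError("disk does not fit in the canvas")
        rr, cc = draw.disk((cy, cx), r + 0.5, shape=(h, w))
        mask[rr, cc] = True
    elif shape_kind == "star":
        n_points = geometry.get("n_points", 5)
        r_out = geometry.get("radius", 0.4 * m)
        ratio = geometry.get("ratio", 0.5)
        if r_out <= 0 or cy - r_out < 0 or cy + r_out >= h or cx - r_out < 0 or cx + r_out >= w:
            raise ValueError("star does not fit in the canvas")
        ang = -np.pi / 2 + np.arange(2 * n_points) * np.pi / n_points
        rad = np.where(np.arange(2 * n_points) % 2 == 0, r_out, ratio * r_out)
        rr, cc = draw.polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), shape=(h, w))
        mask[rr, cc] = True
    elif shape_kind == "two_objects":
        r = geometry.get("radius", round(0.18 * m))
        if r <= 0 or 4 * r >= m:
            raise ValueError("objects do not fit in the canvas")
        rr, cc = draw.disk((cy, cx - round(0.22 * w)), r + 0.5, shape=(h, w))
        mask[rr, cc] = True
        s = round(0.8 * r)
        r0, c0 = cy - s, cx + round(0.22 * w) - s
        if r0 < 0 or cy + s >= h or c0 < 0 or cx + round(0.22 * w) + s >= w:
            raise ValueError("objects do not fit in the canvas")
        mask[r0 : cy + s + 1, c0 : cx + round(0.22 * w) + s + 1] = True
    elif shape_kind == "cross":
        arm = geometry.get("radius", round(0.35 * m))
        width = geometry.get("arm_width", max(round(0.1 * m), 2))
        if arm <= 0 or cy - arm < 0 or cy + arm >= h or cx - arm < 0 or cx + arm >= w:
            raise ValueError("cross does not fit in the canvas")
        half = width // 2
        mask[cy - arm : cy + arm + 1, cx - half : cx + half + 1] = True
        mask[cy - half : cy + half + 1, cx - arm : cx + arm + 1] = True
    else:
        raise ValueError(f"unknown shape kind {shape_kind!r}")

    img = np.where(mask, float(fg_value), float(bg_value))
    return img, mask


def make_bias(size, kind: str = "gaussian_bump", amplitude: float = 0.3) -> np.ndarray:
    """Smooth positive field in ``[1−a, 1+a]`` with mean exactly one.

    Kinds: ``linear_ramp`` (left-to-right), ``gaussian_bump`` (centred),
    ``sinusoid`` (one period along each axis).
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    h, w = _canvas(size)
    if amplitude == 0:
        return np.ones((h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if kind == "linear_ramp":
        g = xx
    elif kind == "gaussian_bump":
        s = 0.35 * min(h, w)
        g = np.exp(-(((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)) / (2 * s * s))
    elif kind == "sinusoid":
        g = np.sin(2 * np.pi * yy / max(h - 1, 1)) + np.sin(2 * np.pi * xx / max(w - 1, 1))
    else:
        raise ValueError(f"unknown bias kind {kind!r}")
    g = g - g.mean()
    return 1.0 + amplitude * g / np.max(np.abs(g))


def add_noise(
    image: np.ndarray,
    noise_level: float,
    seed: int | None = None,
    scale: float = INTENSITY_SCALE,
    semantics: str = "std",
) -> np.ndarray:
    """Additive zero-mean Gaussian noise at the given level.

    With ``semantics="std"`` (default) the level is the noise standard
    deviation on the image normalized by ``scale``;
    ``semantics="variance"`` reads it as the variance on that unit scale
    (the MATLAB ``imnoise`` convention) instead.
    """
    image = np.asarray(image, dtype=float)
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if semantics == "variance":
        std = np.sqrt(noise_level) * scale
    elif semantics == "std":
        std = noise_level * scale
    else:
        raise ValueError(f"semantics must be 'variance' or 'std', got {semantics!r}")
    if std == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, std, size=image.shape)


def compose(
    true_image: np.ndarray,
    bias: np.ndarray,
    noise_level: float,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    scale: float = INTENSITY_SCALE,
    semantics: str = "std",
) -> Phantom:
    """Assemble the observed image ``I = b·J + n``."""
    true_image = np.asarray(true_image, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if true_image.shape != bias.shape:
        raise ValueError("true_image and bias shapes differ")
    if mask is not None and mask.shape != true_image.shape:
        raise ValueError("mask shape differs from true_image")
    observed = add_noise(bias * true_image, noise_level, seed=seed, scale=scale, semantics=semantics)
    return Phantom(
        true_image=true_image,
        mask=mask,
        bias=bias,
        noise_level=float(noise_level),
        observed=observed,
        seed=seed,
    )


def make_phantom(
    shape_kind: str = "disk",
    size=64,
    fg_value: float = 120.0,
    bg_value: float = 40.0,
    bias_kind: str = "gaussian_bump",
    bias_amplitude: float = 0.3,
    noise_level: float = 0.05,
    seed: int | None = 0,
    semantics: str = "std",
    **geometry,
) -> Phantom:
    """One-call phantom: shape, bias field and noise composed with a mask."""
    img, mask = make_shape(shape_kind, size, fg_value, bg_value, **geometry)
    bias = make_bias(size, bias_kind, bias_amplitude)
    return compose(img, bias, noise_level, seed=seed, mask=mask, semantics=semantics)
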