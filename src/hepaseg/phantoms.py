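"""Synthetic liver phantoms with ground-truth tumor masks.

Real abdominal CT/MRI slices of liver-tumor patients are not shippable, so
every test and example in this package runs on phantoms: a bright elliptical
"liver" on a darker background with a small interior "tumor" blob as the
segmentation target, plus smooth intra-organ texture.  Degradations mimic
acquisition artifacts: impulse (salt-and-pepper) pixels and additive
Gaussian noise.

Images are 8-bit grayscale (``uint8``, 0-255); masks are ``uint8`` {0, 1}.
All randomness flows through a dedicated :func:`numpy.random.default_rng`
stream per call — module import and repeated calls never touch global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError

__all__ = ["PhantomSpec", "NoiseSpec", "generate_phantom", "add_noise"]

#: minimum contrast (gray levels) between any two tissue classes
_MIN_CONTRAST = 20


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic axial liver slice.

    Parameters
    ----------
    size : int
        Pixels per side of the square image (default 256).
    liver_axes : tuple of float, optional
        Semi-axes of the liver ellipse in pixels. ``None`` scales with
        ``size`` (0.35 / 0.27 of the side).
    liver_intensity, tumor_intensity, background_intensity : int
        Mean gray level of each tissue class; must differ pairwise by at
        least 20 gray levels so the segmentation task is learnable.
    tumor_radius_range : tuple of float, optional
        (min, max) tumor radius in pixels; ``None`` scales with ``size``.
    texture_sigma : float
        Standard deviation (gray levels) of the smooth intra-organ
        intensity variation.
    rotation_deg : float
        In-plane rotation of the liver ellipse.
    """

    size: int = 256
    liver_axes: tuple[float, float] | None = None
    liver_intensity: int = 160
    tumor_radius_range: tuple[float, float] | None = None
    tumor_intensity: int = 210
    background_intensity: int = 40
    texture_sigma: float = 6.0
    rotation_deg: float = 0.0

    def resolved_axes(self) -> tuple[float, float]:
        if self.liver_axes is not None:
            return self.liver_axes
        return (0.35 * self.size, 0.27 * self.size)

    def resolved_radius_range(self) -> tuple[float, float]:
        if self.tumor_radius_range is not None:
            return self.tumor_radius_range
        return (max(2.0, self.size / 32), max(3.0, self.size / 12))

    def validate(self) -> None:
        if self.size < 16:
            raise ConfigurationError(f"size must be >= 16, got {self.size}")
        levels = {
            "background_intensity": self.background_intensity,
            "liver_intensity": self.liver_intensity,
            "tumor_intensity": self.tumor_intensity,
        }
        for name, v in levels.items():
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{name}={v} outside [0, 255]")
        names = list(levels)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if abs(levels[a] - levels[b]) < _MIN_CONTRAST:
                    raise ConfigurationError(
                        f"{a} and {b} differ by less than {_MIN_CONTRAST} gray levels"
                    )
        a, b = self.resolved_axes()
        if a <= 0 or b <= 0 or 2 * a >= self.size or 2 * b >= self.size:
            raise ConfigurationError(f"liver_axes {(a, b)} do not fit in a {self.size}px frame")
        rmin, rmax = self.resolved_radius_range()
        if not 0 < rmin <= rmax:
            raise ConfigurationError(f"tumor_radius_range {(rmin, rmax)} invalid")
        if rmax >= min(a, b):
            raise ConfigurationError(
                f"tumor radius up to {rmax} cannot fit inside liver semi-axes {(a, b)}"
            )
        if self.texture_sigma < 0:
            raise ConfigurationError("texture_sigma must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Degradation model applied on top of a clean phantom.

    ``mode`` selects impulse (salt-and-pepper), additive Gaussian, or both.
    ``impulse_density`` is the fraction of pixels forced to an extreme;
    ``salt_vs_pepper`` the fraction of those set to 255 rather than 0.
    """

    mode: str = "impulse"
    impulse_density: float = 0.02
    salt_vs_pepper: float = 0.5
    gaussian_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("impulse", "gaussian", "both"):
            raise ConfigurationError(f"unknown noise mode {self.mode!r}")
        if not 0.0 <= self.impulse_density <= 0.5:
            raise ConfigurationError(
                f"impulse_density={self.impulse_density} outside [0, 0.5]"
            )
        if not 0.0 <= self.salt_vs_pepper <= 1.0:
            raise ConfigurationError(f"salt_vs_pepper={self.salt_vs_pepper} outside [0, 1]")
        if self.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be non-negative")


def _ellipse_mask(size: int, center: tuple[float, float], axes: tuple[float, float],
                  rotation_deg: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = center
    t = np.deg2rad(rotation_deg)
    u = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
    v = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom slice and its ground-truth tumor mask.

    Returns
    -------
    image : uint8 array, shape (size, size)
    mask : uint8 array, shape (size, size)
        1 exactly at tumor pixels; the tumor always lies strictly inside
        the liver ellipse.

    The same ``(spec, seed)`` pair yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    s = spec.size
    center = (s / 2.0, s / 2.0)
    axes = spec.resolved_axes()

    liver = _ellipse_mask(s, center, axes, spec.rotation_deg)

    rmin, rmax = spec.resolved_radius_range()
    radius = float(rng.uniform(rmin, rmax))
    # sample the tumor center inside a shrunken ellipse so the full disk
    # (radius + 1px guard) stays within the liver
    inner = (axes[0] - radius - 1.0, axes[1] - radius - 1.0)
    t = np.deg2rad(spec.rotation_deg)
    for _ in range(1000):
        r = np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        u, v = inner[0] * r * np.cos(phi), inner[1] * r * np.sin(phi)
        cx = center[1] + u * np.cos(t) - v * np.sin(t)
        cy = center[0] + u * np.sin(t) + v * np.cos(t)
        if 0 <= cx < s and 0 <= cy < s:
            break
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    tumor = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2

    img = np.full((s, s), float(spec.background_intensity))
    img[liver] = spec.liver_intensity
    img[tumor] = spec.tumor_intensity

    if spec.texture_sigma > 0:
        # band-limited field: smoothed white noise renormalized to the
        # requested gray-level std, applied inside the organ only
        field = rng.standard_normal((s, s))
        field = ndimage.gaussian_filter(field, sigma=max(1.0, s / 32))
        field *= spec.texture_sigma / field.std()
        img[liver] += field[liver]

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, tumor.astype(np.uint8)


def add_noise(img: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply the degradation model; the input array is never modified.

    Impulse mode sets exactly ``round(density * n_pixels)`` distinct pixels
    to 0 or 255 (``salt_vs_pepper`` of them to 255). Reproducible under a
    fixed ``noise.seed``.
    """
    noise.validate()
    if img.ndim != 2 or img.size == 0:
        raise InputError(f"expected a non-empty 2-D grayscale image, got shape {img.shape}")
    rng = np.random.default_rng(noise.seed)
    out = img.astype(np.float64, copy=True)

    if noise.mode in ("gaussian", "both") and noise.gaussian_sigma > 0:
        out += rng.normal(0.0, noise.gaussian_sigma, size=out.shape)

    if noise.mode in ("impulse", "both") and noise.impulse_density > 0:
        n = int(round(noise.impulse_density * img.size))
        flat = rng.choice(img.size, size=n, replace=False)
        n_salt = int(round(noise.salt_vs_pepper * n))
        out.ravel()[flat[:n_salt]] = 255.0
        out.ravel()[flat[n_salt:]] = 0.0

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
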