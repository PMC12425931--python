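"""Synthetic spine-radiograph phantoms with exact ground-truth masks.

Real spinal radiographs show a single elongated, gently curved column of
bright vertebral bodies over a noisy, low-contrast soft-tissue background.
The generator emulates exactly those essentials: stacked rounded-rectangle
"vertebral bodies" whose centreline follows a lateral sinusoid, brightened
against a smooth background gradient, Gaussian-blurred (focal spot /
soft-tissue scatter) and corrupted with additive Gaussian noise.  The binary
mask is the exact union of the rounded rectangles, rasterised before blur
and noise, so every pixel label is known by construction.

Everything is driven by a single integer seed: identical parameters and
seed give bit-identical image/mask pairs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data import split_dataset, write_manifest
from .errors import ConfigurationError, InvalidInputError


@dataclasses.dataclass
class PhantomParams:
    """Geometry and imaging parameters of one synthetic radiograph.

    Lengths are in pixels; intensities on [0, 1].  ``contrast`` is the
    foreground-background intensity gap; ``curvature_amplitude`` the lateral
    sinusoidal offset of the vertebral column's centreline.
    """

    image_size: int = 256
    n_vertebrae: int = 12
    body_width: int = 48
    body_height: int = 14
    gap: int = 4
    curvature_amplitude: float = 20.0
    contrast: float = 0.5
    noise_sigma: float = 0.08
    blur_sigma: float = 1.2
    seed: int = 0

    # margin kept clear of the image border, scaled with the image
    @property
    def margin(self) -> int:
        return max(4, self.image_size // 16)

    def validate(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("image_size must be at least 32")
        if self.n_vertebrae < 1 or self.body_width < 2 or self.body_height < 2 or self.gap < 1:
            raise ConfigurationError("degenerate vertebra geometry")
        if not (0.0 < self.contrast <= 1.0):
            raise ConfigurationError("contrast must lie in (0, 1]")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ConfigurationError("noise_sigma and blur_sigma must be non-negative")
        column_h = self.n_vertebrae * (self.body_height + self.gap) - self.gap
        if column_h > self.image_size - 2 * self.margin:
            raise ConfigurationError(
                f"{self.n_vertebrae} vertebrae of height {self.body_height} (gap {self.gap}) "
                f"do not fit a {self.image_size}-pixel image"
            )
        half_span = self.curvature_amplitude + self.body_width / 2
        if half_span > self.image_size / 2 - self.margin:
            raise ConfigurationError("curved column would leave the image laterally")

    def scaled(self, image_size: int) -> "PhantomParams":
        """Same anatomy proportions at a different raster size."""
        f = image_size / self.image_size
        # floor the body height so the stacked column still fits after rounding
        return dataclasses.replace(
            self,
            image_size=image_size,
            body_width=max(2, round(self.body_width * f)),
            body_height=max(2, int(self.body_height * f)),
            gap=max(1, int(self.gap * f)),
            curvature_amplitude=self.curvature_amplitude * f,
            blur_sigma=self.blur_sigma * f,
        )


def _rounded_rect_mask(yy, xx, cy, cx, hh, hw, radius):
    """Boolean membership of a rounded rectangle centred at (cy, cx)."""
    dy = np.abs(yy - cy) - (hh - radius)
    dx = np.abs(xx - cx) - (hw - radius)
    dy_c = np.maximum(dy, 0.0)
    dx_c = np.maximum(dx, 0.0)
    outside = np.sqrt(dy_c**2 + dx_c**2) - radius
    return outside <= 0.0


def generate_phantom(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom.

    Returns ``(image, mask)``: the image as float in [0, 1], the mask as
    uint8 in {0, 1}.  In the noiseless, blur-free, full-contrast limit the
    image thresholded at 0.5 reproduces the mask exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    s = params.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # smooth background kept strictly below 0.5 so foreground is separable
    base = rng.uniform(0.12, 0.22)
    tilt = rng.uniform(-0.1, 0.1)
    bg = base + 0.12 * (yy / s) + tilt * (xx / s - 0.5)
    bg = np.clip(bg, 0.05, 0.45)

    pitch = params.body_height + params.gap
    column_h = params.n_vertebrae * pitch - params.gap
    top = (s - column_h) / 2
    phase = rng.uniform(0, 2 * np.pi)
    amp = params.curvature_amplitude * rng.uniform(0.7, 1.0)

    mask = np.zeros((s, s), dtype=bool)
    radius = min(3.0, params.body_height / 3, params.body_width / 3)
    for i in range(params.n_vertebrae):
        cy = top + i * pitch + params.body_height / 2
        cx = s / 2 + amp * np.sin(2 * np.pi * cy / s + phase)
        hw = params.body_width / 2 * rng.uniform(0.9, 1.1)
        hh = params.body_height / 2
        mask |= _rounded_rect_mask(yy, xx, cy, cx, hh, hw, radius)

    img = bg + params.contrast * mask
    if params.blur_sigma > 0:
        img = gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32), mask.astype(np.uint8)


def save_pair(img: np.ndarray, mask: np.ndarray, image_path, mask_path) -> None:
    """Write an image/mask pair as 8-bit grayscale PNGs (mask as {0, 255})."""
    Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(image_path)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(mask_path)


def generate_dataset(n: int, params: PhantomParams, out_dir, seed: int = 0,
                     ratios: tuple[int, int, int] = (7, 1, 2)) -> Path:
    """Write ``n`` phantom pairs plus a train/val/test manifest.

    Per-item seeds are ``seed + index`` so any item can be regenerated in
    isolation; the split manifest derives from the same master seed.
    """
    if n < 10:
        raise InvalidInputError(f"need at least 10 items to split, got {n}")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out_dir}: {e}") from e
    names = []
    for i in range(n):
        p = dataclasses.replace(params, seed=seed + i)
        img, mask = generate_phantom(p)
        name = f"phantom_{i:04d}.png"
        save_pair(img, mask, img_dir / name, msk_dir / name)
        names.append(name)
    manifest = split_dataset(names, ratios=ratios, seed=seed)
    write_manifest(manifest, out_dir / "manifest.csv")
    return out_dir
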