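"""Photographic augmentation: expand a small image set into a training set.

The recipe applies, in order, random cropping, rotation, mirror flips,
perspective warp and per-channel RGB gain (emulating different lighting),
then resizes to the training resolution.  Every draw is determined by
(config, draw_seed), so a dataset build is exactly reproducible.  Pillow
performs the geometric transforms (bilinear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["AugmentConfig", "augment_one", "augment_iter", "build_dataset"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameters; defaults target the 375 -> 25,000 regime."""

    target_count: int = 25000
    output_size: int = 256
    crop_scale_range: tuple[float, float] = (0.7, 1.0)
    rotation_range_deg: tuple[float, float] = (-180.0, 180.0)
    allow_horizontal_flip: bool = True
    allow_vertical_flip: bool = True
    perspective_jitter: float = 0.1
    rgb_gain_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def gain_ranges(self) -> tuple[tuple[float, float], ...]:
        """Per-channel (lo, hi) gain bounds; a single pair applies to all three."""
        rg = self.rgb_gain_range
        if isinstance(rg[0], (tuple, list)):
            return tuple((float(lo), float(hi)) for lo, hi in rg)
        return ((float(rg[0]), float(rg[1])),) * 3

    def validate(self, n_sources: int | None = None) -> None:
        for name in ("crop_scale_range", "rotation_range_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"AugmentConfig.{name}={lo, hi} not ordered")
        for lo, hi in self.gain_ranges():
            if lo > hi:
                raise ValueError(f"rgb_gain_range={self.rgb_gain_range} not ordered")
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"crop_scale_range={lo, hi} outside (0, 1]")
        if self.perspective_jitter < 0:
            raise ValueError("perspective_jitter must be >= 0")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if n_sources is not None and self.target_count < n_sources:
            raise ValueError(
                f"target_count={self.target_count} < number of sources {n_sources}"
            )

    def identity(self) -> "AugmentConfig":
        """A collapsed config under which augmentation reduces to a resize."""
        return AugmentConfig(
            target_count=self.target_count,
            output_size=self.output_size,
            crop_scale_range=(1.0, 1.0),
            rotation_range_deg=(0.0, 0.0),
            allow_horizontal_flip=False,
            allow_vertical_flip=False,
            perspective_jitter=0.0,
            rgb_gain_range=(1.0, 1.0),
            seed=self.seed,
        )


def _perspective_coeffs(src_quad, dst_quad):
    # solve the 8-dof projective map sending dst corners onto src corners
    a = []
    b = []
    for (x, y), (u, v) in zip(dst_quad, src_quad):
        a.append([x, y, 1, 0, 0, 0, -u * x, -u * y])
        a.append([0, 0, 0, x, y, 1, -v * x, -v * y])
        b.extend([u, v])
    return np.linalg.solve(np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64))


def augment_one(image: np.ndarray, config: AugmentConfig, draw_seed: int) -> np.ndarray:
    """One augmentation draw: crop, rotate, flip, warp, RGB gain, resize."""
    config.validate()
    if image.size == 0:
        raise ValueError("empty image")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(draw_seed)]))
    h, w = image.shape[:2]

    # random crop (square window, scale relative to the short side)
    scale = rng.uniform(*config.crop_scale_range)
    side = max(1, int(round(scale * min(h, w))))
    if side > min(h, w):
        raise ValueError(f"crop window {side} larger than image {min(h, w)}")
    r0 = int(rng.integers(0, h - side + 1))
    c0 = int(rng.integers(0, w - side + 1))
    im = Image.fromarray(image[r0 : r0 + side, c0 : c0 + side])

    angle = float(rng.uniform(*config.rotation_range_deg))
    if angle != 0.0:
        im = im.rotate(angle, resample=Image.BILINEAR, expand=False)

    if config.allow_horizontal_flip and rng.random() < 0.5:
        im = im.transpose(Image.FLIP_LEFT_RIGHT)
    if config.allow_vertical_flip and rng.random() < 0.5:
        im = im.transpose(Image.FLIP_TOP_BOTTOM)

    if config.perspective_jitter > 0:
        s = im.size[0]
        jit = config.perspective_jitter * s
        src = [(0, 0), (s, 0), (s, s), (0, s)]
        dst = [
            (float(x + rng.uniform(-jit, jit)), float(y + rng.uniform(-jit, jit)))
            for x, y in src
        ]
        coeffs = _perspective_coeffs(src, dst)
        im = im.transform(im.size, Image.PERSPECTIVE, tuple(coeffs), Image.BILINEAR)

    gains = np.array([rng.uniform(lo, hi) for lo, hi in config.gain_ranges()])
    out = im.resize((config.output_size, config.output_size), Image.BILINEAR)
    arr = np.asarray(out, dtype=np.float64) * gains
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def augment_iter(
    images: Sequence[np.ndarray], config: AugmentConfig
) -> Iterator[tuple[np.ndarray, int, int]]:
    """Yield (augmented image, source index, draw_seed), balanced round-robin.

    Exactly ``target_count`` items; each source contributes either
    floor or ceil of target_count / n_sources draws.
    """
    config.validate(n_sources=len(images))
    if len(images) == 0:
        raise ValueError("need at least one source image")
    n = len(images)
    for k in range(config.target_count):
        src = k % n
        yield augment_one(images[src], config, draw_seed=k), src, k


def build_dataset(
    images: Sequence[np.ndarray], config: AugmentConfig
) -> list[np.ndarray]:
    """Materialised augmentation set of exactly ``config.target_count`` images."""
    return [img for img, _, _ in augment_iter(images, config)]


def augment_directory(
    in_dir, out_dir, config: AugmentConfig
) -> pd.DataFrame:
    """Augment every PNG/JPEG under ``in_dir`` into ``out_dir`` + manifest CSV."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    paths = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise ValueError(f"no images found in {in_dir}")
    images = [np.asarray(Image.open(p).convert("RGB")) for p in paths]
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, src, draw in augment_iter(images, config):
        out_id = f"aug_{draw:06d}"
        Image.fromarray(img).save(out_dir / f"{out_id}.png")
        rows.append({"output_id": out_id, "source_id": paths[src].stem, "draw_seed": draw})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
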