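"""Synthetic labelled tongue images with class-conditional colour statistics.

Clinical tongue photographs cannot be redistributed, so the pipeline is
exercised on rendered stand-ins: an ellipse-like "tongue" blob on an exactly
black background, whose base colour is drawn from a per-class HSV palette
box, modulated by smooth multiplicative shading, and sprinkled with
whitish "coating" speckles at a class-specific density.  The five palette
boxes follow the Traditional Chinese Medicine descriptions — light white is
pale (low saturation, high value); light red, red and deep red share the
red hue band with increasing saturation and decreasing value; cyan sits at
the opposite side of the hue circle — and are pairwise disjoint in the
H×S×V product, so classes are separable by colour statistics alone (the
:func:`hue_probe` guard measures this).  The renderer is a pure function of
(label, seed, size, palette): identical inputs give bit-identical images.

These images emulate segmented-tongue geometry, class colour statistics and
coating interference; they do not emulate papillae, cracks, moisture,
lighting gradients of the acquisition device, or photorealistic texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import CLASSES, hsv_to_rgb, load_image, save_image, write_manifest

__all__ = [
    "ClassColors",
    "DEFAULT_PALETTE",
    "SyntheticConfig",
    "TABLE_CLASS_COUNTS",
    "render_tongue",
    "iter_images",
    "generate_arrays",
    "generate_dataset",
    "hue_probe",
]

#: Published per-class case counts of the clinical dataset (light red, red,
#: deep red, light white, cyan) — the default count template.
TABLE_CLASS_COUNTS = {
    "light_red": 382,
    "red": 312,
    "deep_red": 104,
    "light_white": 304,
    "cyan": 269,
}


@dataclass(frozen=True)
class ClassColors:
    """Palette box for one class: hue band [lo, hi), saturation and value
    ranges (all unit-interval), coating speckle density and coating HSV."""

    hue: tuple[float, float]
    sat: tuple[float, float]
    val: tuple[float, float]
    coating_density: float
    coating_hsv: tuple[float, float, float]


def _box(hue, sat, val, density):
    coat_hue = (hue[0] + hue[1]) / 2.0  # same band as the body: keeps the
    # plain (non-circular) mean hue inside the class band
    return ClassColors(hue, sat, val, density, (coat_hue, 0.08, 0.92))


# Hue bands stop short of the 1.0 wrap point so that 8-bit quantisation
# noise cannot wrap pixel hues across the circle; the three red classes
# share the red band and are separated by saturation/value.
DEFAULT_PALETTE: dict[str, ClassColors] = {
    "light_red": _box((0.925, 0.985), (0.30, 0.45), (0.80, 0.95), 0.12),
    "red": _box((0.940, 0.985), (0.55, 0.72), (0.58, 0.75), 0.08),
    "deep_red": _box((0.945, 0.985), (0.78, 0.95), (0.32, 0.46), 0.05),
    "light_white": _box((0.880, 0.975), (0.04, 0.14), (0.86, 0.97), 0.10),
    "cyan": _box((0.450, 0.550), (0.25, 0.55), (0.50, 0.80), 0.15),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset recipe: image size, per-class counts, master seed, palette."""

    size: tuple[int, int] = (256, 256)
    counts: dict[str, int] = field(default_factory=lambda: dict(TABLE_CLASS_COUNTS))
    seed: int = 0
    palette: dict[str, ClassColors] = field(default_factory=lambda: dict(DEFAULT_PALETTE))

    def __post_init__(self):
        if min(self.size) < 32:
            raise ValueError("image side must be >= 32")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        unknown = set(self.counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")


def _rng_for(seed: int, label: str, size: tuple[int, int]) -> np.random.Generator:
    return np.random.default_rng([seed, CLASSES.index(label), size[0], size[1]])


def render_tongue(
    label: str,
    seed: int,
    size: tuple[int, int] = (256, 256),
    palette: dict[str, ClassColors] | None = None,
    return_masks: bool = False,
):
    """Render one synthetic tongue image.

    Returns a uint8 RGB array (and, with ``return_masks``, the boolean
    tongue and coating masks).  Background pixels are exactly (0, 0, 0).
    """
    palette = palette or DEFAULT_PALETTE
    if label not in palette or label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}")
    box = palette[label]
    h, w = size
    rng = _rng_for(seed, label, (h, w))

    # elliptical tongue blob, slightly jittered and taller than wide
    cy = h * (0.5 + rng.uniform(-0.04, 0.04))
    cx = w * (0.5 + rng.uniform(-0.04, 0.04))
    ay = h * rng.uniform(0.30, 0.40)
    ax = w * rng.uniform(0.24, 0.34)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    mask = r2 <= 1.0

    # base colour from the interior of the palette box (15% margin on hue,
    # so jitter + 8-bit quantisation keep the mask-mean hue inside the band)
    hw = box.hue[1] - box.hue[0]
    hue0 = rng.uniform(box.hue[0] + 0.15 * hw, box.hue[1] - 0.15 * hw)
    sat0 = rng.uniform(*box.sat)
    val0 = rng.uniform(*box.val)

    hue = np.clip(hue0 + rng.normal(0.0, 0.004, (h, w)), box.hue[0], box.hue[1] - 1e-6)
    sat = np.clip(sat0 + rng.normal(0.0, 0.02, (h, w)), 0.02, 1.0)

    # gentle multiplicative shading: radial falloff + low-frequency wave
    phase = rng.uniform(0, 2 * np.pi)
    shade = 1.0 - 0.10 * r2 - 0.04 * np.sin(2 * np.pi * yy / h + phase)
    val = np.clip(val0 * np.clip(shade, 0.82, 1.0), 0.05, 1.0)

    # coating speckles: seeded points dilated into small blobs
    speck = rng.random((h, w)) < box.coating_density / 9.0
    coating = ndimage.binary_dilation(speck & mask, iterations=1, structure=np.ones((3, 3), bool))
    coating &= mask
    ch, cs, cv = box.coating_hsv
    hue = np.where(coating, np.clip(ch + (hue - hue0) * 0.3, 0.0, 1.0 - 1e-6), hue)
    sat = np.where(coating, cs, sat)
    val = np.where(coating, cv * np.clip(shade, 0.82, 1.0), val)

    hsv = np.stack([hue, sat, val], axis=-1)
    rgb = hsv_to_rgb(hsv)
    rgb[~mask] = 0
    if return_masks:
        return rgb, mask, coating
    return rgb


def iter_images(cfg: SyntheticConfig):
    """Yield ``(label, index, image)`` for the whole configured dataset."""
    for label in CLASSES:
        n = cfg.counts.get(label, 0)
        for i in range(n):
            yield label, i, render_tongue(label, cfg.seed + i, cfg.size, cfg.palette)


def generate_arrays(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: (images [N,H,W,3] uint8, labels [N] class indices)."""
    imgs, labels = [], []
    for label, _i, img in iter_images(cfg):
        imgs.append(img)
        labels.append(CLASSES.index(label))
    if not imgs:
        return np.empty((0, *cfg.size, 3), np.uint8), np.empty(0, int)
    return np.stack(imgs), np.asarray(labels)


def generate_dataset(cfg: SyntheticConfig, out_dir) -> pd.DataFrame:
    """Write the dataset (PNG per image, per-class subdirectories) and a
    manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    rows = []
    for label, i, img in iter_images(cfg):
        path = out_dir / label / f"{label}_{i:04d}.png"
        save_image(img, path)
        rows.append({"path": str(path), "label": label})
    manifest = pd.DataFrame(rows, columns=["path", "label"])
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def _palette_centers(palette: dict[str, ClassColors]) -> dict[str, np.ndarray]:
    return {
        label: np.array([np.mean(box.hue), np.mean(box.sat), np.mean(box.val)])
        for label, box in palette.items()
    }


def _classify_mean_hsv(mean_hsv: np.ndarray, centers: dict[str, np.ndarray]) -> str:
    best, best_d = None, np.inf
    for label, c in centers.items():
        dh = abs(mean_hsv[0] - c[0])
        dh = min(dh, 1.0 - dh)  # hue is circular
        d = (2.0 * dh) ** 2 + (mean_hsv[1] - c[1]) ** 2 + (mean_hsv[2] - c[2]) ** 2
        if d < best_d:
            best, best_d = label, d
    return best


def hue_probe(records, palette: dict[str, ClassColors] | None = None) -> float:
    """Separability guard: classify each image by the palette centre nearest
    to its tongue-mask mean HSV; return the fraction correct.

    ``records`` is either a manifest DataFrame (images loaded from disk) or
    an iterable of ``(image, label)`` pairs.  A degenerate generator (all
    classes alike) scores near chance; the default palette should score
    high — downstream training tests rely on that signal.
    """
    from .preprocess import rgb_to_hsv

    palette = palette or DEFAULT_PALETTE
    centers = _palette_centers(palette)
    if isinstance(records, pd.DataFrame):
        pairs = ((load_image(r.path), r.label) for r in records.itertuples(index=False))
    else:
        pairs = iter(records)
    correct = total = 0
    for img, label in pairs:
        img = np.asarray(img)
        mask = img.any(axis=-1)
        if not mask.any():
            continue
        hsv = rgb_to_hsv(img)
        mean_hsv = hsv[mask].mean(axis=0)
        correct += _classify_mean_hsv(mean_hsv, centers) == label
        total += 1
    if total == 0:
        raise ValueError("hue_probe needs at least one image")
    return correct / total
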