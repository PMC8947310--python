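"""Deterministic image normalisation for tongue photographs.

Segmented tongue images arrive as 24-bit RGB of varying size (the two
acquisition formats are 1640×2460 and 1480×2220) with the tongue on a black
background.  Preprocessing makes them model-ready:

* :func:`resize_pad` — aspect-preserving "letterbox" resize: the long side
  is scaled to the target side ``L``, the short side by the same factor,
  and the short axis is filled with black pixels to an L×L square.
* :func:`rgb_to_hsv` — conversion to HSV, the representation the classifier
  consumes; all three channels are scaled to the unit interval (a full hue
  circle is 1.0).
* :func:`adjust_brightness` — per-channel power-law (gamma) mapping
  ``I' = (I/255)^k · 255`` with ``k`` in [0.25, 4]; ``k < 1`` brightens,
  ``k > 1`` darkens.  Black stays black, so padding is unaffected.

Integer rounding is round-half-up throughout.  Manifest files are CSV with
columns ``path,label,split``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as _skcolor

__all__ = [
    "CLASSES",
    "ResizeSpec",
    "resize_pad",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "adjust_brightness",
    "BRIGHTNESS_RANGE",
    "load_image",
    "save_image",
    "read_manifest",
    "write_manifest",
    "prepare_image",
]

#: The five diagnostic tongue-body colours of Traditional Chinese Medicine,
#: in canonical label order (used for class indices everywhere).
CLASSES = ("light_red", "red", "deep_red", "light_white", "cyan")

#: Valid range of the brightness adjustment factor k.
BRIGHTNESS_RANGE = (0.25, 4.0)


def _round_half_up(x):
    return np.floor(np.asarray(x) + 0.5)


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("zero-sized image")
    return img


@dataclass(frozen=True)
class ResizeSpec:
    """Letterbox-resize parameters: target square side, bilinear
    interpolation, black centred padding (remainder pixel at bottom/right)."""

    side: int = 128
    interpolation: str = "bilinear"
    pad_value: int = 0

    def __post_init__(self):
        if self.side < 2:
            raise ValueError("target side must be >= 2")
        if self.interpolation != "bilinear":
            raise ValueError("only bilinear interpolation is supported")


def resize_pad(img: np.ndarray, spec: ResizeSpec | int = 128) -> np.ndarray:
    """Scale the long side to ``spec.side``, keep aspect ratio, pad the
    short axis with black to a square.  Already-square inputs of the target
    size pass through pixel-identical."""
    if isinstance(spec, int):
        spec = ResizeSpec(side=spec)
    img = _validate_rgb(img)
    h, w = img.shape[:2]
    L = spec.side
    if h >= w:
        nh, nw = L, int(_round_half_up(w * L / h))
    else:
        nh, nw = int(_round_half_up(h * L / w)), L
    nh, nw = max(nh, 1), max(nw, 1)
    if (nh, nw) == (h, w):
        content = img.astype(np.uint8, copy=True)
    else:
        pil = Image.fromarray(img.astype(np.uint8))
        content = np.asarray(pil.resize((nw, nh), Image.BILINEAR))
    out = np.full((L, L, 3), spec.pad_value, dtype=np.uint8)
    top, left = (L - nh) // 2, (L - nw) // 2
    out[top : top + nh, left : left + nw] = content
    return out


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """8-bit RGB -> HSV floats with H, S, V each in [0, 1] (hexcone model;
    a full hue circle is 1.0)."""
    img = _validate_rgb(img)
    return _skcolor.rgb2hsv(img.astype(np.uint8))


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Unit-interval HSV -> 8-bit RGB (inverse of :func:`rgb_to_hsv`)."""
    hsv = np.asarray(hsv, dtype=float)
    rgb = _skcolor.hsv2rgb(hsv)
    return _round_half_up(rgb * 255.0).astype(np.uint8)


def adjust_brightness(img: np.ndarray, k: float) -> np.ndarray:
    """Power-law brightness mapping ``I' = round((I/255)^k · 255)``.

    ``k`` must lie in [0.25, 4]; k < 1 brightens, k > 1 darkens.  Applied
    per RGB channel through a lookup table.
    """
    lo, hi = BRIGHTNESS_RANGE
    if not (lo <= k <= hi):
        raise ValueError(f"brightness factor k={k} outside [{lo}, {hi}]")
    img = _validate_rgb(img)
    lut = _round_half_up((np.arange(256) / 255.0) ** k * 255.0).astype(np.uint8)
    return lut[img.astype(np.uint8)]


def prepare_image(img: np.ndarray, side: int = 128) -> np.ndarray:
    """Full model-input pipeline: letterbox to ``side`` then HSV floats."""
    return rgb_to_hsv(resize_pad(img, side)).astype(np.float32)


# ---------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as an H×W×3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(img: np.ndarray, path) -> None:
    """Write an RGB array as PNG."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path, format="PNG")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    unknown = set(df["label"]) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown labels in manifest: {sorted(unknown)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
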