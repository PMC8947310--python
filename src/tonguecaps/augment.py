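"""Deterministic, class-balancing data expansion.

Training data is expanded with four transform families — rotation (90°,
180°, counter-clockwise), horizontal/vertical shifts (content moved by a
fraction of the axis, vacated pixels black) and power-law brightness
changes (k = 0.5 brighten, k = 1.5 darken) — applied on the stored 8-bit
RGB images.  Each class gets a per-class multiplier m: every source image
yields m variants (the original counts as the first), so after expansion
the five class counts are approximately balanced.

Everything here is deterministic: the m transforms per class come from a
canonical enumeration (singles first, then pairwise composites), so
re-running an expansion is bit-identical.  The default multipliers
{light_red: 4, red: 5, deep_red: 14, light_white: 5, cyan: 6} are the
unique integers that carry the published per-class training counts
(244, 200, 66, 196, 172) to the published expanded counts
(976, 1000, 924, 980, 1032; 4912 in total).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CLASSES, adjust_brightness, load_image, save_image

__all__ = [
    "TransformSpec",
    "AugmentationPlan",
    "DEFAULT_MULTIPLIERS",
    "apply_transform",
    "enumerate_plan",
    "expand_manifest",
    "balance_dataset",
]

_KINDS = ("identity", "rot90", "rot180", "hshift", "vshift", "brightness")

#: Per-class expansion factors reproducing the published balanced counts.
DEFAULT_MULTIPLIERS = {
    "light_red": 4,
    "red": 5,
    "deep_red": 14,
    "light_white": 5,
    "cyan": 6,
}

_DEFAULT_SHIFT = 0.1
_DEFAULT_BRIGHTNESS = (0.5, 1.5)


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation step; ``compose_with`` chains a second step
    (applied after this one; depth is capped at two)."""

    kind: str
    param: float = 0.0
    compose_with: "TransformSpec | None" = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind in ("hshift", "vshift") and not (0.0 <= self.param <= 0.25):
            raise ValueError("shift fraction must lie in [0, 0.25]")
        if self.compose_with is not None and self.compose_with.compose_with is not None:
            raise ValueError("composition depth is limited to 2")

    def label(self) -> str:
        base = self.kind if self.kind in ("identity", "rot90", "rot180") else f"{self.kind}{self.param:g}"
        if self.compose_with is not None:
            return f"{base}+{self.compose_with.label()}"
        return base


def _apply_single(img: np.ndarray, t: TransformSpec) -> np.ndarray:
    if t.kind == "identity":
        return img.copy()
    if t.kind == "rot90":  # counter-clockwise
        return np.rot90(img, 1)
    if t.kind == "rot180":
        return np.rot90(img, 2)
    if t.kind == "hshift":
        shift = int(np.floor(t.param * img.shape[1] + 0.5))
        out = np.zeros_like(img)
        if shift == 0:
            return img.copy()
        out[:, shift:] = img[:, :-shift]
        return out
    if t.kind == "vshift":
        shift = int(np.floor(t.param * img.shape[0] + 0.5))
        out = np.zeros_like(img)
        if shift == 0:
            return img.copy()
        out[shift:, :] = img[:-shift, :]
        return out
    return adjust_brightness(img, t.param)


def apply_transform(img: np.ndarray, t: TransformSpec) -> np.ndarray:
    """Apply ``t`` (and its optional chained step) to an RGB image.

    Rotations are exact array permutations; shifts move content toward the
    bottom/right, clipping at the border and filling vacated pixels with
    black; brightness delegates to the power-law adjustment (which keeps
    black pixels black, so these families commute with it).
    """
    out = _apply_single(np.asarray(img), t)
    if t.compose_with is not None:
        out = _apply_single(out, t.compose_with)
    return np.ascontiguousarray(out)


def _transform_pool() -> list[TransformSpec]:
    """Canonical ordered pool: 7 singles, then geometric∘brightness, then
    geometric∘geometric composites in lexicographic base-list order.

    Commuting geometric pairs (rotation with rotation, shift with shift)
    are enumerated once — both orders would render identical pixels.
    """
    b_lo, b_hi = _DEFAULT_BRIGHTNESS
    singles = [
        TransformSpec("identity"),
        TransformSpec("rot90"),
        TransformSpec("rot180"),
        TransformSpec("hshift", _DEFAULT_SHIFT),
        TransformSpec("vshift", _DEFAULT_SHIFT),
        TransformSpec("brightness", b_lo),
        TransformSpec("brightness", b_hi),
    ]
    geo = singles[1:5]
    bright = singles[5:7]
    pool = list(singles)
    for g in geo:
        for b in bright:
            pool.append(TransformSpec(g.kind, g.param, compose_with=b))
    rotations = {"rot90", "rot180"}
    shifts = {"hshift", "vshift"}
    for i, g1 in enumerate(geo):
        for j, g2 in enumerate(geo):
            if i == j:
                continue
            same_family = ({g1.kind, g2.kind} <= rotations) or ({g1.kind, g2.kind} <= shifts)
            if same_family and j < i:
                continue
            pool.append(TransformSpec(g1.kind, g1.param, compose_with=g2))
    return pool


def enumerate_plan(m: int) -> list[TransformSpec]:
    """The first ``m`` transforms of the canonical pool (identity first).

    Raises if ``m`` exceeds the enumerable pool (7 singles + 18 composites).
    """
    if m < 1:
        raise ValueError("multiplier must be >= 1")
    pool = _transform_pool()
    if m > len(pool):
        raise ValueError(f"multiplier {m} exceeds the transform pool ({len(pool)})")
    return pool[:m]


@dataclass(frozen=True)
class AugmentationPlan:
    """Per-class multipliers plus the transforms they enumerate."""

    multipliers: dict[str, int]

    def __post_init__(self):
        for label, m in self.multipliers.items():
            if label not in CLASSES:
                raise ValueError(f"unknown class {label!r}")
            if m < 1:
                raise ValueError("multipliers must be positive")

    def transforms(self, label: str) -> list[TransformSpec]:
        return enumerate_plan(self.multipliers[label])


def expand_manifest(manifest: pd.DataFrame, plan: AugmentationPlan | dict[str, int]) -> pd.DataFrame:
    """Pure manifest expansion: one output row per (source image, transform).

    Output columns: ``path`` (the augmented file the materialisation step
    will write), ``label``, ``split`` (if present), ``source`` and
    ``transform`` (provenance).  Per-class output count is exactly
    n_class × m_class.
    """
    if isinstance(plan, dict):
        plan = AugmentationPlan(plan)
    missing = set(manifest["label"]) - set(plan.multipliers)
    if missing:
        raise ValueError(f"no multiplier configured for classes {sorted(missing)}")
    rows = []
    for rec in manifest.itertuples(index=False):
        transforms = plan.transforms(rec.label)
        src = Path(rec.path)
        for idx, t in enumerate(transforms):
            out_name = f"{src.stem}__t{idx:02d}.png"
            row = {
                "path": str(src.parent / out_name),
                "label": rec.label,
                "source": str(src),
                "transform": t.label(),
            }
            if hasattr(rec, "split"):
                row["split"] = rec.split
            rows.append(row)
    return pd.DataFrame(rows)


def balance_dataset(
    manifest: pd.DataFrame,
    plan: AugmentationPlan | dict[str, int],
    out_dir,
    image_root=None,
) -> pd.DataFrame:
    """Materialise the expansion: apply every planned transform and write
    the augmented images (PNG) under ``out_dir``, mirroring per-class
    subdirectories.  Returns the augmented manifest (paths relative to
    ``out_dir``'s parent structure).  Fully deterministic."""
    if isinstance(plan, dict):
        plan = AugmentationPlan(plan)
    out_dir = Path(out_dir)
    expanded = expand_manifest(manifest, plan)
    cache_path, cache_img = None, None
    out_rows = []
    for rec in expanded.itertuples(index=False):
        src = Path(rec.source) if image_root is None else Path(image_root) / rec.source
        if cache_path != src:
            cache_img, cache_path = load_image(src), src
        t = _parse_label(rec.transform)
        out_path = out_dir / rec.label / Path(rec.path).name
        save_image(apply_transform(cache_img, t), out_path)
        row = dict(rec._asdict())
        row["path"] = str(out_path)
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def _parse_label(label: str) -> TransformSpec:
    parts = label.split("+")

    def single(s: str) -> TransformSpec:
        for kind in ("brightness", "hshift", "vshift"):
            if s.startswith(kind):
                return TransformSpec(kind, float(s[len(kind):]))
        return TransformSpec(s)

    t = single(parts[0])
    if len(parts) > 1:
        t = TransformSpec(t.kind, t.param, compose_with=single(parts[1]))
    return t
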