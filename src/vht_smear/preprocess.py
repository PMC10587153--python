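"""Pre-processing: dark-border cropping, standard resizing and augmentation.

The pipeline standardises every smear crop to a square side (default 200 px)
after removing the uninformative dark border, then balances classes by
augmentation: right 90-degree rotation, horizontal flip, vertical flip and
salt-and-pepper noise, applied cyclically to uniformly sampled originals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .synth import SmearImage

#: Fixed augmentation cycle order.
AUGMENT_OPS = ("rot90_right", "flip_horizontal", "flip_vertical", "salt_pepper")

DEFAULT_DARK_THRESHOLD = 20
DEFAULT_SP_DENSITY = 0.02


@dataclass(frozen=True)
class AugmentOp:
    """One augmentation operation; ``density``/``seed`` only for salt_pepper."""

    kind: str
    density: float = DEFAULT_SP_DENSITY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AUGMENT_OPS:
            raise ValueError(f"kind must be one of {AUGMENT_OPS}, got {self.kind!r}")
        if self.kind == "salt_pepper" and not (0.0 < self.density < 1.0):
            raise ValueError("salt_pepper density must be in (0, 1)")


def autocrop(img: SmearImage, dark_threshold: int = DEFAULT_DARK_THRESHOLD) -> SmearImage:
    """Crop to the tight bounding box of pixels brighter than the threshold.

    A pixel counts as non-dark when its maximum channel is >= the threshold.
    If the whole image is dark the input is returned unchanged.
    """
    bright = img.pixels.max(axis=2) >= dark_threshold
    if not bright.any():
        return img
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    sub = img.pixels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    return SmearImage(pixels=sub, label=img.label, provenance=img.provenance)


def resize_to_standard(img: SmearImage, side: int = 200) -> SmearImage:
    """Bilinear resize to ``side`` x ``side``; identity if already that size."""
    if side < 3:
        raise ValueError("side must be >= 3")
    if img.pixels.shape[:2] == (side, side):
        return img
    out = Image.fromarray(img.pixels).resize((side, side), Image.BILINEAR)
    return SmearImage(pixels=np.asarray(out), label=img.label,
                      provenance=img.provenance)


def apply_augment(img: SmearImage, op: AugmentOp) -> SmearImage:
    """Apply one augmentation, recording it in the provenance tag."""
    px = img.pixels
    if op.kind == "rot90_right":
        out = np.rot90(px, k=-1)
    elif op.kind == "flip_horizontal":
        out = px[:, ::-1]
    elif op.kind == "flip_vertical":
        out = px[::-1, :]
    else:  # salt_pepper: exactly floor(density*H*W) pixels forced to 0 or 255
        h, w = px.shape[:2]
        n_noise = int(op.density * h * w)
        rng = np.random.default_rng(op.seed)
        flat = px.reshape(-1, 3).copy()
        idx = rng.choice(h * w, size=n_noise, replace=False)
        half = n_noise // 2
        flat[idx[:half]] = 255
        flat[idx[half:]] = 0
        out = flat.reshape(h, w, 3)
    return SmearImage(pixels=out.copy(), label=img.label,
                      provenance=f"augmented:{op.kind}")


def balance_dataset(
    manifest: pd.DataFrame,
    target_per_class: int,
    ops: Sequence[str] = AUGMENT_OPS,
    seed: int = 0,
    out_dir: str | Path | None = None,
    sp_density: float = DEFAULT_SP_DENSITY,
) -> pd.DataFrame:
    """Augment each class up to ``target_per_class`` rows.

    Originals are never removed; added rows are augmented copies, cycling
    through ``ops`` in order and drawing source images uniformly (seeded).
    Augmented PNGs are written next to their sources unless ``out_dir`` is
    given.  Returns the enlarged manifest.
    """
    counts = manifest["label"].value_counts()
    if (counts == 0).any() or manifest.empty:
        raise ValueError("every class must be nonempty")
    if target_per_class < counts.max():
        raise ValueError(
            f"target_per_class ({target_per_class}) below largest class ({counts.max()})"
        )
    rng = np.random.default_rng(seed)
    new_rows: List[dict] = []
    for label in sorted(counts.index):
        cls = manifest[manifest["label"] == label].reset_index(drop=True)
        n_add = target_per_class - len(cls)
        for j in range(n_add):
            src = cls.iloc[int(rng.integers(len(cls)))]
            kind = ops[j % len(ops)]
            op = AugmentOp(kind, density=sp_density,
                           seed=int(rng.integers(2 ** 31))) \
                if kind == "salt_pepper" else AugmentOp(kind)
            src_path = Path(src["path"])
            img = SmearImage(pixels=np.asarray(Image.open(src_path).convert("RGB")),
                             label=label)
            aug = apply_augment(img, op)
            dest_dir = Path(out_dir) / label if out_dir is not None else src_path.parent
            dest_dir.mkdir(parents=True, exist_ok=True)
            dest = dest_dir / f"{src_path.stem}_aug{j:05d}.png"
            Image.fromarray(aug.pixels).save(dest)
            new_rows.append({"path": str(dest), "label": label,
                             "provenance": aug.provenance})
    out = pd.concat([manifest, pd.DataFrame(new_rows, columns=manifest.columns)],
                    ignore_index=True)
    return out


def load_standard(path: str | Path, side: int = 200,
                  dark_threshold: int = DEFAULT_DARK_THRESHOLD,
                  label: str = "lymphocyte") -> SmearImage:
    """Read a PNG/JPEG, autocrop the dark border and resize to the standard side."""
    img = SmearImage(pixels=np.asarray(Image.open(path).convert("RGB")), label=label)
    return resize_to_standard(autocrop(img, dark_threshold), side)
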