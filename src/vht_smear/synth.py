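"""Synthetic white-blood-cell smear generator.

Renders labeled single-cell smear crops for the four WBC classes so the whole
pipeline can be exercised without any external dataset.  Each image contains a
stained cell — pink low-contrast cytoplasm, purple nucleus — over a dark,
irregular background with a linear illumination gradient and sensor noise.
The nucleus morphology carries the class signal:

* lymphocyte — one large round nucleus covering at least 60% of the cell;
* monocyte   — a kidney-shaped (indented) nucleus;
* eosinophil — two nuclear lobes plus dense granular speckle in the cytoplasm;
* neutrophil — 3 to 5 separate nuclear lobes.

Rendering is fully vectorised and deterministic: the same configuration and
seed reproduce byte-identical pixel grids.  Ground-truth cell/nucleus masks
are kept on the image object for generator self-tests only; the downstream
pipeline never reads them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

#: The four leukocyte classes, in fixed (alphabetical) order.
CLASSES = ("eosinophil", "lymphocyte", "monocyte", "neutrophil")


@dataclass(frozen=True)
class GeneratorConfig:
    """Rendering parameters for the synthetic smear generator."""

    image_size: int = 200
    cell_radius_range: Tuple[float, float] = (55.0, 75.0)
    background_level_range: Tuple[float, float] = (10.0, 35.0)
    illumination_gradient_strength: float = 0.35
    noise_density: float = 0.01
    seed: int = 0


@dataclass
class SmearImage:
    """A smear crop with its class label and provenance tag."""

    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    provenance: str = "synthetic"
    cell_mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    nucleus_mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(
                f"label must be one of {CLASSES}, got {self.label!r}"
            )
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = np.stack([self.pixels] * 3, axis=-1)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxW or HxWx3")
        self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


def _wobbly_disk(yy, xx, cy, cx, radius, rng, wobble=0.05, n_harmonics=3,
                 aspect=1.0, angle=0.0):
    """Boolean mask of a disk with a harmonically perturbed boundary."""
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    dist = np.hypot(u, v)
    theta = np.arctan2(v, u)
    rad = np.full_like(dist, float(radius))
    for k in range(2, 2 + n_harmonics):
        amp = wobble * radius * float(rng.uniform(0.3, 1.0)) / k
        phase = float(rng.uniform(0, 2 * np.pi))
        rad = rad + amp * np.cos(k * theta + phase)
    return dist <= rad


def _smooth_noise(shape, rng, sigma=4.0):
    """Zero-mean unit-ish smooth random field for chromatin/cytoplasm texture."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _nucleus_mask(label, yy, xx, cy, cx, r, rng):
    """Class-specific nucleus morphology mask."""
    if label == "lymphocyte":
        # single large round nucleus, >= 60% of the cell area
        off = 0.05 * r
        ang = rng.uniform(0, 2 * np.pi)
        return _wobbly_disk(
            yy, xx, cy + off * np.sin(ang), cx + off * np.cos(ang),
            0.82 * r, rng, wobble=0.025,
        )
    if label == "monocyte":
        ang = rng.uniform(0, 2 * np.pi)
        body = _wobbly_disk(yy, xx, cy, cx, 0.68 * r, rng, wobble=0.04,
                            aspect=rng.uniform(0.85, 1.0), angle=ang)
        # indentation producing the kidney shape
        d = 0.62 * r
        icy = cy + d * np.sin(ang)
        icx = cx + d * np.cos(ang)
        indent = _wobbly_disk(yy, xx, icy, icx, 0.42 * r, rng, wobble=0.05)
        return body & ~indent
    if label == "eosinophil":
        axis = rng.uniform(0, 2 * np.pi)
        sep = 0.40 * r
        mask = np.zeros_like(yy, dtype=bool)
        for s in (-1.0, 1.0):
            lcy = cy + s * sep * np.sin(axis) + rng.uniform(-2, 2)
            lcx = cx + s * sep * np.cos(axis) + rng.uniform(-2, 2)
            mask |= _wobbly_disk(yy, xx, lcy, lcx, 0.36 * r, rng, wobble=0.05,
                                 aspect=rng.uniform(0.75, 0.95),
                                 angle=rng.uniform(0, np.pi))
        return mask
    if label == "neutrophil":
        n_lobes = int(rng.integers(3, 6))
        ring = 0.47 * r
        base = rng.uniform(0, 2 * np.pi)
        mask = np.zeros_like(yy, dtype=bool)
        for i in range(n_lobes):
            ang = base + 2 * np.pi * i / n_lobes + rng.uniform(-0.12, 0.12)
            lcy = cy + ring * np.sin(ang)
            lcx = cx + ring * np.cos(ang)
            mask |= _wobbly_disk(yy, xx, lcy, lcx, 0.185 * r, rng, wobble=0.06,
                                 aspect=rng.uniform(0.8, 1.0),
                                 angle=rng.uniform(0, np.pi))
        return mask
    raise ValueError(f"label must be one of {CLASSES}, got {label!r}")


def render_cell(label: str, cfg: GeneratorConfig, rng: np.random.Generator) -> SmearImage:
    """Render one synthetic smear crop for the given class.

    The ``rng`` stream fully determines the image: background level and
    illumination direction, cell placement and boundary wobble, nucleus lobe
    geometry, granules and sensor noise are all drawn from it.
    """
    if label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}, got {label!r}")
    n = cfg.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    # --- dark irregular background with linear illumination imbalance ---
    base = rng.uniform(*cfg.background_level_range)
    img = np.full((n, n, 3), base, dtype=float)
    img[..., 0] *= rng.uniform(0.9, 1.2)   # slight colour cast
    img[..., 2] *= rng.uniform(0.9, 1.2)
    for _ in range(int(rng.integers(2, 6))):   # faint out-of-focus ghosts
        gy, gx = rng.uniform(0, n, size=2)
        gr = rng.uniform(0.06 * n, 0.18 * n)
        ghost = _wobbly_disk(yy, xx, gy, gx, gr, rng, wobble=0.1)
        img[ghost] += rng.uniform(4, 14)

    # --- cell body: low-contrast pink cytoplasm ---
    cy = n / 2 + rng.uniform(-0.05 * n, 0.05 * n)
    cx = n / 2 + rng.uniform(-0.05 * n, 0.05 * n)
    r = rng.uniform(*cfg.cell_radius_range)
    cell = _wobbly_disk(yy, xx, cy, cx, r, rng, wobble=0.06)
    cyto_color = np.array([205.0, 168.0, 196.0]) + rng.uniform(-12, 12, size=3)
    shading = 1.0 - 0.12 * (np.hypot(yy - cy, xx - cx) / max(r, 1.0)) ** 2
    tex = 1.0 + 0.05 * _smooth_noise((n, n), rng, sigma=3.0)
    for ch in range(3):
        img[..., ch] = np.where(cell, cyto_color[ch] * shading * tex, img[..., ch])

    # --- eosinophilic granules (dense orange speckle in the cytoplasm) ---
    nucleus = _nucleus_mask(label, yy, xx, cy, cx, r, rng)
    nucleus &= cell
    if label == "eosinophil":
        cyto_only = cell & ~nucleus
        idx = np.flatnonzero(cyto_only.ravel())
        k = int(0.05 * idx.size)
        pick = rng.choice(idx, size=min(k, idx.size), replace=False)
        gmask = np.zeros(n * n, dtype=bool)
        gmask[pick] = True
        gmask = gmask.reshape(n, n)
        gmask = ndimage.binary_dilation(gmask) & cyto_only
        gcolor = np.array([226.0, 118.0, 92.0]) + rng.uniform(-10, 10, size=3)
        for ch in range(3):
            img[..., ch] = np.where(gmask, gcolor[ch], img[..., ch])

    # --- nucleus: purple with chromatin mottling ---
    ncolor = np.array([96.0, 52.0, 138.0]) + rng.uniform(-10, 10, size=3)
    chroma = 1.0 + 0.14 * _smooth_noise((n, n), rng, sigma=2.5)
    for ch in range(3):
        img[..., ch] = np.where(nucleus, ncolor[ch] * chroma, img[..., ch])

    # --- illumination gradient, impulse speckle, sensor noise ---
    ang = rng.uniform(0, 2 * np.pi)
    proj = ((xx * np.cos(ang) + yy * np.sin(ang)) / n)
    proj = proj - proj.mean()
    gain = 1.0 + cfg.illumination_gradient_strength * proj
    img *= gain[..., None]

    n_spk = int(cfg.noise_density * n * n)
    if n_spk > 0:
        spots = rng.choice(n * n, size=n_spk, replace=False)
        flat = img.reshape(-1, 3)
        flat[spots] = rng.uniform(0, 90, size=(n_spk, 3))
    img += rng.normal(0, 2.5, size=img.shape)

    return SmearImage(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        label=label,
        provenance="synthetic",
        cell_mask=cell,
        nucleus_mask=nucleus,
    )


def _image_rng(seed: int, class_idx: int, i: int) -> np.random.Generator:
    # one independent, reproducible stream per image
    return np.random.default_rng(np.random.SeedSequence([seed, class_idx, i]))


def generate_dataset(
    n_per_class: int,
    cfg: GeneratorConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a directory-per-class PNG dataset and return its manifest.

    The manifest (also written to ``out_dir/manifest.csv``) has columns
    ``path,label,provenance`` with ``4 * n_per_class`` rows.  Paths are
    relative to ``out_dir``'s parent-agnostic absolute form.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    rows = []
    for ci, label in enumerate(CLASSES):
        cdir = out_dir / label
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            img = render_cell(label, cfg, _image_rng(cfg.seed, ci, i))
            path = cdir / f"{label}_{i:05d}.png"
            Image.fromarray(img.pixels).save(path)
            rows.append({"path": str(path), "label": label,
                         "provenance": "synthetic"})
    manifest = pd.DataFrame(rows, columns=["path", "label", "provenance"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def dataset_checksum(manifest: pd.DataFrame) -> str:
    """SHA-256 over all image bytes in manifest order (determinism checks)."""
    h = hashlib.sha256()
    for p in manifest["path"]:
        h.update(Path(p).read_bytes())
    return h.hexdigest()
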