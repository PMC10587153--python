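"""COFE: convolution-operator feature extraction with the VHT kernels.

The four VHT gradient kernels (x, y, 45- and 135-degree diagonals) are slid
over the luminance image; the four response maps are pooled on a g x g grid
(default 4 x 4 on a 200 x 200 image) with five statistics per cell — mean,
mean absolute value, energy (mean square), standard deviation, and the
Pearson correlation between the cell's gradient responses and its luminance.
The default configuration therefore yields 4 maps x 16 cells x 5 statistics
= 320 features per image, in fixed map-major, row-major-cell, statistic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .lattice import KernelSet, canonical_kernels
from .preprocess import load_standard
from .synth import SmearImage

#: ITU-R 601 luminance weights; the generator's stain palette is colour but
#: the gradient operators act on a single intensity plane.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

STAT_NAMES = ("mean", "abs_mean", "energy", "std", "corr")
MAP_NAMES = ("x", "y", "45", "135")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered real feature values with a source tag."""

    values: np.ndarray
    source: str  # vht | deep | fused

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float).ravel())
        if self.source not in ("vht", "deep", "fused"):
            raise ValueError(f"unknown feature source {self.source!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return self.values.size


def luminance(img: SmearImage | np.ndarray) -> np.ndarray:
    """Float luminance plane of an RGB (or already-grayscale) image."""
    px = img.pixels if isinstance(img, SmearImage) else np.asarray(img)
    px = px.astype(float)
    if px.ndim == 2:
        return px
    w = np.asarray(LUMA_WEIGHTS)
    return px @ w


def gradient_responses(img: SmearImage | np.ndarray,
                       kernels: KernelSet | None = None) -> List[np.ndarray]:
    """The four gradient response maps of the luminance image.

    Each map has the same extent as the input (reflective border padding);
    kernel entries align with image positions, so a map value is the
    product-sum of the kernel with the 3x3 neighborhood centred there.
    """
    kernels = kernels or canonical_kernels()
    lum = luminance(img)
    if lum.shape[0] < 3 or lum.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    return [ndimage.correlate(lum, k, mode="reflect")
            for k in kernels.as_float().values()]


def _cell_stats(resp: np.ndarray, lum: np.ndarray) -> List[float]:
    r = resp.ravel()
    l = lum.ravel()
    mean = r.mean()
    abs_mean = np.abs(r).mean()
    energy = (r ** 2).mean()
    std = r.std()
    lsd = l.std()
    if std == 0.0 or lsd == 0.0:
        corr = 0.0  # zero-variance cell: correlation defined as 0
    else:
        corr = float(((r - mean) * (l - l.mean())).mean() / (std * lsd))
    return [float(mean), float(abs_mean), float(energy), float(std), corr]


class VHTFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer computing COFE feature vectors.

    Parameters
    ----------
    grid : int
        Pooling grid side; the image is cut into ``grid x grid`` equal cells.
    side : int
        Required (square) image side; images of any other shape are rejected
        with an instruction to preprocess first.
    kernels : KernelSet, optional
        Defaults to the canonical VHT kernels.
    """

    def __init__(self, grid: int = 4, side: int = 200,
                 kernels: KernelSet | None = None):
        self.grid = grid
        self.side = side
        self.kernels = kernels

    @property
    def n_features(self) -> int:
        return 4 * self.grid * self.grid * len(STAT_NAMES)

    def feature_names(self) -> List[str]:
        return [f"vht_{i:03d}" for i in range(self.n_features)]

    def fit(self, X=None, y=None):
        return self

    def transform_image(self, img: SmearImage | np.ndarray) -> FeatureVector:
        lum = luminance(img)
        if lum.shape != (self.side, self.side):
            raise ValueError(
                f"expected a {self.side}x{self.side} image, got {lum.shape}; "
                "preprocess (autocrop + resize_to_standard) first"
            )
        maps = gradient_responses(img, self.kernels or canonical_kernels())
        edges = np.linspace(0, self.side, self.grid + 1).astype(int)
        vals: List[float] = []
        for resp in maps:  # map-major
            for r in range(self.grid):  # cells row-major
                for c in range(self.grid):
                    sl = (slice(edges[r], edges[r + 1]),
                          slice(edges[c], edges[c + 1]))
                    vals.extend(_cell_stats(resp[sl], lum[sl]))
        return FeatureVector(values=np.array(vals), source="vht")

    def transform(self, X: Sequence[SmearImage | np.ndarray]) -> np.ndarray:
        """Feature matrix (n_images x n_features) for a sequence of images."""
        return np.vstack([self.transform_image(im).values for im in X])


def extract(img: SmearImage | np.ndarray, grid: int = 4,
            side: int = 200) -> FeatureVector:
    """COFE feature vector of one standard-size image (default length 320)."""
    return VHTFeatureExtractor(grid=grid, side=side).transform_image(img)


def extract_manifest(manifest: pd.DataFrame, grid: int = 4,
                     side: int = 200) -> pd.DataFrame:
    """One row per manifest image: path, label and the vht_* feature columns."""
    ex = VHTFeatureExtractor(grid=grid, side=side)
    rows = []
    for _, rec in manifest.iterrows():
        img = load_standard(rec["path"], side=side, label=rec["label"])
        rows.append(ex.transform_image(img).values)
    feats = pd.DataFrame(np.vstack(rows) if rows else
                         np.empty((0, ex.n_features)),
                         columns=ex.feature_names())
    out = pd.concat([manifest[["path", "label"]].reset_index(drop=True), feats],
                    axis=1)
    return out
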