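"""Pluggable deep-feature backend with a deterministic surrogate.

The pipeline treats its CNN feature source as an opaque ``FeatureBackend``:
anything mapping an image to a fixed-length vector (4096 by default, the
width of a classical fully-connected embedding layer).  The bundled
surrogate computes multiscale patch statistics — 8x8 block means and
standard deviations of the luminance plane and the four VHT gradient
response maps — and sends them through a fixed, seeded Gaussian random
projection to the target dimension.  It is deterministic, training-free and
carries enough class signal to exercise feature selection and fusion; a real
trained CNN can be plugged in through the same contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .features import gradient_responses, luminance
from .preprocess import load_standard
from .synth import SmearImage


def _block_stats(plane: np.ndarray, block: int) -> np.ndarray:
    """Per-block mean and sd of a 2-D plane, trimming any ragged edge."""
    h, w = plane.shape
    hb, wb = h // block, w // block
    trimmed = plane[: hb * block, : wb * block]
    tiles = trimmed.reshape(hb, block, wb, block).transpose(0, 2, 1, 3)
    tiles = tiles.reshape(hb * wb, block * block)
    return np.concatenate([tiles.mean(axis=1), tiles.std(axis=1)])


class SurrogateDeepFeatures(BaseEstimator, TransformerMixin):
    """Deterministic stand-in deep feature backend (sklearn transformer).

    Parameters
    ----------
    seed : int
        Fixes the random projection; the same seed always yields the same
        projection, hence identical outputs for identical inputs.
    dim : int
        Output feature count (default 4096).
    block : int
        Patch-statistic block side in pixels.
    """

    name = "surrogate"

    def __init__(self, seed: int = 0, dim: int = 4096, block: int = 8):
        self.seed = seed
        self.dim = dim
        self.block = block
        self._projection: np.ndarray | None = None

    def _stats(self, img: SmearImage | np.ndarray) -> np.ndarray:
        lum = luminance(img)
        planes = [lum] + gradient_responses(img)
        return np.concatenate([_block_stats(p, self.block) for p in planes])

    def _project(self, stats: np.ndarray) -> np.ndarray:
        width = stats.shape[-1]
        if self._projection is None or self._projection.shape != (width, self.dim):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed), int(width)]))
            self._projection = rng.standard_normal(
                (width, self.dim)) / np.sqrt(width)
        return stats @ self._projection

    def fit(self, X=None, y=None):
        return self

    def transform_image(self, img: SmearImage | np.ndarray) -> np.ndarray:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        return self._project(self._stats(img))

    def transform(self, X) -> np.ndarray:
        rows = [self._stats(im) for im in X]
        if not rows:
            return np.empty((0, self.dim))
        return self._project(np.vstack(rows))


def surrogate_backend(seed: int = 0, dim: int = 4096) -> SurrogateDeepFeatures:
    """Construct the deterministic surrogate backend."""
    return SurrogateDeepFeatures(seed=seed, dim=dim)


def featurize(manifest: pd.DataFrame, backend: SurrogateDeepFeatures,
              side: int = 200) -> pd.DataFrame:
    """Deep-feature table: path, label and ``deep_0000..`` columns, manifest order."""
    cols = [f"deep_{i:04d}" for i in range(backend.dim)]
    rows = []
    for _, rec in manifest.iterrows():
        try:
            img = load_standard(rec["path"], side=side, label=rec["label"])
        except OSError as e:
            raise OSError(f"cannot read image {rec['path']!r}: {e}") from e
        rows.append(img)
    feats = backend.transform(rows)
    out = pd.concat(
        [manifest[["path", "label"]].reset_index(drop=True),
         pd.DataFrame(feats, columns=cols)],
        axis=1,
    )
    return out
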