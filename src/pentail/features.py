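"""Frame -> feature-row pipeline: extraction, cleaning, PCA, scaling.

The reference backbone in the original study is an ImageNet-pretrained
VGG-16 truncated after its first fully-connected layer, yielding a
4,096-dimensional latent vector per 224x224 frame.  Here the extractor
is a pluggable contract: anything deterministic that maps images to
fixed-width rows satisfies it.  Two lightweight implementations are
provided for testing and synthetic runs (grid mean-pooling, optionally
followed by a fixed random projection up to the reference width).

The transform pipeline applied to extracted features is, in order:

1. drop columns whose sample variance is exactly zero across the whole
   dataset (bitwise-constant columns, not a small-variance threshold);
2. optionally project onto the first ``n_pc`` principal components,
   fitted on all pens simultaneously;
3. min-max scale each output dimension to [0, 1].

By default the transform is fitted on all pens — including test pens —
which reproduces the original protocol and its mild leakage; restrict
the rows passed to :func:`fit_transform_pipeline` to training pens to
avoid it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from sklearn.decomposition import PCA

REFERENCE_INPUT_SIZE = (224, 224)
REFERENCE_OUTPUT_DIM = 4096


@runtime_checkable
class ExtractorContract(Protocol):
    """Deterministic image -> feature-vector mapping of fixed width."""

    input_size: tuple[int, int]
    output_dim: int

    def __call__(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        ...


def _load_grayscale(source, input_size: tuple[int, int]) -> np.ndarray:
    from PIL import Image

    if isinstance(source, (str, Path)):
        with Image.open(source) as img:
            img = img.convert("L").resize(input_size[::-1], Image.BILINEAR)
            return np.asarray(img, dtype=np.float64)
    arr = np.asarray(source, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.shape != input_size:
        img = Image.fromarray(arr.astype(np.float32), mode="F")
        arr = np.asarray(img.resize(input_size[::-1], Image.BILINEAR), dtype=np.float64)
    return arr


@dataclass
class GridPoolExtractor:
    """Mean-pool a g x g grid over the resized grayscale frame.

    Interpretable stub: feature j is the mean intensity of one grid
    cell, so a localized motif moves exactly one feature.
    """

    grid: int = 8
    input_size: tuple[int, int] = REFERENCE_INPUT_SIZE

    @property
    def output_dim(self) -> int:
        return self.grid * self.grid

    def __call__(self, image) -> np.ndarray:
        arr = _load_grayscale(image, self.input_size)
        h, w = arr.shape
        gh, gw = h // self.grid, w // self.grid
        arr = arr[: gh * self.grid, : gw * self.grid]
        pooled = arr.reshape(self.grid, gh, self.grid, gw).mean(axis=(1, 3))
        return pooled.ravel()


class StubExtractor:
    """Grid pooling followed by a fixed seeded random projection.

    Matches the reference backbone's 4,096-wide output contract without
    pretrained weights; deterministic given (grid, output_dim, seed).
    """

    def __init__(self, output_dim: int = REFERENCE_OUTPUT_DIM, grid: int = 8, seed: int = 0):
        self.input_size = REFERENCE_INPUT_SIZE
        self.output_dim = output_dim
        self._pool = GridPoolExtractor(grid=grid)
        rng = np.random.default_rng(seed)
        d = self._pool.output_dim
        self._projection = rng.standard_normal((d, output_dim)) / np.sqrt(d)

    def __call__(self, image) -> np.ndarray:
        return self._pool(image) @ self._projection


def extract(images: Iterable, extractor: ExtractorContract) -> np.ndarray:
    """Apply the extractor to every frame, preserving row order."""
    rows = []
    for i, image in enumerate(images):
        try:
            rows.append(np.asarray(extractor(image), dtype=np.float64))
        except (OSError, FileNotFoundError) as exc:
            raise OSError(f"frame {i} ({image!r}): {exc}") from exc
    if not rows:
        return np.empty((0, extractor.output_dim))
    return np.vstack(rows)


@dataclass
class FeatureTransform:
    """Fitted zero-variance mask + optional PCA basis + min-max bounds.

    ``pca_basis`` rows are orthonormal principal directions ordered by
    non-increasing explained variance; ``n_pc is None`` means no PCA
    (masked raw features, the "all retained features" baseline).
    """

    variance_mask: np.ndarray  # bool, over raw input columns
    n_pc: int | None
    pca_mean: np.ndarray | None
    pca_basis: np.ndarray | None  # (n_pc, n_retained)
    explained_variance: np.ndarray | None
    minmax_lo: np.ndarray
    minmax_hi: np.ndarray

    @property
    def n_raw(self) -> int:
        return int(self.variance_mask.size)

    @property
    def output_dim(self) -> int:
        return int(self.minmax_lo.size)

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        """Transform new rows with the fitted parameters (no clipping)."""
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[1] != self.n_raw:
            raise ValueError(
                f"expected {self.n_raw} raw columns, got shape {matrix.shape}"
            )
        x = matrix[:, self.variance_mask]
        if self.n_pc is not None:
            x = (x - self.pca_mean) @ self.pca_basis.T
        span = self.minmax_hi - self.minmax_lo
        safe = np.where(span > 0, span, 1.0)
        out = (x - self.minmax_lo) / safe
        out[:, span == 0] = 0.0
        return out

    # -- serialization: JSON header + npz array container ------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = {"n_pc": self.n_pc, "n_raw": self.n_raw, "output_dim": self.output_dim}
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        arrays = {
            "variance_mask": self.variance_mask,
            "minmax_lo": self.minmax_lo,
            "minmax_hi": self.minmax_hi,
        }
        if self.n_pc is not None:
            arrays.update(
                pca_mean=self.pca_mean,
                pca_basis=self.pca_basis,
                explained_variance=self.explained_variance,
            )
        np.savez(path.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTransform":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        return cls(
            variance_mask=arrays["variance_mask"],
            n_pc=header["n_pc"],
            pca_mean=arrays.get("pca_mean"),
            pca_basis=arrays.get("pca_basis"),
            explained_variance=arrays.get("explained_variance"),
            minmax_lo=arrays["minmax_lo"],
            minmax_hi=arrays["minmax_hi"],
        )


def fit_transform_pipeline(
    matrix: np.ndarray, n_pc: int | None = None
) -> tuple[FeatureTransform, np.ndarray]:
    """Fit mask -> (PCA) -> min-max on a feature matrix and transform it.

    Parameters
    ----------
    matrix
        Raw (n_frames, n_raw_features) matrix, all pens stacked.
    n_pc
        Number of leading principal components to retain, or ``None``
        for the no-PCA baseline.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    mask = matrix.min(axis=0) != matrix.max(axis=0)
    x = matrix[:, mask]
    if n_pc is not None:
        if n_pc < 1 or n_pc > x.shape[1]:
            raise ValueError(
                f"n_pc={n_pc} outside [1, {x.shape[1]}] retained columns"
            )
        pca = PCA(n_components=n_pc, random_state=0)
        scores = pca.fit_transform(x)
        transform_core = (pca.mean_, pca.components_, pca.explained_variance_)
        x = scores
    else:
        transform_core = (None, None, None)
    lo, hi = x.min(axis=0), x.max(axis=0)
    transform = FeatureTransform(
        variance_mask=mask,
        n_pc=n_pc,
        pca_mean=transform_core[0],
        pca_basis=transform_core[1],
        explained_variance=transform_core[2],
        minmax_lo=lo,
        minmax_hi=hi,
    )
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (x - lo) / safe
    out[:, span == 0] = 0.0
    return transform, out


def apply_transform(transform: FeatureTransform, matrix: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`FeatureTransform.apply`."""
    return transform.apply(matrix)
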