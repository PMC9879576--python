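"""Windowing feature rows into labelled sub-sequences.

Each pen's retained (non-obstructed) frames are divided, in
chronological order, into contiguous non-overlapping windows of
``n_obs`` frames (10, 20 or 30 in the reference grid); a trailing
remainder shorter than ``n_obs`` is discarded.  A window is labelled
positive iff at least one member frame shows biting; its behaviour
category is the highest-priority category present among member frames
(tail_biting > negative_social > nursing > no_event).  Windows never
span pens, and window boundaries ignore event boundaries: an event
split across two windows yields two positive windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from pentail.data_io import CATEGORIES, FrameTable

_PRIORITY = {cat: i for i, cat in enumerate(CATEGORIES)}


@dataclass
class SequenceSet:
    """Windowed sequences: ``x`` is (n_sequences, n_obs, n_dims)."""

    x: np.ndarray
    labels: np.ndarray        # int8, 1 = contains biting
    categories: np.ndarray    # object, one of CATEGORIES
    pen_ids: np.ndarray       # object
    window_start: np.ndarray  # int64, start offset in the pen's retained order

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("labels", "categories", "pen_ids", "window_start"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match x")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_obs(self) -> int:
        return self.x.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, index: np.ndarray) -> "SequenceSet":
        return SequenceSet(
            self.x[index],
            self.labels[index],
            self.categories[index],
            self.pen_ids[index],
            self.window_start[index],
        )

    def for_pens(self, pens: Iterable[str]) -> "SequenceSet":
        pens = {str(p) for p in pens}
        mask = np.array([p in pens for p in self.pen_ids])
        return self.subset(mask)

    @property
    def pens(self) -> list[str]:
        return sorted(set(self.pen_ids))


def categorize_sequence(member_categories: Sequence[str]) -> str:
    """Highest-priority behaviour category present among member frames."""
    return min(member_categories, key=_PRIORITY.__getitem__)


def build_sequences(
    table: FrameTable,
    features: dict[str, np.ndarray],
    n_obs: int,
    stride: int | None = None,
) -> SequenceSet:
    """Window per-pen feature rows into a labelled :class:`SequenceSet`.

    ``features[pen]`` must be row-aligned with the pen's retained frames
    (or with all its frames, in which case excluded rows are dropped
    here).  ``stride`` defaults to ``n_obs`` (non-overlapping windows);
    other strides exist for experimentation only.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    stride = n_obs if stride is None else int(stride)
    if stride < 1:
        raise ValueError("stride must be >= 1")

    xs, labels, cats, pens, starts = [], [], [], [], []
    for pen_id in table.pens:
        full = table.pen(pen_id, include_excluded=True)
        retained = full[~full["excluded"]].reset_index(drop=True)
        mat = np.asarray(features[pen_id])
        if len(mat) == len(full):
            mat = mat[~full["excluded"].to_numpy()]
        elif len(mat) != len(retained):
            raise ValueError(
                f"pen {pen_id}: {len(mat)} feature rows vs "
                f"{len(retained)} retained / {len(full)} total frames"
            )
        biting = retained["biting"].to_numpy()
        category = retained["category"].to_numpy()
        for start in range(0, len(retained) - n_obs + 1, stride):
            sl = slice(start, start + n_obs)
            xs.append(mat[sl])
            labels.append(int(biting[sl].any()))
            cats.append(categorize_sequence(category[sl]))
            pens.append(pen_id)
            starts.append(start)

    if not xs:
        import warnings

        warnings.warn(f"no pen has {n_obs} retained frames; empty SequenceSet")
        d = next(iter(features.values())).shape[1] if features else 0
        return SequenceSet(
            np.empty((0, n_obs, d), dtype=np.float32),
            np.empty(0, dtype=np.int8),
            np.empty(0, dtype=object),
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
        )
    return SequenceSet(
        np.stack(xs).astype(np.float32),
        np.array(labels, dtype=np.int8),
        np.array(cats, dtype=object),
        np.array(pens, dtype=object),
        np.array(starts, dtype=np.int64),
    )


def to_sequence_image(sequence: np.ndarray) -> np.ndarray:
    """View an (n_obs, n_dims) sequence as a 1-channel image tensor.

    The matrix is used verbatim — height n_obs, width n_dims, no
    resizing or quantization — so the CNN convolves the scaled feature
    grid directly.
    """
    sequence = np.asarray(sequence)
    if sequence.ndim != 2:
        raise ValueError("expected a 2-D (n_obs, n_dims) sequence")
    return sequence[:, :, None]


def export_png16(sequence: np.ndarray, path) -> None:
    """Write a [0,1]-scaled sequence as a 16-bit grayscale PNG (inspection only)."""
    from PIL import Image

    arr = np.clip(np.asarray(sequence, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(path)


def load_png16(path) -> np.ndarray:
    """Read back a PNG written by :func:`export_png16` as floats in [0,1]."""
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img, dtype=np.float64)
    return arr / 65535.0
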