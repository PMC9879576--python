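"""Frame-label manifests, feature containers and per-pen dataset summaries.

A *manifest* is a CSV with one row per extracted video frame: the pen it
came from, its 0-based index in the 10-fps frame stream, whether a
tail-biting event is visible, the behaviour category, an optional image
path and an obstruction flag.  Feature containers hold one
``n_frames x n_features`` matrix per pen, row-aligned with the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pentail.errors import IntegrityError, ManifestFormatError

#: Behaviour categories, in label-priority order (highest first).
CATEGORIES = ("tail_biting", "negative_social", "nursing", "no_event")

REQUIRED_COLUMNS = ("pen_id", "frame_index", "biting", "category")
OPTIONAL_COLUMNS = ("image_path", "excluded")


@dataclass
class FrameTable:
    """Per-frame records for a set of pens, sorted by (pen, frame index).

    Parameters
    ----------
    frames
        DataFrame with columns ``pen_id`` (str), ``frame_index`` (int),
        ``biting`` (bool), ``category`` (one of :data:`CATEGORIES`),
        ``image_path`` (str or None) and ``excluded`` (bool).
    fps
        Frame rate of the stream the indices refer to (10 by default).
    """

    frames: pd.DataFrame
    fps: float = 10.0

    def __post_init__(self) -> None:
        df = self.frames.copy()
        if "image_path" not in df.columns:
            df["image_path"] = None
        df["image_path"] = df["image_path"].astype(object).where(
            df["image_path"].notna(), None
        )
        if "excluded" not in df.columns:
            df["excluded"] = False
        df["pen_id"] = df["pen_id"].astype(str)
        df["frame_index"] = df["frame_index"].astype(np.int64)
        df["biting"] = df["biting"].astype(bool)
        df["excluded"] = df["excluded"].astype(bool)
        df = df.sort_values(["pen_id", "frame_index"], kind="stable").reset_index(drop=True)
        self.frames = df
        self.validate()

    def validate(self) -> None:
        df = self.frames
        bad = ~df["category"].isin(CATEGORIES)
        if bad.any():
            raise IntegrityError(
                f"unknown categories: {sorted(df.loc[bad, 'category'].unique())}"
            )
        if df.duplicated(subset=["pen_id", "frame_index"]).any():
            dup = df[df.duplicated(subset=["pen_id", "frame_index"], keep=False)]
            raise IntegrityError(
                f"duplicate (pen_id, frame_index) pairs, e.g. "
                f"{dup.iloc[0]['pen_id']}/{dup.iloc[0]['frame_index']}"
            )
        mismatch = df["biting"] != (df["category"] == "tail_biting")
        if mismatch.any():
            row = df[mismatch].iloc[0]
            raise IntegrityError(
                "biting flag and category disagree at pen "
                f"{row['pen_id']} frame {row['frame_index']}: "
                f"biting={row['biting']} category={row['category']}"
            )

    @property
    def pens(self) -> list[str]:
        return sorted(self.frames["pen_id"].unique())

    def pen(self, pen_id: str, *, include_excluded: bool = False) -> pd.DataFrame:
        """Rows for one pen in chronological order."""
        df = self.frames[self.frames["pen_id"] == str(pen_id)]
        if not include_excluded:
            df = df[~df["excluded"]]
        return df.reset_index(drop=True)

    def retained(self) -> pd.DataFrame:
        """All non-excluded rows; the basis for every downstream stage."""
        return self.frames[~self.frames["excluded"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frames)


def load_manifest(path: str | Path, fps: float = 10.0) -> FrameTable:
    """Read a manifest CSV into a validated :class:`FrameTable`.

    Raises
    ------
    ManifestFormatError
        If a required column is missing or booleans are unparseable.
    IntegrityError
        On duplicate (pen, frame) pairs or biting/category mismatches.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"pen_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"{path}: missing required column(s) {missing}")
    for col in ("biting", "excluded"):
        if col in df.columns and df[col].dtype == object:
            parsed = df[col].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
            if parsed.isna().any():
                raise ManifestFormatError(f"{path}: column {col!r} has non-boolean values")
            df[col] = parsed
    return FrameTable(df, fps=fps)


def save_manifest(table: FrameTable, path: str | Path) -> None:
    df = table.frames.copy()
    df["biting"] = df["biting"].map({True: "true", False: "false"})
    df["excluded"] = df["excluded"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def downsample_indices(source_fps: float, target_fps: float, n_source_frames: int) -> np.ndarray:
    """Source-frame indices realising a lower target frame rate.

    Nearest-index sampling: index ``round(k * source_fps / target_fps)``
    for k = 0, 1, 2, ... while the index stays below ``n_source_frames``.
    The result is strictly increasing.
    """
    if source_fps <= 0 or target_fps <= 0:
        raise ValueError("frame rates must be positive")
    if target_fps > source_fps:
        raise ValueError("target_fps must not exceed source_fps")
    step = source_fps / target_fps
    n_out = int(np.floor((n_source_frames - 1) / step)) + 1 if n_source_frames > 0 else 0
    idx = np.round(np.arange(n_out) * step).astype(np.int64)
    idx = idx[idx < n_source_frames]
    # rounding can only repeat when step < 1, excluded by the precondition
    return idx


def count_events(biting: np.ndarray) -> int:
    """Number of maximal runs of consecutive biting frames (0->1 transitions)."""
    b = np.asarray(biting, dtype=bool).astype(np.int8)
    if b.size == 0:
        return 0
    return int(b[0] + np.sum(np.diff(b) == 1))


def summarize(table: FrameTable) -> pd.DataFrame:
    """Per-pen dataset accounting, plus a totals row.

    Columns: non-biting / biting image counts, unique biting events
    (maximal runs of consecutive biting frames within a pen) and excluded
    frames.  Excluded frames do not contribute to any count but their own.
    """
    rows = []
    for pen_id in table.pens:
        df = table.pen(pen_id)
        n_excl = int(table.pen(pen_id, include_excluded=True)["excluded"].sum())
        biting = df["biting"].to_numpy()
        rows.append(
            {
                "pen_id": pen_id,
                "n_non_biting": int((~biting).sum()),
                "n_biting": int(biting.sum()),
                "n_events": count_events(biting),
                "n_excluded": n_excl,
            }
        )
    out = pd.DataFrame(
        rows, columns=["pen_id", "n_non_biting", "n_biting", "n_events", "n_excluded"]
    )
    if len(out):
        total = out.drop(columns="pen_id").sum()
        total["pen_id"] = "total"
        out = pd.concat([out, total.to_frame().T], ignore_index=True)
        for c in ("n_non_biting", "n_biting", "n_events", "n_excluded"):
            out[c] = out[c].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Feature containers: one .npy matrix per pen + one JSON sidecar per pen.

def save_features(features: dict[str, np.ndarray], out_dir: str | Path) -> None:
    """Write per-pen feature matrices as ``pen_<id>.npy`` with JSON sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pen_id, mat in features.items():
        mat = np.asarray(mat)
        np.save(out_dir / f"pen_{pen_id}.npy", mat)
        sidecar = {
            "pen_id": pen_id,
            "n_frames": int(mat.shape[0]),
            "n_features": int(mat.shape[1]),
            "dtype": str(mat.dtype),
        }
        (out_dir / f"pen_{pen_id}.json").write_text(json.dumps(sidecar, indent=1))


def load_features(in_dir: str | Path) -> dict[str, np.ndarray]:
    """Read feature containers written by :func:`save_features`."""
    in_dir = Path(in_dir)
    out: dict[str, np.ndarray] = {}
    for sidecar in sorted(in_dir.glob("pen_*.json")):
        meta = json.loads(sidecar.read_text())
        mat = np.load(sidecar.with_suffix(".npy"))
        if mat.shape != (meta["n_frames"], meta["n_features"]):
            raise IntegrityError(
                f"{sidecar.name}: matrix shape {mat.shape} disagrees with sidecar"
            )
        out[meta["pen_id"]] = mat
    return out
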