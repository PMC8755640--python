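"""ROI extraction, block decomposition, and per-position training matrices.

A mass region of interest (ROI) is a square grayscale crop around an annotated
lesion centroid.  Each ROI is divided into a regular grid of ``m x n`` pixel
blocks; stacking the block at grid position ``j`` across all training ROIs
gives the per-position training matrix from which the block dictionary for
position ``j`` is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BENIGN = -1
MALIGNANT = +1

#: Vectorization convention, single-sourced: pixels within a block are read in
#: column-major (Fortran) order; blocks are ordered row-major over the grid.
BLOCK_PIXEL_ORDER = "F"

_LABEL_ALIASES = {
    "benign": BENIGN,
    "malignant": MALIGNANT,
    "-1": BENIGN,
    "1": MALIGNANT,
    "+1": MALIGNANT,
}


def encode_label(label) -> int:
    """Map a textual or numeric class label to the canonical {-1, +1} codes."""
    if isinstance(label, str):
        key = label.strip().lower()
        if key in _LABEL_ALIASES:
            return _LABEL_ALIASES[key]
        raise ValueError(f"unknown class label {label!r}")
    value = int(label)
    if value not in (BENIGN, MALIGNANT):
        raise ValueError(f"numeric labels must be -1 (benign) or +1 (malignant), got {label!r}")
    return value


@dataclass(frozen=True)
class LabeledROI:
    """A square grayscale intensity grid with a binary class label.

    ``pixels`` are floats in [0, 1]; ``label`` is -1 for benign and +1 for
    malignant (malignant is the positive class throughout).
    """

    pixels: np.ndarray
    label: int
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"ROI pixels must be square 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("ROI is empty")
        if np.isnan(px).any():
            raise ValueError("ROI contains NaN")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("ROI intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "label", encode_label(self.label))

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class MassAnnotation:
    """One annotated mass: image path, centroid (x=column, y=row), radius, label."""

    image_path: str
    centroid_xy: tuple[float, float]
    radius_px: float
    label: int

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        object.__setattr__(self, "label", encode_label(self.label))


@dataclass(frozen=True)
class BlockGrid:
    """The spatially ordered, vectorized blocks of one ROI."""

    blocks: np.ndarray  # (NB, m*n), rows in the fixed lexicographic order
    block_shape: tuple[int, int]
    grid_shape: tuple[int, int]

    def __post_init__(self):
        blocks = np.asarray(self.blocks, dtype=float)
        m, n = self.block_shape
        rows, cols = self.grid_shape
        if blocks.ndim != 2 or blocks.shape != (rows * cols, m * n):
            raise ValueError(
                f"blocks shape {blocks.shape} inconsistent with grid {self.grid_shape} "
                f"and block {self.block_shape}"
            )
        object.__setattr__(self, "blocks", blocks)

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]


@dataclass(frozen=True)
class BlockTrainingMatrix:
    """Blocks from one grid position across all training ROIs, as columns."""

    block_index: int
    columns: np.ndarray  # (m*n, s)
    column_labels: np.ndarray  # (s,)

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        labels = np.asarray(self.column_labels, dtype=int)
        if cols.ndim != 2:
            raise ValueError("columns must be a 2-D matrix")
        if labels.shape != (cols.shape[1],):
            raise ValueError("column_labels must align with columns")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "column_labels", labels)


class RejectedROI:
    """Sentinel returned when a mass fails the minimum-size criterion."""

    def __init__(self, reason: str):
        self.reason = reason

    def __repr__(self):  # pragma: no cover
        return f"RejectedROI({self.reason!r})"


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale raster (PNG/PGM/TIFF; DICOM if pydicom is available).

    Intensities are rescaled to [0, 1] regardless of the on-disk bit depth.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover
            raise ImportError("DICOM input requires pydicom") from exc
        arr = pydicom.dcmread(str(path)).pixel_array.astype(float)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path).astype(float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def read_annotations(csv_path: str | Path) -> list[MassAnnotation]:
    """Read the annotation table: image_path,centroid_x,centroid_y,radius_px,label."""
    df = pd.read_csv(csv_path)
    required = {"image_path", "centroid_x", "centroid_y", "radius_px", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return [
        MassAnnotation(
            image_path=str(r.image_path),
            centroid_xy=(float(r.centroid_x), float(r.centroid_y)),
            radius_px=float(r.radius_px),
            label=r.label,
        )
        for r in df.itertuples()
    ]


def _mirror_crop(image: np.ndarray, cy: int, cx: int, side: int) -> np.ndarray:
    """Center crop of given side; mirror-pad when the window overruns a border."""
    half_lo = side // 2
    top, left = cy - half_lo, cx - half_lo
    bottom, right = top + side, left + side
    pad_top = max(0, -top)
    pad_left = max(0, -left)
    pad_bottom = max(0, bottom - image.shape[0])
    pad_right = max(0, right - image.shape[1])
    if pad_top or pad_left or pad_bottom or pad_right:
        image = np.pad(image, ((pad_top, pad_bottom), (pad_left, pad_right)), mode="reflect")
        top += pad_top
        left += pad_left
    return image[top : top + side, left : left + side]


def extract_roi(
    image: np.ndarray,
    ann: MassAnnotation,
    policy: str = "min_size_crop",
    min_side: int = 64,
    target_side: int = 128,
    source_id: str | None = None,
) -> LabeledROI | RejectedROI:
    """Extract the square mass ROI from a full image, per the selection policy.

    ``min_size_crop``: the mass bounding square has side ``2 * radius_px``; if
    that is smaller than ``min_side`` the mass is rejected, otherwise a
    ``min_side`` center crop about the centroid is returned so the blocks cover
    the mass interior.  ``resample``: the full bounding square (mass plus
    surrounding background) is cropped and bilinearly resampled to
    ``target_side``.
    """
    image = np.asarray(image, dtype=float)
    x, y = ann.centroid_xy
    if not (0 <= x < image.shape[1] and 0 <= y < image.shape[0]):
        raise ValueError(f"annotation centroid {ann.centroid_xy} outside image {image.shape}")
    cy, cx = int(round(y)), int(round(x))
    sid = source_id if source_id is not None else ann.image_path

    if policy == "min_size_crop":
        if min_side <= 0:
            raise ValueError("min_side must be positive")
        if 2 * ann.radius_px < min_side:
            return RejectedROI(
                f"bounding square {2 * ann.radius_px:g} px < minimum ROI size {min_side}"
            )
        crop = _mirror_crop(image, cy, cx, min_side)
    elif policy == "resample":
        if target_side <= 0:
            raise ValueError("target_side must be positive")
        side = max(2, int(round(2 * ann.radius_px)))
        crop = _mirror_crop(image, cy, cx, side)
        from skimage.transform import resize

        crop = resize(crop, (target_side, target_side), order=1, mode="reflect",
                      anti_aliasing=side > target_side)
    else:
        raise ValueError(f"unknown ROI policy {policy!r}")

    crop = np.clip(crop, 0.0, 1.0)
    return LabeledROI(pixels=crop, label=ann.label, source_id=sid)


def decompose(roi: LabeledROI | np.ndarray, block_shape: tuple[int, int]) -> BlockGrid:
    """Divide a square ROI into m x n blocks in fixed lexicographic order.

    Blocks traverse the grid row-major; pixels within each block are
    vectorized column-major.  Raises if the ROI side is not divisible by the
    block dimensions (no implicit padding).
    """
    pixels = roi.pixels if isinstance(roi, LabeledROI) else np.asarray(roi, dtype=float)
    side = pixels.shape[0]
    m, n = block_shape
    if m <= 0 or n <= 0:
        raise ValueError("block dimensions must be positive")
    if side % m or side % n:
        raise ValueError(f"ROI side {side} not divisible by block shape {block_shape}")
    rows, cols = side // m, side // n
    # (rows, m, cols, n) -> (rows, cols, m, n) -> vectorize each block
    tiles = pixels.reshape(rows, m, cols, n).transpose(0, 2, 1, 3)
    blocks = tiles.reshape(rows * cols, m, n)
    blocks = blocks.transpose(0, 2, 1).reshape(rows * cols, m * n)  # column-major in-block
    return BlockGrid(blocks=blocks, block_shape=(m, n), grid_shape=(rows, cols))


def reassemble(grid: BlockGrid) -> np.ndarray:
    """Exact inverse of :func:`decompose`; returns the ROI pixel array."""
    m, n = grid.block_shape
    rows, cols = grid.grid_shape
    tiles = grid.blocks.reshape(rows * cols, n, m).transpose(0, 2, 1)  # undo column-major
    tiles = tiles.reshape(rows, cols, m, n).transpose(0, 2, 1, 3)
    return tiles.reshape(rows * m, cols * n)


def build_block_training_matrices(
    rois: Sequence[LabeledROI],
    block_shape: tuple[int, int],
    require_both_classes: bool = True,
) -> list[BlockTrainingMatrix]:
    """Stack block ``j`` of every training ROI into the position-``j`` matrix."""
    if not rois:
        raise ValueError("empty ROI list")
    sides = {r.side_px for r in rois}
    if len(sides) != 1:
        raise ValueError(f"mixed ROI sizes {sorted(sides)}")
    labels = np.array([r.label for r in rois], dtype=int)
    if require_both_classes and len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    grids = [decompose(r, block_shape) for r in rois]
    n_blocks = grids[0].n_blocks
    out = []
    for j in range(n_blocks):
        cols = np.stack([g.blocks[j] for g in grids], axis=1)
        out.append(BlockTrainingMatrix(block_index=j, columns=cols, column_labels=labels))
    return out
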