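"""Synthetic two-class mass ROI generator.

Each ROI is a soft-edged bright disc (the "mass") on a mid-gray background,
modulated by an oriented sinusoidal texture whose spatial frequency and
orientation are class-conditional, plus i.i.d. Gaussian intensity noise.  The
texture is block-stationary, so the class structure is visible to every block
dictionary; the phase is randomized per ROI so training sets are not trivially
collinear.  The default class specs differ only in texture frequency (4 vs 14
cycles per ROI side), the axis along which class separation is controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .block_model import BENIGN, MALIGNANT, LabeledROI

_BACKGROUND = 0.35
_TEXTURE_AMPLITUDE = 0.18


@dataclass(frozen=True)
class ClassSpec:
    """Class-conditional appearance parameters."""

    texture_frequency: float  # cycles per ROI side
    orientation: float = 0.0  # radians
    blob_contrast: float = 0.3  # added intensity at the disc center, in [0, 1]
    blob_radius_frac: float = 0.6  # disc radius as a fraction of side/2

    def __post_init__(self):
        if not 0.0 <= self.blob_contrast <= 1.0:
            raise ValueError("blob_contrast must lie in [0, 1]")
        if not 0.0 < self.blob_radius_frac < 1.0:
            raise ValueError("blob_radius_frac must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    side_px: int = 64
    class_specs: Mapping[int, ClassSpec] = field(
        default_factory=lambda: {
            BENIGN: ClassSpec(texture_frequency=4.0),
            MALIGNANT: ClassSpec(texture_frequency=14.0),
        }
    )
    noise_sigma: float = 0.05
    n_per_class: int | Mapping[int, int] = 36
    seed: int = 0

    def __post_init__(self):
        side = self.side_px
        if side < 32 or side & (side - 1):
            raise ValueError("side_px must be a power of two >= 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        specs = dict(self.class_specs)
        if set(specs) != {BENIGN, MALIGNANT}:
            raise ValueError("class_specs must cover exactly the benign and malignant classes")
        if specs[BENIGN] == specs[MALIGNANT]:
            raise ValueError("class specs must differ in at least one parameter")
        object.__setattr__(self, "class_specs", specs)

    def count_for(self, c: int) -> int:
        if isinstance(self.n_per_class, Mapping):
            return int(self.n_per_class[c])
        return int(self.n_per_class)


def generate_roi(c: int, cfg: SyntheticConfig, rng: np.random.Generator,
                 index: int = 0) -> LabeledROI:
    """Render one labeled ROI of class ``c`` (deterministic given the rng state)."""
    if c not in cfg.class_specs:
        raise ValueError(f"unknown class {c}")
    spec = cfg.class_specs[c]
    side = cfg.side_px
    coords = (np.arange(side) + 0.5) / side - 0.5  # in [-0.5, 0.5)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")

    # soft-edged disc: cosine rolloff over the outer 20% of the disc radius
    r = np.hypot(xx, yy) / 0.5  # radial coordinate in units of side/2
    rr = spec.blob_radius_frac
    edge = 0.2 * rr
    disc = np.clip((rr - r) / edge, 0.0, 1.0)
    disc = 0.5 - 0.5 * np.cos(np.pi * np.clip(disc, 0, 1))

    phase = rng.uniform(0.0, 2.0 * np.pi)
    u = xx * np.cos(spec.orientation) + yy * np.sin(spec.orientation)
    texture = np.sin(2.0 * np.pi * spec.texture_frequency * u + phase)

    img = _BACKGROUND + spec.blob_contrast * disc + _TEXTURE_AMPLITUDE * texture
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    name = "benign" if c == BENIGN else "malignant"
    return LabeledROI(pixels=img, label=c, source_id=f"synthetic-{name}-{index:04d}")


def generate_dataset(cfg: SyntheticConfig) -> list[LabeledROI]:
    """Deterministic labeled dataset: n_per_class ROIs per class, shuffled."""
    rng = np.random.default_rng(cfg.seed)
    rois = []
    for c in (BENIGN, MALIGNANT):
        n = cfg.count_for(c)
        if n < 1:
            raise ValueError("n_per_class must be >= 1")
        rois.extend(generate_roi(c, cfg, rng, index=i) for i in range(n))
    order = rng.permutation(len(rois))
    return [rois[i] for i in order]


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write the dataset as PNGs plus the annotation CSV used by the real
    ingestion path (centroid = image center, radius = disc radius)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for roi in generate_dataset(cfg):
        fname = f"{roi.source_id}.png"
        iio.imwrite(out_dir / fname, (roi.pixels * 255).round().astype(np.uint8))
        spec = cfg.class_specs[roi.label]
        rows.append(
            {
                "image_path": fname,
                "centroid_x": cfg.side_px / 2,
                "centroid_y": cfg.side_px / 2,
                "radius_px": spec.blob_radius_frac * cfg.side_px / 2,
                "label": "benign" if roi.label == BENIGN else "malignant",
            }
        )
    csv_path = out_dir / "annotations.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
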