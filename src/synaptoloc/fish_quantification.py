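"""Per-cell single-molecule FISH particle counting.

Cells are segmented as ROIs from a blurred composite of the nuclear and
mRNA channels; per-channel particle thresholds are calibrated on negative
controls (the smallest threshold at which no control cell shows more than
three particles); mRNA particles are then counted per ROI per probe from
the thresholded channel images.  Multi-plane stacks are handled by running
planes independently and summing counts per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import gaussian
from skimage.measure import label as cc_label

from .puncta_detection import DetectionParams, detect_puncta

__all__ = [
    "CellROI",
    "FishCounts",
    "CalibrationError",
    "segment_cell_rois",
    "calibrate_channel_threshold",
    "count_particles",
]

DEFAULT_MIN_ROI_AREA_PX = 100
MAX_NEGATIVE_PARTICLES_PER_CELL = 3


class CalibrationError(RuntimeError):
    """The negative-control criterion is unreachable on the search grid."""


@dataclass(frozen=True)
class CellROI:
    id: int
    pixels: frozenset[tuple[int, int]] = field(repr=False)
    centroid: tuple[float, float] = (0.0, 0.0)

    @property
    def area_px(self) -> int:
        return len(self.pixels)


@dataclass
class FishCounts:
    """Particle counts per (ROI id, probe name)."""

    counts: dict[tuple[int, str], int] = field(default_factory=dict)

    def add(self, other: "FishCounts") -> "FishCounts":
        merged = dict(self.counts)
        for key, v in other.counts.items():
            merged[key] = merged.get(key, 0) + v
        return FishCounts(merged)

    def per_probe_mean(self, probe: str) -> float:
        vals = [v for (_, p), v in self.counts.items() if p == probe]
        return float(np.mean(vals)) if vals else float("nan")

    def max_per_cell(self, probe: str | None = None) -> int:
        vals = [
            v for (_, p), v in self.counts.items() if probe is None or p == probe
        ]
        return max(vals) if vals else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(roi, probe, v) for (roi, probe), v in sorted(self.counts.items())],
            columns=["roi_id", "probe", "count"],
        )


def segment_cell_rois(
    composite: np.ndarray,
    threshold: float,
    sigma_px: float = 2.0,
    min_area_px: int = DEFAULT_MIN_ROI_AREA_PX,
) -> list[CellROI]:
    """Segment cell ROIs from a blurred composite image.

    Gaussian blur (SD ``sigma_px``), global threshold, 8-connected
    components; components smaller than ``min_area_px`` are discarded as
    debris.  A threshold above the image maximum yields zero ROIs.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    blurred = gaussian(np.asarray(composite, dtype=float), sigma=sigma_px, preserve_range=True)
    mask = blurred >= threshold
    labels = cc_label(mask, connectivity=2)
    rois: list[CellROI] = []
    for lbl in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lbl)
        if rr.size < min_area_px:
            continue
        rois.append(
            CellROI(
                id=len(rois),
                pixels=frozenset(zip(rr.tolist(), cc.tolist())),
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    return rois


def count_particles(
    channel: np.ndarray,
    rois: list[CellROI],
    threshold: float,
    noise_tolerance: float = 0.0,
    probe: str = "",
) -> FishCounts:
    """Count detected particles per ROI in one probe channel.

    Runs puncta detection with ``min_intensity=threshold`` on the whole
    plane; a particle belongs to the ROI containing its maximum, and
    particles whose maxima fall outside every ROI are not counted.
    """
    params = DetectionParams(min_intensity=threshold, noise_tolerance=noise_tolerance)
    puncta = detect_puncta(np.asarray(channel, dtype=float), params)
    roi_of: dict[tuple[int, int], int] = {}
    for roi in rois:
        for px in roi.pixels:
            roi_of[px] = roi.id
    counts = {(roi.id, probe): 0 for roi in rois}
    for p in puncta:
        rid = roi_of.get(p.position)
        if rid is not None:
            counts[(rid, probe)] += 1
    return FishCounts(counts)


def calibrate_channel_threshold(
    negative_images: list[np.ndarray],
    rois_per_image: list[list[CellROI]],
    start: float,
    step: float,
    noise_tolerance: float = 0.0,
    max_particles: int = MAX_NEGATIVE_PARTICLES_PER_CELL,
    max_threshold: float | None = None,
) -> float:
    """Smallest grid threshold with <= ``max_particles`` per negative-control cell.

    Scans ``start + k * step`` upward; per-ROI counts are non-increasing in
    the threshold, so the scan terminates on a bounded grid.  Raises
    :class:`CalibrationError` (naming the worst ROI) if the criterion is
    still unmet at the grid top.
    """
    if not negative_images:
        raise ValueError("need at least one negative-control image")
    if len(negative_images) != len(rois_per_image):
        raise ValueError("negative_images and rois_per_image lengths differ")
    if step <= 0:
        raise ValueError("step must be > 0")
    if max_threshold is None:
        max_threshold = max(float(np.max(img)) for img in negative_images) + step

    threshold = float(start)
    while threshold <= max_threshold:
        worst = (-1, -1, -1)  # count, image index, roi id
        for i, (img, rois) in enumerate(zip(negative_images, rois_per_image)):
            counts = count_particles(img, rois, threshold, noise_tolerance)
            for (rid, _), v in counts.counts.items():
                if v > worst[0]:
                    worst = (v, i, rid)
        if worst[0] <= max_particles:
            return threshold
        threshold += step
    raise CalibrationError(
        f"criterion of <= {max_particles} particles/cell unreachable up to threshold "
        f"{max_threshold:g}; worst ROI {worst[2]} in negative image {worst[1]} "
        f"had {worst[0]} particles"
    )
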