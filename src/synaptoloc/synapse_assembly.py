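"""Pairing pre- and postsynaptic puncta into synapses and classifying inputs.

A synapse is an overlapping pair of a presynaptic (bassoon) and a
postsynaptic (homer / PSD95 / SAP102) punctum: their regions, dilated by the
configured disk radius, must share at least one pixel.  Each postsynaptic
punctum yields at most one synapse, paired to the overlapping presynaptic
punctum with the shortest maxima-to-maxima distance; the number of
overlapping presynaptic regions is kept as a quality metric (multi-overlap
synapses are rare when detection parameters are sane).  A synapse's input
class comes from its presynaptic punctum overlapping thresholded VGLUT1
(corticothalamic) or VGLUT2 (sensory) signal by at least one pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .puncta_detection import DetectionParams, Punctum, PunctaSet, dilate_region, threshold_mask

__all__ = [
    "Synapse",
    "SynapseTable",
    "maxima_distance",
    "pair_synapses",
    "classify_inputs",
    "synapse_rates",
]


@dataclass(frozen=True)
class Synapse:
    id: int
    pre_id: int
    post_id: int
    pre_post_distance_nm: float
    input_label: str = "unassigned"  # VGLUT1 | VGLUT2 | unassigned
    multi_overlap_count: int = 1


@dataclass
class SynapseTable:
    synapses: list[Synapse]
    n_pre_detected: int
    n_post_detected: int
    pixel_size_nm: float
    pre_marker: str = ""
    post_marker: str = ""

    def __len__(self) -> int:
        return len(self.synapses)

    def __iter__(self):
        return iter(self.synapses)

    def distances_nm(self) -> np.ndarray:
        return np.array([s.pre_post_distance_nm for s in self.synapses])


def maxima_distance(a: Punctum, b: Punctum, pixel_size_nm: float) -> float:
    """Euclidean distance between two puncta maxima, in nm."""
    return math.hypot(a.max_row - b.max_row, a.max_col - b.max_col) * pixel_size_nm


def _dilated(ps: PunctaSet, params: DetectionParams) -> dict[int, frozenset]:
    r = params.dilation_radius_px
    return {p.id: dilate_region(p.region, r, ps.shape) for p in ps}


def _pixel_index(regions: dict[int, frozenset]) -> dict[tuple[int, int], list[int]]:
    index: dict[tuple[int, int], list[int]] = {}
    for pid, region in regions.items():
        for px in region:
            index.setdefault(px, []).append(pid)
    return index


def pair_synapses(
    pre: PunctaSet, post: PunctaSet, params: DetectionParams
) -> SynapseTable:
    """Pair each postsynaptic punctum to its nearest overlapping presynaptic punctum.

    Overlap is tested between regions dilated by ``params.dilation_radius_px``.
    Distance ties are broken toward the lower presynaptic id.  A presynaptic
    punctum may serve several synapses.
    """
    if pre.shape != post.shape:
        raise ValueError(f"image shapes differ: pre {pre.shape} vs post {post.shape}")
    pre_regions = _dilated(pre, params)
    post_regions = _dilated(post, params)
    pre_index = _pixel_index(pre_regions)
    pre_by_id = {p.id: p for p in pre}

    synapses: list[Synapse] = []
    for post_p in sorted(post, key=lambda p: p.id):
        overlapping: set[int] = set()
        for px in post_regions[post_p.id]:
            overlapping.update(pre_index.get(px, ()))
        if not overlapping:
            continue
        best = min(
            overlapping,
            key=lambda pid: (maxima_distance(pre_by_id[pid], post_p, post.pixel_size_nm), pid),
        )
        synapses.append(
            Synapse(
                id=len(synapses),
                pre_id=best,
                post_id=post_p.id,
                pre_post_distance_nm=maxima_distance(pre_by_id[best], post_p, post.pixel_size_nm),
                multi_overlap_count=len(overlapping),
            )
        )
    return SynapseTable(
        synapses=synapses,
        n_pre_detected=len(pre),
        n_post_detected=len(post),
        pixel_size_nm=post.pixel_size_nm,
        pre_marker=pre.channel,
        post_marker=post.channel,
    )


def classify_inputs(
    table: SynapseTable,
    pre: PunctaSet,
    vglut1_image: np.ndarray | None,
    vglut2_image: np.ndarray | None,
    vglut_thresholds: dict[str, float],
    params: DetectionParams,
) -> SynapseTable:
    """Label synapses VGLUT1 / VGLUT2 by presynaptic overlap with thresholded VGLUT signal.

    A synapse is VGLUT-positive when its paired presynaptic punctum's
    dilated region shares at least one pixel with the suprathreshold VGLUT
    mask.  If both VGLUT channels overlap, the larger overlapping pixel
    count wins; exact ties stay unassigned.
    """
    masks: dict[str, np.ndarray] = {}
    for name, image in (("vglut1", vglut1_image), ("vglut2", vglut2_image)):
        if image is None:
            continue
        if name not in vglut_thresholds:
            raise ValueError(f"missing threshold for provided channel {name!r}")
        if image.shape != pre.shape:
            raise ValueError(f"{name} image shape {image.shape} != {pre.shape}")
        masks[name] = threshold_mask(image, vglut_thresholds[name])

    pre_regions = _dilated(pre, params)
    labeled: list[Synapse] = []
    for syn in table:
        region = pre_regions[syn.pre_id]
        counts = {
            name: sum(1 for (r, c) in region if mask[r, c]) for name, mask in masks.items()
        }
        n1 = counts.get("vglut1", 0)
        n2 = counts.get("vglut2", 0)
        if n1 == 0 and n2 == 0:
            label = "unassigned"
        elif n1 > n2:
            label = "VGLUT1"
        elif n2 > n1:
            label = "VGLUT2"
        else:
            label = "unassigned"
        labeled.append(replace(syn, input_label=label))
    return SynapseTable(
        synapses=labeled,
        n_pre_detected=table.n_pre_detected,
        n_post_detected=table.n_post_detected,
        pixel_size_nm=table.pixel_size_nm,
        pre_marker=table.pre_marker,
        post_marker=table.post_marker,
    )


def synapse_rates(table: SynapseTable) -> dict[str, float | None]:
    """Summary rates of the synapse table.

    Percentages are reported against the detected punctum totals (the
    fraction of presynaptic / postsynaptic puncta taking part in a synapse),
    plus the share of synapses overlapping more than one presynaptic
    punctum and the VGLUT label shares.  A rate with a zero denominator is
    ``None`` (undefined), never 0.
    """
    n_syn = len(table)
    distinct_pre = len({s.pre_id for s in table})

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "pct_pre_synaptic": pct(distinct_pre, table.n_pre_detected),
        "pct_post_synaptic": pct(n_syn, table.n_post_detected),
        "pct_multi_overlap": pct(sum(1 for s in table if s.multi_overlap_count > 1), n_syn),
        "pct_vglut1": pct(sum(1 for s in table if s.input_label == "VGLUT1"), n_syn),
        "pct_vglut2": pct(sum(1 for s in table if s.input_label == "VGLUT2"), n_syn),
    }
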