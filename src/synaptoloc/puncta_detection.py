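"""Fluorescent puncta detection by local-maxima search with noise tolerance.

A punctum is a diffraction-limited fluorescent spot (a protein cluster or a
single mRNA molecule).  Detection follows find-maxima semantics: a local
maximum counts as a separate punctum only if its peak lies within the
configured ``[min_intensity, max_intensity]`` window and its prominence over
the highest saddle connecting it to any stronger maximum is at least the
noise tolerance.  Each punctum carries a pixel region (an 8-connected flood
from its maximum down to a per-punctum cut level) which downstream modules
dilate for overlap-based colocalization tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "DetectionParams",
    "Punctum",
    "PunctaSet",
    "detect_puncta",
    "punctum_region",
    "dilate_region",
    "disk_offsets",
    "threshold_mask",
]

Pixel = tuple[int, int]

# 8-connected neighborhood offsets
_NEIGHBORS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class DetectionParams:
    """Per-channel detection parameters, in detector (intensity) units.

    Parameters are held constant for one immunogen across all images from a
    single imaging session.

    Attributes
    ----------
    min_intensity:
        Minimum peak intensity for a punctum; also the floor of its region.
    max_intensity:
        Maximum peak intensity (rejects saturated objects); unbounded by
        default.
    noise_tolerance:
        Minimum prominence of a maximum over the highest saddle to any
        stronger maximum, and the depth of the region flood below the peak.
    dilation_radius_px:
        Euclidean disk radius used when regions are dilated for overlap
        tests (2 px by default).
    """

    min_intensity: float
    max_intensity: float = math.inf
    noise_tolerance: float = 0.0
    dilation_radius_px: int = 2

    def __post_init__(self) -> None:
        if not self.min_intensity <= self.max_intensity:
            raise ValueError("min_intensity must be <= max_intensity")
        if self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be >= 0")


@dataclass(frozen=True)
class Punctum:
    """A detected spot: maximum position, peak intensity and pixel region."""

    id: int
    channel: str
    max_row: int
    max_col: int
    peak: float
    region: frozenset[Pixel] = field(repr=False)

    @property
    def position(self) -> Pixel:
        return (self.max_row, self.max_col)

    @property
    def area_px(self) -> int:
        return len(self.region)


@dataclass
class PunctaSet:
    """All puncta detected in one channel of one field of view."""

    channel: str
    puncta: list[Punctum]
    shape: tuple[int, int]
    pixel_size_nm: float

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    def by_id(self, punctum_id: int) -> Punctum:
        return self._index[punctum_id]

    @property
    def _index(self) -> dict[int, Punctum]:
        return {p.id: p for p in self.puncta}

    def positions_nm(self) -> np.ndarray:
        """Maxima positions as (x, y) in nm (x = col, y = row)."""
        if not self.puncta:
            return np.empty((0, 2))
        rc = np.array([[p.max_col, p.max_row] for p in self.puncta], dtype=float)
        return rc * self.pixel_size_nm


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    return image


def _find_maxima(image: np.ndarray, params: DetectionParams) -> list[tuple[float, int, int]]:
    """Accepted maxima as (peak, row, col), by the prominence criterion.

    Runs a descending union-find sweep (persistence pairing).  When two
    components meet at a saddle, the weaker peak survives as a separate
    punctum only if peak - saddle >= noise_tolerance; otherwise it merges
    into the stronger component.  Equal-intensity ties are broken by
    row-major order, which also merges flat plateaus into a single maximum
    at their first row-major pixel.

    Only pixels >= min_intensity - noise_tolerance enter the sweep: any
    saddle able to disqualify a maximum whose peak clears min_intensity sits
    above that floor, so the result equals a full-image sweep.
    """
    h, w = image.shape
    floor = params.min_intensity - params.noise_tolerance
    flat_img = image.ravel()
    sel = np.flatnonzero(flat_img >= floor)
    if sel.size == 0:
        return []
    # descending intensity, ties in row-major (ascending flat index) order
    order = sel[np.lexsort((sel, -flat_img[sel]))]

    comp_of = np.full(h * w, -1, dtype=np.int64)  # pixel -> component id
    parent: list[int] = []
    peak_val: list[float] = []
    peak_pos: list[int] = []

    def find(c: int) -> int:
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    accepted: list[tuple[float, int, int]] = []
    tol = params.noise_tolerance

    for flat in order:
        r, c = divmod(int(flat), w)
        val = flat_img[flat]
        roots: list[int] = []
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                comp = comp_of[rr * w + cc]
                if comp >= 0:
                    root = find(int(comp))
                    if root not in roots:
                        roots.append(root)
        if not roots:
            comp = len(parent)
            parent.append(comp)
            peak_val.append(float(val))
            peak_pos.append(int(flat))
            comp_of[flat] = comp
            continue
        if len(roots) > 1:
            # merge event at saddle level `val`
            roots.sort(key=lambda rt: (-peak_val[rt], peak_pos[rt]))
            strongest = roots[0]
            for weaker in roots[1:]:
                # zero persistence = a plateau shoulder of the stronger
                # component, not a genuine local maximum
                if peak_val[weaker] - val >= tol and peak_val[weaker] > val:
                    # prominent: a separate punctum (first merge = highest saddle)
                    pr, pc = divmod(peak_pos[weaker], w)
                    accepted.append((peak_val[weaker], pr, pc))
                parent[weaker] = strongest
            root = strongest
        else:
            root = roots[0]
        comp_of[flat] = root

    # components never suppressed at a saddle are maxima in their own right
    for comp in range(len(parent)):
        if parent[comp] == comp:
            pr, pc = divmod(peak_pos[comp], w)
            accepted.append((peak_val[comp], pr, pc))

    accepted = [
        (v, r, c)
        for (v, r, c) in accepted
        if params.min_intensity <= v <= params.max_intensity
    ]
    accepted.sort(key=lambda t: (-t[0], t[1], t[2]))
    return accepted


def punctum_region(
    image: np.ndarray,
    maximum: "Pixel | Punctum",
    peak: float | None = None,
    params: DetectionParams | None = None,
    claimed: Iterable[Pixel] = (),
) -> frozenset[Pixel]:
    """8-connected flood from a maximum down to its cut level.

    The cut level is ``max(min_intensity, peak - noise_tolerance)``.  Pixels
    in ``claimed`` (territory of stronger maxima) stop the flood.  Accepts
    either a (row, col) position plus its peak intensity, or a
    :class:`Punctum`.
    """
    if isinstance(maximum, Punctum):
        peak = maximum.peak
        maximum = maximum.position
    if peak is None or params is None:
        raise TypeError("peak and params are required")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cut = max(params.min_intensity, peak - params.noise_tolerance)
    blocked = set(claimed)
    r0, c0 = maximum
    if image[r0, c0] < cut or (r0, c0) in blocked:
        return frozenset()
    region = {(r0, c0)}
    stack = [(r0, c0)]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                px = (rr, cc)
                if px not in region and px not in blocked and image[rr, cc] >= cut:
                    region.add(px)
                    stack.append(px)
    return frozenset(region)


def detect_puncta(
    image: np.ndarray,
    params: DetectionParams,
    channel: str = "",
    pixel_size_nm: float = 1.0,
) -> PunctaSet:
    """Detect puncta in a single-plane channel image.

    Returns one :class:`Punctum` per accepted local maximum, sorted by
    descending peak intensity (ties by row-major position), with ids
    assigned in that order.  Regions are flooded from strongest to weakest
    so that a stronger punctum's territory blocks its weaker neighbors.
    """
    image = _validate_image(image)
    maxima = _find_maxima(image, params)
    claimed: set[Pixel] = set()
    puncta: list[Punctum] = []
    for idx, (peak, r, c) in enumerate(maxima):
        region = punctum_region(image, (r, c), peak, params, claimed)
        claimed |= region
        puncta.append(
            Punctum(id=idx, channel=channel, max_row=r, max_col=c, peak=peak, region=region)
        )
    return PunctaSet(channel=channel, puncta=puncta, shape=image.shape, pixel_size_nm=pixel_size_nm)


def disk_offsets(radius_px: int) -> list[Pixel]:
    """Offsets (dr, dc) with dr^2 + dc^2 <= radius^2 (Euclidean disk)."""
    r = int(radius_px)
    return [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ]


def dilate_region(
    region: Iterable[Pixel], radius_px: int, shape: tuple[int, int]
) -> frozenset[Pixel]:
    """Morphological dilation of a pixel set by a Euclidean disk.

    Radius 0 is the identity (clipped to bounds).  Mirrors the 2-px
    dilation applied to synaptic-marker and receptor signals before overlap
    testing.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    h, w = shape
    offsets = disk_offsets(radius_px)
    out: set[Pixel] = set()
    for r, c in region:
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out.add((rr, cc))
    return frozenset(out)


def threshold_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of pixels at or above an intensity threshold."""
    return np.asarray(image, dtype=float) >= threshold
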