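"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (exhaustive scans, all-pairs
comparisons, level-set searches) and shares no code with the package
internals beyond the public data types.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from synaptoloc.puncta_detection import DetectionParams, Punctum, PunctaSet

NB = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_local_maxima(image: np.ndarray) -> list[tuple[float, tuple[int, int]]]:
    """All plateau local maxima as (peak, first-row-major position)."""
    h, w = image.shape
    visited: set[tuple[int, int]] = set()
    out = []
    for r, c in product(range(h), range(w)):
        if (r, c) in visited:
            continue
        val = image[r, c]
        comp = {(r, c)}
        stack = [(r, c)]
        while stack:
            rr, cc = stack.pop()
            for dr, dc in NB:
                nr, nc = rr + dr, cc + dc
                if 0 <= nr < h and 0 <= nc < w and (nr, nc) not in comp and image[nr, nc] == val:
                    comp.add((nr, nc))
                    stack.append((nr, nc))
        visited |= comp
        is_max = all(
            image[rr + dr, cc + dc] < val
            for (rr, cc) in comp
            for dr, dc in NB
            if 0 <= rr + dr < h and 0 <= cc + dc < w and (rr + dr, cc + dc) not in comp
        )
        if is_max:
            out.append((float(val), min(comp)))
    return out


def _component_at_level(image: np.ndarray, start: tuple[int, int], level: float) -> set:
    h, w = image.shape
    comp = {start}
    stack = [start]
    while stack:
        rr, cc = stack.pop()
        for dr, dc in NB:
            nr, nc = rr + dr, cc + dc
            if 0 <= nr < h and 0 <= nc < w and (nr, nc) not in comp and image[nr, nc] >= level:
                comp.add((nr, nc))
                stack.append((nr, nc))
    return comp


def brute_accepted_maxima(image: np.ndarray, params: DetectionParams) -> set:
    """Maxima positions accepted under the prominence criterion, by level scan.

    A maximum is suppressed when its prominence over the highest saddle to
    a stronger maximum (higher peak; ties broken row-major) is below the
    noise tolerance, or when its peak falls outside [min, max] intensity.
    """
    maxima = brute_local_maxima(image)
    levels = sorted({float(v) for v in image.ravel()}, reverse=True)
    accepted = set()
    for peak, pos in maxima:
        stronger = [
            p for (v, p) in maxima if v > peak or (v == peak and p < pos)
        ]
        prominence = math.inf
        for level in levels:
            if level > peak:
                continue
            comp = _component_at_level(image, pos, level)
            if any(s in comp for s in stronger):
                prominence = peak - level
                break
        if prominence >= params.noise_tolerance and params.min_intensity <= peak <= params.max_intensity:
            accepted.add(pos)
    return accepted


def brute_dilate(region, radius: int, shape) -> set:
    """Union of Euclidean disks around every region pixel."""
    h, w = shape
    out = set()
    for r, c in region:
        for rr in range(h):
            for cc in range(w):
                if (rr - r) ** 2 + (cc - c) ** 2 <= radius**2:
                    out.add((rr, cc))
    return out


def dist_px(a: Punctum, b: Punctum) -> float:
    return math.hypot(a.max_row - b.max_row, a.max_col - b.max_col)


def brute_pair(pre: PunctaSet, post: PunctaSet, params: DetectionParams):
    """All-pairs pixel-intersection pairing: (post_id, pre_id, n_overlap) list."""
    r = params.dilation_radius_px
    pre_dil = {p.id: brute_dilate(p.region, r, pre.shape) for p in pre}
    post_dil = {p.id: brute_dilate(p.region, r, post.shape) for p in post}
    pre_by_id = {p.id: p for p in pre}
    out = []
    for post_p in sorted(post, key=lambda p: p.id):
        overlapping = [
            pid for pid, reg in pre_dil.items() if reg & post_dil[post_p.id]
        ]
        if not overlapping:
            continue
        best = min(overlapping, key=lambda pid: (dist_px(pre_by_id[pid], post_p), pid))
        out.append((post_p.id, best, len(overlapping)))
    return out


def brute_assign(
    receptors: PunctaSet,
    synapse_rows,  # iterable of (synapse_id, pre_id, post_id)
    post: PunctaSet,
    pre: PunctaSet,
    params: DetectionParams,
    max_post_nm: float,
):
    """Receptor compartment calls by exhaustive enumeration of marker overlaps."""
    r = params.dilation_radius_px
    px = receptors.pixel_size_nm
    post_by_id = {p.id: p for p in post}
    pre_by_id = {p.id: p for p in pre}
    post_syn = {prow[2]: prow[0] for prow in synapse_rows}
    pre_syn: dict[int, list[int]] = {}
    for sid, pid, _ in synapse_rows:
        pre_syn.setdefault(pid, []).append(sid)
    out = {}
    for rec in receptors:
        rec_dil = brute_dilate(rec.region, r, receptors.shape)
        cands = []
        for pid in post_syn:
            if rec_dil & brute_dilate(post_by_id[pid].region, r, post.shape):
                cands.append((dist_px(rec, post_by_id[pid]) * px, 0, post_syn[pid], "post"))
        for pid in pre_syn:
            if rec_dil & brute_dilate(pre_by_id[pid].region, r, pre.shape):
                cands.append((dist_px(rec, pre_by_id[pid]) * px, 1, min(pre_syn[pid]), "pre"))
        if not cands:
            out[rec.id] = ("none", None, math.nan)
            continue
        dist, _, sid, kind = min(cands)
        if kind == "post":
            if dist > max_post_nm:
                out[rec.id] = ("none", None, math.nan)
            else:
                out[rec.id] = ("postsynaptic", sid, dist)
        else:
            out[rec.id] = ("presynaptic", sid, dist)
    return out


def brute_nn(xpts: np.ndarray, ypts: np.ndarray) -> np.ndarray:
    return np.array(
        [min(math.hypot(x[0] - y[0], x[1] - y[1]) for y in ypts) for x in xpts]
    )


def random_puncta_set(
    rng: np.random.Generator,
    n: int,
    shape=(40, 40),
    channel: str = "",
    pixel_size_nm: float = 50.0,
) -> PunctaSet:
    """Random puncta with small square-ish regions around their maxima."""
    h, w = shape
    puncta = []
    for i in range(n):
        r = int(rng.integers(2, h - 2))
        c = int(rng.integers(2, w - 2))
        size = int(rng.integers(1, 4))
        region = {
            (rr, cc)
            for rr in range(r, min(h, r + size))
            for cc in range(c, min(w, c + size))
        }
        puncta.append(
            Punctum(
                id=i,
                channel=channel,
                max_row=r,
                max_col=c,
                peak=float(rng.uniform(10, 100)),
                region=frozenset(region),
            )
        )
    return PunctaSet(channel=channel, puncta=puncta, shape=shape, pixel_size_nm=pixel_size_nm)
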