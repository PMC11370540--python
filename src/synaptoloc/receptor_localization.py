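"""Receptor compartment assignment and localization summaries.

Each receptor punctum gets exactly one compartment call:

* ``postsynaptic`` — its dilated region overlaps a synaptic postsynaptic
  marker and that marker is the nearest overlapping synaptic marker, at a
  maxima distance no greater than the postsynaptic cutoff (400 nm by
  default; beyond it the receptor is too far to be credibly associated with
  the density and the call is demoted to ``none``);
* ``presynaptic`` — it overlaps a synaptic presynaptic marker but no
  postsynaptic marker wins the distance tie-break (no distance cap);
* ``none`` — no overlap with any synaptic marker.

Distances are measured between maxima.  When a receptor overlaps markers of
several synapses, the nearest marker wins.  Exact distance ties resolve to
the postsynaptic marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .puncta_detection import DetectionParams, PunctaSet, dilate_region
from .synapse_assembly import SynapseTable, maxima_distance

__all__ = [
    "ReceptorAssignment",
    "LocalizationSummary",
    "DistanceHistogram",
    "assign_receptors",
    "localization_summary",
    "distance_histogram",
]

DEFAULT_MAX_POST_DISTANCE_NM = 400.0


@dataclass(frozen=True)
class ReceptorAssignment:
    receptor_id: int
    synapse_id: int | None
    compartment: str  # postsynaptic | presynaptic | none
    distance_nm: float  # NaN when compartment == none


@dataclass
class LocalizationSummary:
    """The panel metrics: synapse- and receptor-denominated rates plus distances.

    Percentages are ``None`` when their denominator is zero.  ``distances``
    maps a stratum name (e.g. ``postsynaptic_all``, ``postsynaptic_VGLUT1``)
    to the list of receptor-to-marker distances in that stratum.
    """

    pct_synapses_with_postsynaptic_receptor: float | None
    pct_synapses_with_presynaptic_receptor: float | None
    pct_receptors_postsynaptic: float | None
    pct_receptors_at_vglut1_post: float | None
    pct_receptors_at_vglut2_post: float | None
    pct_vglut1_synapses_with_postsynaptic_receptor: float | None
    pct_vglut2_synapses_with_postsynaptic_receptor: float | None
    pct_vglut1_synapses_with_presynaptic_receptor: float | None
    pct_vglut2_synapses_with_presynaptic_receptor: float | None
    n_synapses: int
    n_receptors: int
    distances: dict[str, list[float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            k: getattr(self, k)
            for k in (
                "pct_synapses_with_postsynaptic_receptor",
                "pct_synapses_with_presynaptic_receptor",
                "pct_receptors_postsynaptic",
                "pct_receptors_at_vglut1_post",
                "pct_receptors_at_vglut2_post",
                "pct_vglut1_synapses_with_postsynaptic_receptor",
                "pct_vglut2_synapses_with_postsynaptic_receptor",
                "pct_vglut1_synapses_with_presynaptic_receptor",
                "pct_vglut2_synapses_with_presynaptic_receptor",
            )
        }


@dataclass
class DistanceHistogram:
    bin_edges_nm: np.ndarray
    frequencies: np.ndarray  # relative, sum to 1
    n: int
    median_nm: float
    iqr_nm: float


def assign_receptors(
    receptors: PunctaSet,
    synapses: SynapseTable,
    post: PunctaSet,
    pre: PunctaSet,
    params: DetectionParams,
    max_post_distance_nm: float = DEFAULT_MAX_POST_DISTANCE_NM,
) -> list[ReceptorAssignment]:
    """Assign every receptor punctum to a compartment.

    Candidate markers are the postsynaptic and presynaptic puncta of
    detected synapses whose dilated regions share at least one pixel with
    the receptor's dilated region.  The nearest candidate wins (ties to the
    postsynaptic marker, then lower synapse id); a winning postsynaptic
    marker farther than ``max_post_distance_nm`` demotes the call to none.
    """
    if receptors.shape != post.shape or receptors.shape != pre.shape:
        raise ValueError("receptor / marker image shapes differ")

    r = params.dilation_radius_px
    post_by_id = {p.id: p for p in post}
    pre_by_id = {p.id: p for p in pre}

    # synapse lookup: marker punctum id -> synapse ids (pre may serve many)
    post_synapse: dict[int, int] = {}
    pre_synapses: dict[int, list[int]] = {}
    for syn in synapses:
        post_synapse[syn.post_id] = syn.id
        pre_synapses.setdefault(syn.pre_id, []).append(syn.id)

    # pixel index over dilated synaptic marker regions
    marker_index: dict[tuple[int, int], list[tuple[str, int]]] = {}
    for pid in post_synapse:
        for px in dilate_region(post_by_id[pid].region, r, post.shape):
            marker_index.setdefault(px, []).append(("post", pid))
    for pid in pre_synapses:
        for px in dilate_region(pre_by_id[pid].region, r, pre.shape):
            marker_index.setdefault(px, []).append(("pre", pid))

    assignments: list[ReceptorAssignment] = []
    for rec in sorted(receptors, key=lambda p: p.id):
        candidates: set[tuple[str, int]] = set()
        for px in dilate_region(rec.region, r, receptors.shape):
            candidates.update(marker_index.get(px, ()))
        if not candidates:
            assignments.append(
                ReceptorAssignment(rec.id, None, "none", math.nan)
            )
            continue

        def sort_key(cand: tuple[str, int]):
            kind, pid = cand
            marker = post_by_id[pid] if kind == "post" else pre_by_id[pid]
            dist = maxima_distance(rec, marker, receptors.pixel_size_nm)
            # ties: postsynaptic first, then lower synapse id
            tie = 0 if kind == "post" else 1
            sid = post_synapse[pid] if kind == "post" else min(pre_synapses[pid])
            return (dist, tie, sid)

        kind, pid = min(candidates, key=sort_key)
        marker = post_by_id[pid] if kind == "post" else pre_by_id[pid]
        dist = maxima_distance(rec, marker, receptors.pixel_size_nm)
        if kind == "post":
            if dist > max_post_distance_nm:
                assignments.append(ReceptorAssignment(rec.id, None, "none", math.nan))
            else:
                assignments.append(
                    ReceptorAssignment(rec.id, post_synapse[pid], "postsynaptic", dist)
                )
        else:
            assignments.append(
                ReceptorAssignment(rec.id, min(pre_synapses[pid]), "presynaptic", dist)
            )
    return assignments


def localization_summary(
    assignments: list[ReceptorAssignment],
    synapses: SynapseTable,
    receptors: PunctaSet,
) -> LocalizationSummary:
    """Aggregate assignments into the synapse- and receptor-level rates."""
    n_syn = len(synapses)
    n_rec = len(receptors)
    label_of = {s.id: s.input_label for s in synapses}

    post_syn_ids = {a.synapse_id for a in assignments if a.compartment == "postsynaptic"}
    pre_syn_ids = {a.synapse_id for a in assignments if a.compartment == "presynaptic"}

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    def per_label(label: str, ids: set) -> float | None:
        den = sum(1 for s in synapses if s.input_label == label)
        num = sum(1 for sid in ids if label_of.get(sid) == label)
        return pct(num, den)

    n_rec_post = sum(1 for a in assignments if a.compartment == "postsynaptic")
    n_rec_post_v1 = sum(
        1
        for a in assignments
        if a.compartment == "postsynaptic" and label_of.get(a.synapse_id) == "VGLUT1"
    )
    n_rec_post_v2 = sum(
        1
        for a in assignments
        if a.compartment == "postsynaptic" and label_of.get(a.synapse_id) == "VGLUT2"
    )

    distances: dict[str, list[float]] = {
        "postsynaptic_all": [],
        "postsynaptic_VGLUT1": [],
        "postsynaptic_VGLUT2": [],
        "presynaptic_all": [],
    }
    for a in assignments:
        if a.compartment == "postsynaptic":
            distances["postsynaptic_all"].append(a.distance_nm)
            lbl = label_of.get(a.synapse_id)
            if lbl in ("VGLUT1", "VGLUT2"):
                distances[f"postsynaptic_{lbl}"].append(a.distance_nm)
        elif a.compartment == "presynaptic":
            distances["presynaptic_all"].append(a.distance_nm)

    return LocalizationSummary(
        pct_synapses_with_postsynaptic_receptor=pct(len(post_syn_ids), n_syn),
        pct_synapses_with_presynaptic_receptor=pct(len(pre_syn_ids), n_syn),
        pct_receptors_postsynaptic=pct(n_rec_post, n_rec),
        pct_receptors_at_vglut1_post=pct(n_rec_post_v1, n_rec),
        pct_receptors_at_vglut2_post=pct(n_rec_post_v2, n_rec),
        pct_vglut1_synapses_with_postsynaptic_receptor=per_label("VGLUT1", post_syn_ids),
        pct_vglut2_synapses_with_postsynaptic_receptor=per_label("VGLUT2", post_syn_ids),
        pct_vglut1_synapses_with_presynaptic_receptor=per_label("VGLUT1", pre_syn_ids),
        pct_vglut2_synapses_with_presynaptic_receptor=per_label("VGLUT2", pre_syn_ids),
        n_synapses=n_syn,
        n_receptors=n_rec,
        distances=distances,
    )


def distance_histogram(
    distances_nm, bin_width_nm: float = 20.0
) -> DistanceHistogram:
    """Relative-frequency histogram of distances with fixed-width bins from 0.

    Median and IQR are computed on the raw values with linear-interpolation
    quantiles, not from the binned data.
    """
    d = np.asarray(list(distances_nm), dtype=float)
    if d.size == 0:
        raise ValueError("no distances to histogram")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be > 0")
    n_bins = max(1, int(np.ceil((d.max() + 1e-9) / bin_width_nm)))
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts, _ = np.histogram(d, bins=edges)
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    return DistanceHistogram(
        bin_edges_nm=edges,
        frequencies=counts / d.size,
        n=int(d.size),
        median_nm=float(q50),
        iqr_nm=float(q75 - q25),
    )
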