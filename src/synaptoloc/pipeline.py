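"""End-to-end analysis of one multichannel field of view.

Wires the stages together: per-channel puncta detection, synapse pairing,
VGLUT input classification, receptor compartment assignment, and the
per-FOV metric summary consumed by the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthetic_data as sd
from .puncta_detection import DetectionParams, PunctaSet, detect_puncta
from .receptor_localization import (
    DEFAULT_MAX_POST_DISTANCE_NM,
    LocalizationSummary,
    ReceptorAssignment,
    assign_receptors,
    localization_summary,
)
from .reporting_stats import FOVSummary, density_per_area
from .synapse_assembly import SynapseTable, classify_inputs, pair_synapses, synapse_rates

__all__ = ["AnalysisConfig", "FOVResult", "analyze_fov", "default_analysis_config"]


@dataclass
class AnalysisConfig:
    """Channel mapping and per-channel detection parameters for one session."""

    pre_channel: str = sd.PRE_CHANNEL
    post_channel: str = sd.POST_CHANNEL
    receptor_channel: str = sd.RECEPTOR_CHANNEL
    vglut1_channel: str = sd.VGLUT1_CHANNEL
    vglut2_channel: str = sd.VGLUT2_CHANNEL
    detection: dict[str, DetectionParams] = field(default_factory=dict)
    vglut_thresholds: dict[str, float] = field(default_factory=dict)
    max_post_distance_nm: float = DEFAULT_MAX_POST_DISTANCE_NM

    def params_for(self, channel: str) -> DetectionParams:
        try:
            return self.detection[channel]
        except KeyError:
            raise ValueError(f"no detection parameters configured for channel {channel!r}")


def default_analysis_config() -> AnalysisConfig:
    """Detection parameters matched to the synthetic generator's defaults.

    Spot peaks sit around background + amplitude (~900 counts); the minimum
    threshold rejects background and noise, and the noise tolerance sets
    the flood depth that defines punctum regions.
    """
    marker = DetectionParams(min_intensity=350.0, noise_tolerance=150.0, dilation_radius_px=2)
    return AnalysisConfig(
        detection={
            sd.PRE_CHANNEL: marker,
            sd.POST_CHANNEL: marker,
            sd.RECEPTOR_CHANNEL: marker,
        },
        vglut_thresholds={"vglut1": 300.0, "vglut2": 300.0},
    )


@dataclass
class FOVResult:
    puncta: dict[str, PunctaSet]
    synapses: SynapseTable
    assignments: list[ReceptorAssignment]
    localization: LocalizationSummary
    rates: dict[str, float | None]
    metrics: dict[str, float | None]

    def summary(self, mouse_id: str = "", fov_index: int = 1) -> FOVSummary:
        return FOVSummary(mouse_id=mouse_id, fov_index=fov_index, metrics=self.metrics)


def analyze_fov(images: sd.FOVImages, config: AnalysisConfig) -> FOVResult:
    """Run detection, pairing, classification and receptor assignment."""
    px = images.pixel_size_nm

    def detect(channel: str) -> PunctaSet:
        return detect_puncta(images[channel], config.params_for(channel), channel, px)

    pre = detect(config.pre_channel)
    post = detect(config.post_channel)

    table = pair_synapses(pre, post, config.params_for(config.pre_channel))
    v1 = images.channels.get(config.vglut1_channel)
    v2 = images.channels.get(config.vglut2_channel)
    if v1 is not None or v2 is not None:
        table = classify_inputs(
            table, pre, v1, v2, config.vglut_thresholds, config.params_for(config.pre_channel)
        )

    receptors = None
    assignments: list[ReceptorAssignment] = []
    if config.receptor_channel in images.channels:
        receptors = detect(config.receptor_channel)
        assignments = assign_receptors(
            receptors,
            table,
            post,
            pre,
            config.params_for(config.receptor_channel),
            config.max_post_distance_nm,
        )
    if receptors is None:
        receptors = PunctaSet(channel=config.receptor_channel, puncta=[], shape=images.shape, pixel_size_nm=px)

    loc = localization_summary(assignments, table, receptors)
    rates = synapse_rates(table)

    h, w = images.shape
    area_um2 = (h * px / 1000.0) * (w * px / 1000.0)
    pre_post = table.distances_nm()
    post_dists = loc.distances.get("postsynaptic_all", [])
    metrics: dict[str, float | None] = dict(rates)
    metrics.update(loc.as_dict())
    metrics.update(
        {
            "median_pre_post_distance_nm": float(np.median(pre_post)) if pre_post.size else None,
            "median_receptor_post_distance_nm": (
                float(np.median(post_dists)) if post_dists else None
            ),
            "puncta_density_per_25um2": density_per_area(len(receptors), area_um2),
            "n_synapses": float(len(table)),
            "n_pre_puncta": float(len(pre)),
            "n_post_puncta": float(len(post)),
            "n_receptor_puncta": float(len(receptors)),
        }
    )
    return FOVResult(
        puncta={ps.channel: ps for ps in (pre, post, receptors)},
        synapses=table,
        assignments=assignments,
        localization=loc,
        rates=rates,
        metrics=metrics,
    )
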