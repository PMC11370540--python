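"""Reading and writing the package's on-disk formats.

Fields of view travel as multi-page TIFF (one page per channel) with the
channel names and pixel size recorded in the image description; tables
(puncta, synapses, assignments, ground truth, FISH counts) as CSV; configs
as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .puncta_detection import PunctaSet
from .receptor_localization import ReceptorAssignment
from .synapse_assembly import SynapseTable
from .synthetic_data import FOVImages, GroundTruth, SynthConfig

__all__ = [
    "write_fov_tiff",
    "read_fov_tiff",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_synth_config_yaml",
    "read_synth_config_yaml",
    "puncta_to_frame",
    "synapses_to_frame",
    "assignments_to_frame",
]


def write_fov_tiff(images: FOVImages, path: str | Path) -> None:
    names = list(images.channels)
    stack = np.stack([images.channels[n] for n in names]).astype(np.float32)
    description = json.dumps({"channels": names, "pixel_size_nm": images.pixel_size_nm})
    tifffile.imwrite(path, stack, description=description)


def read_fov_tiff(path: str | Path) -> FOVImages:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: np.asarray(stack[i], dtype=float) for i, name in enumerate(meta["channels"])}
    return FOVImages(channels=channels, pixel_size_nm=float(meta["pixel_size_nm"]))


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    truth.synapses.to_csv(path, index=False)
    extra = Path(path).with_suffix(".extra_sites.csv")
    truth.extra_pre_sites.to_csv(extra, index=False)


def read_ground_truth_csv(path: str | Path) -> GroundTruth:
    synapses = pd.read_csv(path)
    extra_path = Path(path).with_suffix(".extra_sites.csv")
    extra = (
        pd.read_csv(extra_path)
        if extra_path.exists()
        else pd.DataFrame(columns=["synapse_id", "x_nm", "y_nm"])
    )
    return GroundTruth(synapses=synapses, extra_pre_sites=extra)


def write_synth_config_yaml(config: SynthConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_synth_config_yaml(path: str | Path) -> SynthConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("fov_size_px", "pre_post_sep_nm", "receptor_offset_nm", "spot_amplitude"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SynthConfig(**data)


def puncta_to_frame(ps: PunctaSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(id=p.id, channel=p.channel, row=p.max_row, col=p.max_col, peak=p.peak, area_px=p.area_px)
            for p in ps
        ],
        columns=["id", "channel", "row", "col", "peak", "area_px"],
    )


def synapses_to_frame(table: SynapseTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                synapse_id=s.id,
                pre_id=s.pre_id,
                post_id=s.post_id,
                distance_nm=s.pre_post_distance_nm,
                input_label=s.input_label,
                multi_overlap_count=s.multi_overlap_count,
            )
            for s in table
        ],
        columns=["synapse_id", "pre_id", "post_id", "distance_nm", "input_label", "multi_overlap_count"],
    )


def assignments_to_frame(assignments: list[ReceptorAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                receptor_id=a.receptor_id,
                synapse_id=a.synapse_id,
                compartment=a.compartment,
                distance_nm=a.distance_nm,
            )
            for a in assignments
        ],
        columns=["receptor_id", "synapse_id", "compartment", "distance_nm"],
    )
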