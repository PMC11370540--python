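"""Synthetic multichannel fields of view with known synapse ground truth.

Emulates punctate immunofluorescence of glutamatergic synapses in thalamus:
numerous small corticothalamic (CT) terminals marked by VGLUT1, sparse large
multi-release-site sensory terminals marked by VGLUT2, presynaptic (bassoon)
and postsynaptic (homer) scaffold puncta juxtaposed ~150-200 nm apart, and a
receptor channel occupying a configurable fraction of synapses at a
configurable offset from the postsynaptic marker.  Spots are rendered as
isotropic 2-D Gaussians (sigma set by the imaging resolution), on a uniform
background with additive Gaussian noise.  Every downstream pipeline stage is
testable against the returned truth table without any external data.

Conventions: positions are continuous (x, y) in nm with x = column direction
and y = row direction; pixel (r, c) has its center at (c * px, r * px) nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "FOVImages",
    "PlacementError",
    "generate_fov",
    "generate_negative_control",
    "generate_point_patterns",
    "render_spots",
]

# channel names used by the generator and the default analysis config
PRE_CHANNEL = "bassoon"
POST_CHANNEL = "homer"
RECEPTOR_CHANNEL = "glun"
VGLUT1_CHANNEL = "vglut1"
VGLUT2_CHANNEL = "vglut2"


class PlacementError(RuntimeError):
    """FOV too small to place the requested synapses at the required spacing."""


@dataclass
class SynthConfig:
    """Parameters of one synthetic field of view.

    Defaults describe the emulated study conditions: a 50 nm pixel grid
    (below the ~120 nm XY optical resolution so juxtaposed markers are
    resolvable), pre/post marker separation 190 +/- 30 nm, receptor offset
    from the postsynaptic marker 150 +/- 40 nm directed away from the
    presynaptic side, and a CT:sensory synapse ratio of about 10:1.
    """

    fov_size_px: tuple[int, int] = (1024, 1024)  # (H, W)
    pixel_size_nm: float = 50.0
    n_ct_synapses: int = 100
    n_sensory_synapses: int = 10
    pre_post_sep_nm: tuple[float, float] = (190.0, 30.0)  # mean, SD
    receptor_occupancy: dict[str, float] = field(
        default_factory=lambda: {"CT": 0.5, "sensory": 0.15}
    )
    receptor_offset_nm: tuple[float, float] = (150.0, 40.0)  # mean, SD
    receptor_angle_sd_deg: float = 45.0  # angular spread about the away-from-pre axis
    sensory_terminal_n_sites: int = 4
    psf_sigma_nm: float = 120.0
    vglut2_envelope_sigma_nm: float = 250.0
    spot_amplitude: tuple[float, float] = (800.0, 150.0)  # mean, SD
    vglut_amplitude: float = 600.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    spurious_spot_rate: float = 5.0  # expected spurious spots per negative-control FOV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ct_synapses < 0 or self.n_sensory_synapses < 0:
            raise ValueError("synapse counts must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if self.sensory_terminal_n_sites < 1:
            raise ValueError("sensory_terminal_n_sites must be >= 1")
        for cls, f in self.receptor_occupancy.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"receptor_occupancy[{cls!r}] must be in [0, 1]")
        if self.spurious_spot_rate < 0:
            raise ValueError("spurious_spot_rate must be >= 0")

    @property
    def fov_size_nm(self) -> tuple[float, float]:
        h, w = self.fov_size_px
        return (h * self.pixel_size_nm, w * self.pixel_size_nm)

    @property
    def min_spacing_nm(self) -> float:
        # >= 4 sigma keeps rendered spots of neighboring synapses separable;
        # the 600 nm floor keeps VGLUT2 envelope tails off neighboring CT
        # presynaptic regions so input labels stay unambiguous.
        return max(4.0 * self.psf_sigma_nm, 600.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-synapse truth table plus decoy release-site positions.

    ``synapses`` columns: synapse_id, input_class (CT | sensory), pre_x_nm,
    pre_y_nm, post_x_nm, post_y_nm, receptor_present, rec_x_nm, rec_y_nm
    (NaN when absent).  ``extra_pre_sites`` holds the additional
    release-site spots of sensory terminals (pre channel only; no paired
    postsynaptic marker), columns synapse_id, x_nm, y_nm.
    """

    synapses: pd.DataFrame
    extra_pre_sites: pd.DataFrame

    def __len__(self) -> int:
        return len(self.synapses)

    def occupancy(self, input_class: str) -> float:
        sub = self.synapses[self.synapses.input_class == input_class]
        if len(sub) == 0:
            return float("nan")
        return float(sub.receptor_present.mean())


@dataclass
class FOVImages:
    """Named channel -> 2-D intensity grid, all sharing one shape."""

    channels: dict[str, np.ndarray]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share the same shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def render_spots(
    shape: tuple[int, int],
    positions_nm: np.ndarray,
    amplitudes: np.ndarray,
    sigma_nm: float,
    pixel_size_nm: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Add isotropic Gaussian spots to an image (positions are (x, y) nm)."""
    h, w = shape
    img = np.zeros(shape) if out is None else out
    sigma_px = sigma_nm / pixel_size_nm
    half = max(2, int(np.ceil(5 * sigma_px)))
    positions_nm = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    for (x, y), amp in zip(positions_nm, amplitudes):
        cx = x / pixel_size_nm  # column coordinate of the center
        cy = y / pixel_size_nm
        r0 = max(0, int(np.floor(cy)) - half)
        r1 = min(h, int(np.ceil(cy)) + half + 1)
        c0 = max(0, int(np.floor(cx)) - half)
        c1 = min(w, int(np.ceil(cx)) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma_px**2)
        )
    return img


def _place_centers(config: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform synapse centers with minimum spacing, by rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    h_nm, w_nm = config.fov_size_nm
    margin = 4 * config.psf_sigma_nm + 600.0  # keep all rendered positions inside
    if w_nm <= 2 * margin or h_nm <= 2 * margin:
        raise PlacementError(
            f"FOV {config.fov_size_px} px at {config.pixel_size_nm} nm/px is too small "
            f"for the {margin:.0f} nm placement margin"
        )
    spacing = config.min_spacing_nm
    centers: list[np.ndarray] = []
    max_tries = 2000 * n + 10000
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} synapses with spacing >= {spacing:.0f} nm "
                f"in a {w_nm:.0f} x {h_nm:.0f} nm FOV after {max_tries} attempts"
            )
        cand = np.array(
            [rng.uniform(margin, w_nm - margin), rng.uniform(margin, h_nm - margin)]
        )
        if all(np.hypot(*(cand - c)) >= spacing for c in centers):
            centers.append(cand)
    return np.array(centers)


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean vector with exactly round(fraction * n) True entries."""
    k = int(round(fraction * n))
    out = np.zeros(n, dtype=bool)
    if k > 0:
        out[rng.choice(n, size=k, replace=False)] = True
    return out


def generate_fov(config: SynthConfig) -> tuple[FOVImages, GroundTruth]:
    """Render one multichannel FOV and its ground-truth table.

    Deterministic given ``config.seed``.  Pre markers sit at the synapse
    center; the post marker is offset by a random direction at
    ``pre_post_sep_nm``; the receptor (when present) is offset from the post
    marker along the direction pointing away from the presynaptic side.
    Sensory terminals additionally render ``n_sites - 1`` decoy pre spots
    under a wide VGLUT2 envelope; decoys carry no postsynaptic partner and
    are kept clear of all true marker positions.
    """
    rng = np.random.default_rng(config.seed)
    n_ct, n_sen = config.n_ct_synapses, config.n_sensory_synapses
    n = n_ct + n_sen
    shape = tuple(config.fov_size_px)

    centers = _place_centers(config, rng, n)
    classes = np.array(["CT"] * n_ct + ["sensory"] * n_sen)

    sep_mean, sep_sd = config.pre_post_sep_nm
    off_mean, off_sd = config.receptor_offset_nm

    rows = []
    extra_sites = []
    occupied = {
        cls: _exact_subset(rng, int(np.sum(classes == cls)), config.receptor_occupancy.get(cls, 0.0))
        for cls in ("CT", "sensory")
    }
    class_counters = {"CT": 0, "sensory": 0}

    for i in range(n):
        cls = classes[i]
        pre = centers[i]
        sep = max(0.0, rng.normal(sep_mean, sep_sd))
        theta = rng.uniform(0, 2 * np.pi)
        post = pre + sep * np.array([np.cos(theta), np.sin(theta)])

        present = bool(occupied[cls][class_counters[cls]])
        class_counters[cls] += 1
        rec = np.array([np.nan, np.nan])
        if present:
            dist = max(0.0, rng.normal(off_mean, off_sd))
            # away-from-pre bias: receptors sit on the postsynaptic side
            away = theta + np.deg2rad(rng.normal(0.0, config.receptor_angle_sd_deg))
            rec = post + dist * np.array([np.cos(away), np.sin(away)])

        rows.append(
            dict(
                synapse_id=i,
                input_class=cls,
                pre_x_nm=pre[0],
                pre_y_nm=pre[1],
                post_x_nm=post[0],
                post_y_nm=post[1],
                receptor_present=present,
                rec_x_nm=rec[0],
                rec_y_nm=rec[1],
            )
        )

        if cls == "sensory":
            # decoy release sites of the large terminal, away from all
            # true marker positions so they cannot capture a pairing
            placed = 0
            guard = 0
            while placed < config.sensory_terminal_n_sites - 1 and guard < 500:
                guard += 1
                radius = rng.uniform(500.0, 700.0)
                ang = rng.uniform(0, 2 * np.pi)
                site = pre + radius * np.array([np.cos(ang), np.sin(ang)])
                if np.hypot(*(site - post)) < 600.0:
                    continue
                if present and np.hypot(*(site - rec)) < 600.0:
                    continue
                if any(
                    np.hypot(*(site - c)) < config.min_spacing_nm
                    for j, c in enumerate(centers)
                    if j != i
                ):
                    continue
                extra_sites.append(dict(synapse_id=i, x_nm=site[0], y_nm=site[1]))
                placed += 1

    truth = GroundTruth(
        synapses=pd.DataFrame(
            rows,
            columns=[
                "synapse_id",
                "input_class",
                "pre_x_nm",
                "pre_y_nm",
                "post_x_nm",
                "post_y_nm",
                "receptor_present",
                "rec_x_nm",
                "rec_y_nm",
            ],
        ),
        extra_pre_sites=pd.DataFrame(extra_sites, columns=["synapse_id", "x_nm", "y_nm"]),
    )

    amp_mean, amp_sd = config.spot_amplitude

    def amps(k: int) -> np.ndarray:
        return np.clip(rng.normal(amp_mean, amp_sd, size=k), 0.0, None)

    syn = truth.synapses
    channels: dict[str, np.ndarray] = {}

    pre_positions = [syn[["pre_x_nm", "pre_y_nm"]].to_numpy()]
    if len(truth.extra_pre_sites):
        pre_positions.append(truth.extra_pre_sites[["x_nm", "y_nm"]].to_numpy())
    pre_xy = np.vstack(pre_positions) if n else np.empty((0, 2))

    channels[PRE_CHANNEL] = render_spots(
        shape, pre_xy, amps(len(pre_xy)), config.psf_sigma_nm, config.pixel_size_nm
    )
    post_xy = syn[["post_x_nm", "post_y_nm"]].to_numpy() if n else np.empty((0, 2))
    channels[POST_CHANNEL] = render_spots(
        shape, post_xy, amps(len(post_xy)), config.psf_sigma_nm, config.pixel_size_nm
    )
    rec_xy = syn.loc[syn.receptor_present, ["rec_x_nm", "rec_y_nm"]].to_numpy() if n else np.empty((0, 2))
    channels[RECEPTOR_CHANNEL] = render_spots(
        shape, rec_xy, amps(len(rec_xy)), config.psf_sigma_nm, config.pixel_size_nm
    )

    # VGLUT1 spots co-centered with CT pre markers
    ct_xy = syn.loc[syn.input_class == "CT", ["pre_x_nm", "pre_y_nm"]].to_numpy() if n else np.empty((0, 2))
    channels[VGLUT1_CHANNEL] = render_spots(
        shape,
        ct_xy,
        np.full(len(ct_xy), config.vglut_amplitude),
        config.psf_sigma_nm,
        config.pixel_size_nm,
    )
    # VGLUT2 envelopes: one wide Gaussian per sensory terminal at the true pre
    sen_xy = syn.loc[syn.input_class == "sensory", ["pre_x_nm", "pre_y_nm"]].to_numpy() if n else np.empty((0, 2))
    channels[VGLUT2_CHANNEL] = render_spots(
        shape,
        sen_xy,
        np.full(len(sen_xy), config.vglut_amplitude),
        config.vglut2_envelope_sigma_nm,
        config.pixel_size_nm,
    )

    for name, img in channels.items():
        img += config.background_level
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)

    return FOVImages(channels=channels, pixel_size_nm=config.pixel_size_nm), truth


def generate_negative_control(config: SynthConfig) -> FOVImages:
    """Background + noise + Poisson-count spurious low-amplitude spots.

    Emulates negative-control acquisitions used to calibrate detection
    thresholds (controls must show at most a few particles per cell); no
    true synapses are rendered.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.fov_size_px)
    h_nm, w_nm = config.fov_size_nm
    n_spots = int(rng.poisson(config.spurious_spot_rate))
    amp_mean = 0.35 * config.spot_amplitude[0]
    xy = np.column_stack([rng.uniform(0, w_nm, n_spots), rng.uniform(0, h_nm, n_spots)])
    amps = np.clip(rng.normal(amp_mean, 0.1 * amp_mean, n_spots), 0.0, None)
    img = render_spots(shape, xy, amps, config.psf_sigma_nm, config.pixel_size_nm)
    img += config.background_level
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=shape)
    np.clip(img, 0.0, None, out=img)
    channels = {name: img.copy() for name in (RECEPTOR_CHANNEL,)}
    return FOVImages(channels=channels, pixel_size_nm=config.pixel_size_nm)


def generate_point_patterns(
    kind: str,
    n_x: int,
    n_y: int,
    region: tuple[float, float, float, float],
    offset_nm: float = 0.0,
    seed: int = 0,
):
    """Paired planar point patterns for exercising the NN statistic.

    ``kind='csr'``: X and Y independent uniform (complete spatial
    randomness).  ``kind='attractive'``: Y uniform; each X point is a
    uniformly chosen Y point plus an isotropic Gaussian offset of SD
    ``offset_nm``, clipped to the region.
    """
    from .nn_interaction import PointPattern

    if n_x < 1 or n_y < 1:
        raise ValueError("n_x and n_y must be >= 1")
    x0, y0, x1, y1 = region
    if not (x1 > x0 and y1 > y0):
        raise ValueError("region must have positive area")
    rng = np.random.default_rng(seed)
    ypts = np.column_stack([rng.uniform(x0, x1, n_y), rng.uniform(y0, y1, n_y)])
    if kind == "csr":
        xpts = np.column_stack([rng.uniform(x0, x1, n_x), rng.uniform(y0, y1, n_x)])
    elif kind == "attractive":
        anchors = ypts[rng.integers(0, n_y, n_x)]
        xpts = anchors + rng.normal(0.0, offset_nm, size=(n_x, 2))
        xpts[:, 0] = np.clip(xpts[:, 0], x0, x1)
        xpts[:, 1] = np.clip(xpts[:, 1], y0, y1)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return PointPattern(xpts, region), PointPattern(ypts, region)
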