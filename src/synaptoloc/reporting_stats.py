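"""Per-mouse aggregation, descriptive statistics and Welch's t-test.

The study design images three fields of view (FOV) per animal and averages
each metric across them, so the animal — not the FOV — is the experimental
unit.  Group comparisons use Welch's unequal-variance t-test with
Welch-Satterthwaite degrees of freedom, reported with the mean difference
and its 95% confidence interval.  Text-style descriptives are mean +/- SD
and median (IQR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FOVSummary",
    "MouseSummary",
    "GroupComparison",
    "aggregate_by_mouse",
    "welch_t",
    "welch_t_from_summary",
    "descriptives",
    "density_per_area",
    "METRIC_REGISTRY",
]

# metric names a FOVSummary may carry (synapse rates, localization summary
# scalars, NN statistics, densities)
METRIC_REGISTRY = frozenset(
    {
        "pct_pre_synaptic",
        "pct_post_synaptic",
        "pct_multi_overlap",
        "pct_vglut1",
        "pct_vglut2",
        "pct_synapses_with_postsynaptic_receptor",
        "pct_synapses_with_presynaptic_receptor",
        "pct_receptors_postsynaptic",
        "pct_receptors_at_vglut1_post",
        "pct_receptors_at_vglut2_post",
        "pct_vglut1_synapses_with_postsynaptic_receptor",
        "pct_vglut2_synapses_with_postsynaptic_receptor",
        "pct_vglut1_synapses_with_presynaptic_receptor",
        "pct_vglut2_synapses_with_presynaptic_receptor",
        "median_pre_post_distance_nm",
        "median_receptor_post_distance_nm",
        "nn_epsilon",
        "nn_epsilon_rotated_control",
        "puncta_density_per_25um2",
        "n_synapses",
        "n_pre_puncta",
        "n_post_puncta",
        "n_receptor_puncta",
    }
)


@dataclass
class FOVSummary:
    """Scalar metrics measured on one field of view of one mouse."""

    mouse_id: str
    fov_index: int
    metrics: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - METRIC_REGISTRY
        if unknown:
            raise ValueError(f"unknown metric keys: {sorted(unknown)}")


@dataclass
class MouseSummary:
    mouse_id: str
    means: dict[str, float]
    n_fov: int


@dataclass
class GroupComparison:
    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t: float
    df: float
    p: float
    mean_difference: float
    ci95: tuple[float, float]


def aggregate_by_mouse(fovs: list[FOVSummary]) -> list[MouseSummary]:
    """Unweighted mean of each metric over a mouse's FOVs.

    Undefined (None / NaN) FOV metrics are excluded from that metric's
    mean; a metric undefined in every FOV stays NaN.
    """
    by_mouse: dict[str, list[FOVSummary]] = {}
    for fov in fovs:
        by_mouse.setdefault(fov.mouse_id, []).append(fov)
    out: list[MouseSummary] = []
    for mouse_id, group in by_mouse.items():
        frame = pd.DataFrame([f.metrics for f in group], dtype=float)
        means = frame.mean(skipna=True).to_dict() if not frame.empty else {}
        out.append(MouseSummary(mouse_id=mouse_id, means=means, n_fov=len(group)))
    return out


def welch_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Welch's t-test from group summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch-Satterthwaite
    degrees of freedom and a two-sided p from the t distribution.  With
    zero variance in both groups and equal means the statistic is
    undefined and reported as NaN.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = math.sqrt(v1 + v2)
    diff = mean1 - mean2
    if se == 0.0:
        t = math.nan if diff == 0.0 else math.copysign(math.inf, diff)
        df = float(n1 + n2 - 2)
        p = math.nan if diff == 0.0 else 0.0
        ci = (diff, diff)
    else:
        t = diff / se
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
        half = stats.t.ppf(0.975, df) * se
        ci = (diff - half, diff + half)
    return GroupComparison(
        group_names=group_names,
        means=(mean1, mean2),
        sds=(sd1, sd2),
        ns=(n1, n2),
        t=t,
        df=df,
        p=p,
        mean_difference=diff,
        ci95=ci,
    )


def welch_t(
    a, b, group_names: tuple[str, str] = ("group1", "group2")
) -> GroupComparison:
    """Welch's t-test from raw per-group values."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    return welch_t_from_summary(
        float(a.mean()),
        float(a.std(ddof=1)),
        int(a.size),
        float(b.mean()),
        float(b.std(ddof=1)),
        int(b.size),
        group_names=group_names,
    )


def descriptives(values) -> dict[str, float]:
    """mean, sample SD, median, IQR (linear-interpolation quartiles), n."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else math.nan,
        "median": float(q50),
        "iqr": float(q75 - q25),
        "n": int(v.size),
    }


def density_per_area(n_puncta: int, area_um2: float, per_um2: float = 25.0) -> float:
    """Puncta density normalized to a reference area (25 um^2 by default)."""
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    return n_puncta / area_um2 * per_um2
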