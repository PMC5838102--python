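"""Per-axon longitudinal analysis of slice measurements.

Measurements are taken from 2D sections at fixed intervals (default 5 µm of
arc length) along each traced axon; this module assembles them into per-axon
profiles and derives the longitudinal statistics: per-metric range
(max - min over the sampled sections), per-axon means, the decompaction
point score (sections with more than 40% of the myelinated circumference
decompacted, per µm of measured axon length), and single-section / random
2D sampling used to contrast 3D tracing against conventional single-section
morphometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .centerline import Centerline, sample_positions, trace_axon
from .io import METRIC_UNITS, LabelVolume, MeasurementTable
from .morphometry import (
    DEFAULT_N_RAYS,
    SliceMeasurement,
    cross_section,
    measure_cross_section,
)

log = logging.getLogger("axonmorph")

METRICS = [
    "area",
    "axon_diameter",
    "myelin_thickness",
    "fiber_diameter",
    "g_ratio",
    "decompaction_pct",
]

DEFAULT_INTERVAL_UM = 5.0
DEFAULT_THRESHOLD_PCT = 40.0


@dataclass
class AxonProfile:
    """Ordered slice measurements along one traced axon."""

    axon_id: int
    measurements: list[SliceMeasurement]
    measured_length_um: float
    group: str = ""
    animal_id: int = 0

    def __post_init__(self) -> None:
        pos = [m.arc_position_um for m in self.measurements]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("sample positions must be strictly increasing")

    def values(self, metric: str) -> np.ndarray:
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        return np.array([m.as_dict()[metric] for m in self.measurements])


@dataclass
class ProfileSummary:
    """Per-axon summary: mean/min/max/range per metric + decompaction score."""

    axon_id: int
    stats: dict[str, dict[str, float]]  # metric -> {mean,min,max,range}
    decompaction_score: float  # points per µm
    group: str = ""
    animal_id: int = 0


def measure_profile(
    volume: LabelVolume,
    axon_id: int,
    interval_um: float = DEFAULT_INTERVAL_UM,
    n_rays: int = DEFAULT_N_RAYS,
    use_arc: bool = True,
) -> AxonProfile:
    """Trace an axon and measure 2D sections at fixed arc intervals."""
    cl = trace_axon(volume, axon_id)
    zs = sample_positions(cl, interval_um, volume.spacing.dz_um, use_arc=use_arc)
    measurements = []
    for z in zs:
        cs = cross_section(volume, axon_id, z, component_mask=cl.components[z])
        measurements.append(
            measure_cross_section(cs, arc_position_um=cl.arc_at(z), n_rays=n_rays)
        )
    return AxonProfile(
        axon_id=axon_id,
        measurements=measurements,
        measured_length_um=cl.measured_length_um,
    )


def metric_range(profile: AxonProfile, metric: str) -> float:
    """max - min of a metric over the profile's sampled sections."""
    v = profile.values(metric)
    if len(v) < 2:
        raise ValueError("range needs at least 2 samples")
    return float(v.max() - v.min())


def profile_mean(profile: AxonProfile, metric: str) -> float:
    """Arithmetic mean of a metric over the sampled sections."""
    v = profile.values(metric)
    if len(v) == 0:
        raise ValueError("empty profile")
    return float(v.mean())


def decompaction_score(
    profile: AxonProfile, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> float:
    """Decompaction points per µm of measured axon length.

    A sampled section scores a point when strictly more than ``threshold_pct``
    of its myelinated circumference is decompacted; the total is normalized
    by the measured (arc) length of the axon, giving µm⁻¹.
    """
    if profile.measured_length_um <= 0:
        raise ValueError("measured length must be positive")
    flagged = int(np.sum(profile.values("decompaction_pct") > threshold_pct))
    return flagged / profile.measured_length_um


def summarize_profile(
    profile: AxonProfile, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> ProfileSummary:
    stats = {}
    for metric in METRICS:
        v = profile.values(metric)
        stats[metric] = {
            "mean": float(v.mean()),
            "min": float(v.min()),
            "max": float(v.max()),
            "range": float(v.max() - v.min()),
        }
    return ProfileSummary(
        axon_id=profile.axon_id,
        stats=stats,
        decompaction_score=decompaction_score(profile, threshold_pct),
        group=profile.group,
        animal_id=profile.animal_id,
    )


# ---------------------------------------------------------------------------
# 2D single-section sampling (3D-vs-2D comparisons)
# ---------------------------------------------------------------------------


def _measurements_to_table(ms: list[SliceMeasurement]) -> MeasurementTable:
    records = []
    for m in ms:
        for metric, value in m.as_dict().items():
            records.append(
                {
                    "axon_id": m.axon_id,
                    "z_index": m.z_index,
                    "metric": metric,
                    "value": value,
                    "units": METRIC_UNITS[metric],
                }
            )
    return MeasurementTable.from_records(records)


def single_section_sample(
    profiles: list[AxonProfile], position_um: float
) -> MeasurementTable:
    """One section per axon at the sampled position nearest ``position_um``.

    Profiles shorter than the requested position are skipped with a warning;
    it is an error if no profile reaches it.
    """
    chosen: list[SliceMeasurement] = []
    for p in profiles:
        if position_um > p.measured_length_um:
            log.warning(
                "axon %d: measured length %.1f µm < position %.1f µm; skipped",
                p.axon_id, p.measured_length_um, position_um,
            )
            continue
        pos = np.array([m.arc_position_um for m in p.measurements])
        chosen.append(p.measurements[int(np.argmin(np.abs(pos - position_um)))])
    if not chosen:
        raise ValueError(f"no profile covers position {position_um} µm")
    return _measurements_to_table(chosen)


def random_axon_section_sample(
    volume: LabelVolume,
    z_index: int,
    n: int,
    seed: int,
    n_rays: int = DEFAULT_N_RAYS,
) -> MeasurementTable:
    """Measure ``n`` randomly chosen axons in one 2D section.

    Mirrors conventional single-section morphometry: axons are sampled
    uniformly without replacement among those present at the slice.
    """
    lo, hi = volume.channel_map["axon"]
    plane = volume.stack[z_index]
    present = sorted(
        int(v) for v in np.unique(plane) if lo <= v <= hi
    )
    if len(present) < n:
        raise ValueError(
            f"slice {z_index} holds {len(present)} axons, fewer than n={n}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(present, size=n, replace=False).tolist())
    ms = []
    for axon_id in chosen:
        cs = cross_section(volume, axon_id, z_index)
        ms.append(measure_cross_section(cs, n_rays=n_rays))
    return _measurements_to_table(ms)
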