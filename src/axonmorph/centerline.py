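"""Trace axon instances through the stack and position measurements along them.

An axon is followed from the first slice in which its label appears until it
leaves the imaged volume.  Per slice, the traced point is the area centroid of
the axon's in-plane connected component; when a slice contains several
components with the same id, the one with the largest voxel overlap against
the previous slice's component is followed.  The cumulative arc length of the
resulting 3D polyline is the "length of the axon" along which measurement
positions (by default every 5 µm) are placed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LabelVolume

log = logging.getLogger("axonmorph")


@dataclass
class Centerline:
    """Ordered per-slice centroids of one axon, with physical arc length."""

    axon_id: int
    z_indices: np.ndarray  # strictly increasing slice indices
    points_um: np.ndarray  # (n, 2) centroid (x, y) in µm, matching z_indices
    arc_um: np.ndarray  # cumulative arc length s(z), arc_um[0] == 0
    dz_um: float  # slice thickness
    #: per-slice boolean mask of the followed component, keyed by z_index
    components: dict[int, np.ndarray]

    @property
    def measured_length_um(self) -> float:
        """Traced length: centre-to-centre arc plus the two half-slice ends,
        so an axon spanning all n slices measures the full n*dz extent."""
        return float(self.arc_um[-1]) + self.dz_um

    @property
    def z_extent(self) -> tuple[int, int]:
        return int(self.z_indices[0]), int(self.z_indices[-1])

    def arc_at(self, z_index: int) -> float:
        i = int(np.searchsorted(self.z_indices, z_index))
        if i >= len(self.z_indices) or self.z_indices[i] != z_index:
            raise KeyError(f"slice {z_index} not on centerline")
        return float(self.arc_um[i])


def _slice_components(plane: np.ndarray, axon_id: int) -> tuple[np.ndarray, int]:
    labeled, n = ndimage.label(plane == axon_id)
    return labeled, n


def _centroid_um(mask: np.ndarray, volume: LabelVolume) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    cy = (ys.mean() + 0.5) * volume.spacing.dy_um
    cx = (xs.mean() + 0.5) * volume.spacing.dx_um
    return cx, cy


def trace_axon(
    volume: LabelVolume, axon_id: int, max_gap: int = 2
) -> Centerline:
    """Trace one axon id through the stack by largest-overlap linking.

    Mitochondrion labels punch holes in the axon mask (they carry their own
    ids inside the axon interior), so each in-plane component is hole-filled
    before its centroid is taken.

    A run of more than ``max_gap`` consecutive slices with no overlapping
    component terminates the trace with a warning rather than an error.
    """
    lo, hi = volume.channel_map["axon"]
    if not (lo <= axon_id <= hi):
        raise ValueError(f"{axon_id} is not in the axon label range {lo}-{hi}")
    present = np.flatnonzero(
        (volume.stack == axon_id).any(axis=(1, 2))
    )
    if len(present) < 2:
        raise ValueError(f"axon {axon_id} present in fewer than 2 slices")

    z_first = int(present[0])
    zs: list[int] = []
    pts: list[tuple[float, float]] = []
    comps: dict[int, np.ndarray] = {}
    prev_mask: np.ndarray | None = None
    gap = 0
    for z in range(z_first, volume.n_slices):
        labeled, n = _slice_components(volume.stack[z], axon_id)
        chosen: np.ndarray | None = None
        if n == 1:
            chosen = labeled == 1
        elif n > 1:
            if prev_mask is None:
                sizes = ndimage.sum_labels(
                    np.ones_like(labeled), labeled, index=range(1, n + 1)
                )
                chosen = labeled == (int(np.argmax(sizes)) + 1)
            else:
                overlaps = [
                    int(np.count_nonzero(prev_mask & (labeled == k)))
                    for k in range(1, n + 1)
                ]
                best = int(np.argmax(overlaps))
                if overlaps[best] > 0:
                    chosen = labeled == (best + 1)
        if chosen is not None and prev_mask is not None:
            if not np.count_nonzero(chosen & prev_mask):
                # same id but spatially disconnected from the trace
                chosen = None
        if chosen is None:
            gap += 1
            if gap > max_gap:
                log.warning(
                    "axon %d: trace terminated at z=%d after %d-slice gap",
                    axon_id, z, gap,
                )
                break
            continue
        gap = 0
        filled = ndimage.binary_fill_holes(chosen)
        zs.append(z)
        pts.append(_centroid_um(filled, volume))
        comps[z] = filled
        prev_mask = filled

    if len(zs) < 2:
        raise ValueError(f"axon {axon_id}: could not trace 2 consecutive slices")

    z_idx = np.asarray(zs)
    points = np.asarray(pts)
    dz_um = volume.spacing.dz_um
    steps = np.sqrt(
        np.diff(points[:, 0]) ** 2
        + np.diff(points[:, 1]) ** 2
        + (np.diff(z_idx) * dz_um) ** 2
    )
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    return Centerline(
        axon_id=axon_id, z_indices=z_idx, points_um=points, arc_um=arc,
        dz_um=dz_um, components=comps,
    )


def sample_positions(
    cl: Centerline, interval_um: float, dz_um: float, use_arc: bool = True
) -> list[int]:
    """Slice indices nearest to arc positions 0, i, 2i, ... <= measured length.

    ``use_arc=False`` spaces samples by z-distance instead of arc length (the
    two coincide for near-axial axons).  The interval must resolve at least
    one slice step.
    """
    if interval_um <= 0:
        raise ValueError("interval must be positive")
    if interval_um < dz_um:
        raise ValueError(
            f"interval {interval_um} µm is below the slice step {dz_um} µm"
        )
    if use_arc:
        coord = cl.arc_um
        total = cl.measured_length_um
    else:
        coord = (cl.z_indices - cl.z_indices[0]) * dz_um
        total = coord[-1] + dz_um
    targets = np.arange(0.0, total + 1e-9, interval_um)
    out: list[int] = []
    for t in targets:
        i = int(np.argmin(np.abs(coord - t)))
        z = int(cl.z_indices[i])
        if not out or z > out[-1]:
            out.append(z)
    return out
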