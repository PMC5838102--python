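"""Nodes of Ranvier, paranodal gaps, and nodal mitochondria.

A node is detected as a maximal run of consecutive unmyelinated slices along
a traced axon (myelin coverage below half the circumference, the same rule
that zeroes myelin thickness on nodal sections).  The paranodal gap is the
arc distance between the termini of the two flanking myelin internodes.
Mitochondrion length is the pure z-span of its label (first slice in view to
last), and a mitochondrion is "nodal" when its midpoint lies within a 10 µm
arc window of a node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import Centerline
from .io import LabelVolume
from .morphometry import cross_section, myelin_thickness

DEFAULT_MIN_RUN = 3
DEFAULT_NODAL_WINDOW_UM = 10.0


@dataclass
class NodeRecord:
    axon_id: int
    center_s_um: float  # arc position of the node centre
    gap_um: float  # myelin terminus-to-terminus arc distance
    flank_before_s_um: float
    flank_after_s_um: float


@dataclass
class MitoRecord:
    mito_id: int
    axon_id: int
    first_slice: int
    last_slice: int
    length_um: float
    nearest_node: int | None = None  # index into the axon's node list
    node_distance_um: float = float("inf")

    @property
    def is_nodal(self) -> bool:
        return self.node_distance_um <= DEFAULT_NODAL_WINDOW_UM


def detect_nodes(
    volume: LabelVolume,
    cl: Centerline,
    min_run: int = DEFAULT_MIN_RUN,
    n_rays: int = 180,
) -> list[NodeRecord]:
    """Find nodes of Ranvier along a traced axon.

    Every traced slice (not only the sampled measurement positions) is
    classified as myelinated or not; runs of at least ``min_run`` consecutive
    unmyelinated slices count as nodes, which suppresses single-slice
    segmentation dropouts.  Runs touching either end of the trace are
    discarded because their gap cannot be delimited.
    """
    myelinated = np.empty(len(cl.z_indices), dtype=bool)
    for i, z in enumerate(cl.z_indices):
        cs = cross_section(volume, cl.axon_id, int(z),
                           component_mask=cl.components[int(z)])
        myelinated[i] = myelin_thickness(cs, n_rays=n_rays) > 0.0

    records: list[NodeRecord] = []
    n = len(myelinated)
    i = 0
    while i < n:
        if myelinated[i]:
            i += 1
            continue
        j = i
        while j < n and not myelinated[j]:
            j += 1
        run = j - i
        touches_end = i == 0 or j == n
        if run >= min_run and not touches_end:
            # myelin termini lie between the flanking myelinated slice and
            # the first/last unmyelinated one; the transition midpoint is the
            # unbiased sub-slice estimate of each terminus
            s_start = 0.5 * (cl.arc_um[i - 1] + cl.arc_um[i])
            s_end = 0.5 * (cl.arc_um[j - 1] + cl.arc_um[j])
            records.append(
                NodeRecord(
                    axon_id=cl.axon_id,
                    center_s_um=0.5 * (s_start + s_end),
                    gap_um=s_end - s_start,
                    flank_before_s_um=float(cl.arc_um[i - 1]),
                    flank_after_s_um=float(cl.arc_um[j]),
                )
            )
        i = j
    return records


def mito_length(volume: LabelVolume, mito_id: int) -> float:
    """Mitochondrion length in µm as its z-span: slices in view x dz."""
    present = np.flatnonzero((volume.stack == mito_id).any(axis=(1, 2)))
    if len(present) == 0:
        raise ValueError(f"mitochondrion {mito_id} absent from volume")
    return float((present[-1] - present[0] + 1) * volume.spacing.dz_um)


def collect_mitochondria(
    volume: LabelVolume, centerlines: dict[int, Centerline]
) -> list[MitoRecord]:
    """Build MitoRecords for every mitochondrion label, assigning each to the
    axon whose traced component contains (or surrounds) its voxels."""
    records = []
    for mid in volume.mito_ids():
        present = np.flatnonzero((volume.stack == mid).any(axis=(1, 2)))
        first, last = int(present[0]), int(present[-1])
        owner = _owning_axon(volume, mid, first, centerlines)
        records.append(
            MitoRecord(
                mito_id=mid,
                axon_id=owner,
                first_slice=first,
                last_slice=last,
                length_um=(last - first + 1) * volume.spacing.dz_um,
            )
        )
    return records


def _owning_axon(
    volume: LabelVolume, mito_id: int, z: int, centerlines: dict[int, Centerline]
) -> int:
    mask = volume.stack[z] == mito_id
    for axon_id, cl in centerlines.items():
        comp = cl.components.get(z)
        if comp is not None and (comp & mask).any():
            return axon_id
    return 0


def _mito_arc_position(mito: MitoRecord, cl: Centerline) -> float | None:
    """Arc position of the mitochondrion's z-midpoint on its axon's trace."""
    mid_z = 0.5 * (mito.first_slice + mito.last_slice)
    i = int(np.argmin(np.abs(cl.z_indices - mid_z)))
    return float(cl.arc_um[i])


def nodal_mito_stats(
    mitos: list[MitoRecord],
    nodes: list[NodeRecord],
    centerlines: dict[int, Centerline],
    window_um: float = DEFAULT_NODAL_WINDOW_UM,
) -> dict[int, tuple[int, list[float]]]:
    """Per-node count and length list of nodal mitochondria.

    Each mitochondrion is assigned to at most one node — the nearest on its
    own axon — and only when the arc distance is within ``window_um``.
    Returns {node index -> (count, [lengths µm])}; also annotates the
    MitoRecords with their nearest node and distance.
    """
    if window_um <= 0:
        raise ValueError("window must be positive")
    out: dict[int, tuple[int, list[float]]] = {
        i: (0, []) for i in range(len(nodes))
    }
    for mito in mitos:
        cl = centerlines.get(mito.axon_id)
        if cl is None:
            continue
        s = _mito_arc_position(mito, cl)
        best_i, best_d = None, float("inf")
        for i, node in enumerate(nodes):
            if node.axon_id != mito.axon_id:
                continue
            d = abs(s - node.center_s_um)
            if d < best_d:
                best_i, best_d = i, d
        mito.nearest_node = best_i
        mito.node_distance_um = best_d
        if best_i is not None and best_d <= window_um:
            count, lengths = out[best_i]
            out[best_i] = (count + 1, lengths + [mito.length_um])
    return out
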