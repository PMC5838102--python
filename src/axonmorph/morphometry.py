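"""Per-slice (2D) ultrastructural measurements.

Cross-sections are taken in the acquisition z-plane, exactly as recorded by
the microscope — not resampled perpendicular to the axon.  Because axons
wander relative to the sectioning plane, a section through a tilted cylinder
is an ellipse whose long axis inflates with obliquity; the *minimum* caliper
(Feret) diameter of the section is invariant to that inflation, which is why
minimum diameter and minimum myelin thickness are the operative definitions
here.

Measurements per section: cross-sectional area, minimum axon diameter,
minimum myelin thickness (ray casting from the axon centroid), fiber diameter
(axon + sheath), G-ratio (axon diameter / fiber diameter), and the percentage
of the myelinated circumference occupied by decompacted myelin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .io import LabelVolume, VoxelSpacing

DEFAULT_N_RAYS = 360


@dataclass
class CrossSection:
    """One axon's in-plane masks at a single z-slice."""

    axon_id: int
    z_index: int
    axon_mask: np.ndarray  # filled in-plane component (bool, full slice shape)
    compact_mask: np.ndarray
    decompacted_mask: np.ndarray
    centroid_um: tuple[float, float]  # (x, y)
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        if not self.axon_mask.any():
            raise ValueError("axon mask is empty")

    @property
    def myelin_mask(self) -> np.ndarray:
        return self.compact_mask | self.decompacted_mask


@dataclass
class SliceMeasurement:
    """All per-section metrics for one axon at one slice."""

    axon_id: int
    z_index: int
    arc_position_um: float
    area_um2: float
    axon_diameter_um: float
    myelin_thickness_um: float
    fiber_diameter_um: float
    g_ratio: float
    decompaction_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area_um2,
            "axon_diameter": self.axon_diameter_um,
            "myelin_thickness": self.myelin_thickness_um,
            "fiber_diameter": self.fiber_diameter_um,
            "g_ratio": self.g_ratio,
            "decompaction_pct": self.decompaction_pct,
        }


def cross_section(
    volume: LabelVolume,
    axon_id: int,
    z_index: int,
    component_mask: np.ndarray | None = None,
) -> CrossSection:
    """Extract one axon's cross-section from a slice.

    ``component_mask`` selects the in-plane component chosen by centerline
    tracing; by default the largest component of the axon id is used and
    hole-filled (mitochondria carry their own labels inside the axon, so the
    raw axon mask has holes where mitochondria sit).
    """
    plane = volume.stack[z_index]
    if component_mask is None:
        raw = plane == axon_id
        if not raw.any():
            raise ValueError(f"axon {axon_id} absent from slice {z_index}")
        labeled, n = ndimage.label(raw)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                                       index=range(1, n + 1))
            raw = labeled == (int(np.argmax(sizes)) + 1)
        component_mask = ndimage.binary_fill_holes(raw)
    compact_label, decomp_label = volume.myelin_labels(axon_id)
    ys, xs = np.nonzero(component_mask)
    cx = (xs.mean() + 0.5) * volume.spacing.dx_um
    cy = (ys.mean() + 0.5) * volume.spacing.dy_um
    return CrossSection(
        axon_id=axon_id,
        z_index=z_index,
        axon_mask=component_mask,
        compact_mask=(plane == compact_label) & ~component_mask,
        decompacted_mask=(plane == decomp_label) & ~component_mask,
        centroid_um=(cx, cy),
        spacing=volume.spacing,
    )


# ---------------------------------------------------------------------------
# individual measurements
# ---------------------------------------------------------------------------


def cross_sectional_area(cs: CrossSection) -> float:
    """Axon cross-sectional area in µm² (voxel count x pixel area)."""
    return float(np.count_nonzero(cs.axon_mask)) * cs.spacing.pixel_area_um2


def _hull_points_um(mask: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """Corner points (x, y) in µm of all mask voxels (hull input)."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask")
    dx, dy = spacing.dx_um, spacing.dy_um
    corners = np.concatenate(
        [
            np.c_[xs * dx, ys * dy],
            np.c_[(xs + 1) * dx, ys * dy],
            np.c_[xs * dx, (ys + 1) * dy],
            np.c_[(xs + 1) * dx, (ys + 1) * dy],
        ]
    )
    return corners


def min_caliper_diameter(mask: np.ndarray, spacing: VoxelSpacing) -> float:
    """Minimum Feret (caliper) width of a voxel mask, in µm.

    The minimum width of a convex polygon is attained perpendicular to one of
    its edges, so the exact value is the smallest over hull edges of the
    farthest vertex distance from that edge's line.
    """
    pts = _hull_points_um(mask, spacing)
    if np.count_nonzero(mask) == 1:
        return min(spacing.dx_um, spacing.dy_um)
    hull = ConvexHull(pts)
    v = pts[hull.vertices]  # counter-clockwise
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    edges, origins = edges[keep], v[keep]
    normals = np.c_[-edges[:, 1], edges[:, 0]] / lengths[keep, None]
    # distance of every vertex from every edge line: (n_edges, n_vertices)
    d = np.abs(normals @ v.T - np.sum(normals * origins, axis=1)[:, None])
    widths = d.max(axis=1)
    return float(widths.min())


def brute_force_min_width(
    mask: np.ndarray,
    spacing: VoxelSpacing,
    step_deg: float = 0.5,
    refine: bool = False,
) -> float:
    """Directional-sweep oracle: min over projection widths at fixed angles.

    Independent of the rotating-calipers route; used for validation only.
    A finite sweep can only overestimate the true minimum width, by up to
    ``width''(theta) * (step/2)^2`` at the sweep resolution; with
    ``refine=True`` the sweep minimum is polished by a bounded 1D search
    inside the bracketing step, which removes that grid error while staying
    a pure direction search.
    """
    pts = _hull_points_um(mask, spacing)

    def width(theta: np.ndarray | float) -> np.ndarray | float:
        theta = np.atleast_1d(theta)
        dirs = np.c_[np.cos(theta), np.sin(theta)]
        proj = pts @ dirs.T  # (n_points, n_angles)
        w = proj.max(axis=0) - proj.min(axis=0)
        return w if w.size > 1 else float(w[0])

    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    widths = width(angles)
    if not refine:
        return float(widths.min())
    from scipy.optimize import minimize_scalar

    # near-tied local minima are common (near-circular shapes), so every
    # local minimum of the circular sweep is polished, not just the best
    step = math.radians(step_deg)
    left = np.roll(widths, 1)
    right = np.roll(widths, -1)
    candidates = np.flatnonzero((widths <= left) & (widths <= right))
    best = float(widths.min())
    for i in candidates:
        res = minimize_scalar(
            width,
            bounds=(angles[i] - step, angles[i] + step),
            method="bounded",
            options={"xatol": 1e-9},
        )
        best = min(best, float(res.fun))
    return best


def _ray_hits(
    cs: CrossSection, n_rays: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample rays from the centroid; return per-(ray, step) membership in
    (myelin, decompacted) masks, plus the radial step length in µm."""
    if n_rays < 90:
        raise ValueError("need at least 90 rays")
    sp = cs.spacing
    step = 0.5 * min(sp.dx_um, sp.dy_um)
    ny, nx = cs.axon_mask.shape
    max_r = math.hypot(nx * sp.dx_um, ny * sp.dy_um)
    radii = np.arange(step, max_r, step)
    angles = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    cx, cy = cs.centroid_um
    x = cx + radii[None, :] * np.cos(angles)[:, None]
    y = cy + radii[None, :] * np.sin(angles)[:, None]
    ix = np.floor(x / sp.dx_um).astype(int)
    iy = np.floor(y / sp.dy_um).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    myelin = cs.myelin_mask[iy, ix] & inside
    decomp = cs.decompacted_mask[iy, ix] & inside
    return myelin, decomp, step


def myelin_thickness(cs: CrossSection, n_rays: int = DEFAULT_N_RAYS) -> float:
    """Minimum radial myelin thickness in µm by centroid ray casting.

    Per ray, thickness is the length of the ray's intersection with the
    myelin sheath (compact or decompacted); the minimum over rays that hit
    myelin is returned.  Slices where fewer than half the rays hit myelin
    are treated as unmyelinated (nodal) and return 0.
    """
    myelin, _, step = _ray_hits(cs, n_rays)
    per_ray = myelin.sum(axis=1) * step
    hit = per_ray > 0
    if hit.sum() < 0.5 * n_rays:
        return 0.0
    return float(per_ray[hit].min())


def fiber_diameter(cs: CrossSection, n_rays: int = DEFAULT_N_RAYS) -> float:
    """Minimum caliper diameter of the whole fiber (axon + myelin) in µm.

    Equals the axon diameter exactly when the section is unmyelinated.
    """
    fiber_mask = cs.axon_mask | cs.myelin_mask
    return min_caliper_diameter(fiber_mask, cs.spacing)


def g_ratio(axon_diameter_um: float, fiber_diameter_um: float) -> float:
    """Axon diameter / fiber diameter; 1.0 for an unmyelinated section."""
    if fiber_diameter_um <= 0:
        raise ValueError("fiber diameter must be positive")
    if axon_diameter_um > fiber_diameter_um + 1e-12:
        raise ValueError(
            f"axon diameter {axon_diameter_um} exceeds fiber diameter "
            f"{fiber_diameter_um}"
        )
    return min(axon_diameter_um / fiber_diameter_um, 1.0)


def decompaction_percent(cs: CrossSection, n_rays: int = DEFAULT_N_RAYS) -> float:
    """Percent of the myelinated circumference occupied by decompacted myelin.

    Counted over rays that hit any myelin, so a partial wrap next to a node
    is scored over its actual circumference; 0 when no ray hits myelin.
    """
    myelin, decomp, _ = _ray_hits(cs, n_rays)
    myelin_rays = myelin.any(axis=1)
    if not myelin_rays.any():
        return 0.0
    decomp_rays = decomp.any(axis=1)
    return float(100.0 * decomp_rays.sum() / myelin_rays.sum())


def measure_cross_section(
    cs: CrossSection,
    arc_position_um: float = 0.0,
    n_rays: int = DEFAULT_N_RAYS,
) -> SliceMeasurement:
    """Compute the full per-section metric set for one cross-section."""
    area = cross_sectional_area(cs)
    axon_d = min_caliper_diameter(cs.axon_mask, cs.spacing)
    thick = myelin_thickness(cs, n_rays)
    if thick > 0:
        fiber_d = fiber_diameter(cs, n_rays)
        decomp = decompaction_percent(cs, n_rays)
    else:
        fiber_d = axon_d
        decomp = 0.0
    return SliceMeasurement(
        axon_id=cs.axon_id,
        z_index=cs.z_index,
        arc_position_um=arc_position_um,
        area_um2=area,
        axon_diameter_um=axon_d,
        myelin_thickness_um=thick,
        fiber_diameter_um=max(fiber_d, axon_d),
        g_ratio=g_ratio(axon_d, max(fiber_d, axon_d)),
        decompaction_pct=decomp,
    )
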