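"""Synthetic labeled phantoms of myelinated axons with known ground truth.

The generator emulates the geometry of a serial block-face SEM acquisition of
optic nerve: tortuous myelinated axons running roughly along z, with
sinusoidally varying caliber, a myelin annulus whose thickness follows the
classical linear caliber coupling ``thickness = g * diameter + c``
(defaults g = 0.20, c = 0.13 µm for healthy nerve), nodes of Ranvier as
myelin-free gaps, patches of decompacted myelin (modelled as a radially
widened annulus sector carrying its own label class), and intra-axonal
mitochondria near nodes.

Every structure is recorded in a :class:`PhantomTruth` table before
rasterization, so downstream measurements can be validated against exact
design values.  Generation is a pure function of the configuration; all
randomness flows from per-axon child generators seeded as
``(config.seed, axon_index, stream)``, which makes "normal" and "injured"
cohorts built from the same seed share axon geometry (caliber profile,
tortuosity, node position) while differing only in the condition parameters
— a matched design that isolates the injury contrasts.

At full acquisition scale a stack is 10000 x 10000 px at 5 nm/px with 2000
slices of 50 nm (50 x 50 x 100 µm); the default phantom is desk-scale,
256 x 256 px at 20 nm/px and 400 slices of 100 nm (5.12 x 5.12 x 40 µm),
preserving the strong z anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import (
    COMPACT_OFFSET,
    DECOMPACTED_OFFSET,
    DEFAULT_CHANNEL_MAP,
    LabelVolume,
    VoxelSpacing,
)

#: desk-scale default spacing (nm): coarser in-plane, finer z than acquisition,
#: keeping anisotropy while fitting µm-scale axons into a small grid
TEST_SPACING = VoxelSpacing(dx=20.0, dy=20.0, dz=100.0)
TEST_SHAPE = (400, 256, 256)

#: radial widening factor applied to decompacted myelin sectors
DECOMPACTION_WIDENING = 1.5

MITO_BASE = DEFAULT_CHANNEL_MAP["mitochondrion"][0] - 1  # mito i -> label MITO_BASE+i

# child-generator stream tags
_GEOM, _NOISE, _SECTOR = 1, 2, 3


class PhantomOverlapError(RuntimeError):
    """Two structures claimed the same voxel during rasterization."""


@dataclass
class AxonSpec:
    """Design parameters for a single phantom axon.

    Radii and thicknesses in µm; the radius profile is
    ``base * (1 + variation * sin(2*pi*z/period + phase))`` where ``phase``
    gains a random offset at generation time.
    """

    base_radius_um: float = 0.45
    radius_variation: float = 0.25
    radius_period_um: float = 18.0
    radius_phase: float = 0.0
    max_tilt_deg: float = 8.0
    thickness_slope: float = 0.20
    thickness_intercept_um: float = 0.13
    thickness_noise_sd_um: float = 0.0
    #: (z_start_um, z_end_um, angular_fraction in (0,1])
    decompaction_spans: list[tuple[float, float, float]] = field(default_factory=list)
    #: (node_center_z_um, paranodal_gap_um)
    nodes: list[tuple[float, float]] = field(default_factory=list)
    #: (mito_center_z_um, mito_span_um)
    mitochondria: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = TEST_SHAPE
    spacing: VoxelSpacing = field(default_factory=lambda: TEST_SPACING)
    axons: list[AxonSpec] = field(default_factory=lambda: [AxonSpec()])
    seed: int = 0
    mito_radius_um: float = 0.15

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    def z_extent_um(self) -> float:
        return self.shape[0] * self.spacing.dz_um


@dataclass
class PhantomTruth:
    """Ground-truth tables for one generated phantom.

    ``profiles``: one row per (axon_id, z_index) with true centerline point,
    radius, myelin thickness (0 inside node gaps) and decompacted angular
    fraction.  ``nodes``: designed node centres and gap lengths.
    ``mitos``: designed mitochondrion spans, owning axons, and the slice
    range actually rasterized.
    """

    profiles: pd.DataFrame
    nodes: pd.DataFrame
    mitos: pd.DataFrame

    def axon_profile(self, axon_id: int) -> pd.DataFrame:
        return self.profiles[self.profiles.axon_id == axon_id].reset_index(drop=True)

    def centerline_length_um(self, axon_id: int) -> float:
        p = self.axon_profile(axon_id)
        d = np.diff(np.c_[p.z_um, p.cy_um, p.cx_um], axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------


def _random_walk_centerline(
    rng: np.random.Generator,
    z_um: np.ndarray,
    start_xy: tuple[float, float],
    bounds: tuple[float, float, float, float],
    max_tilt_deg: float,
    waypoint_spacing_um: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth tortuous centerline: spline through randomly tilted waypoints.

    Each waypoint-to-waypoint segment tilts away from z by an angle drawn
    uniformly in [0, max_tilt]; steps that would leave ``bounds``
    (x_lo, x_hi, y_lo, y_hi) are reflected back inside.
    """
    z_lo, z_hi = z_um[0], z_um[-1]
    n_seg = max(2, int(math.ceil((z_hi - z_lo) / waypoint_spacing_um)))
    wp_z = np.linspace(z_lo, z_hi, n_seg + 1)
    x_lo, x_hi, y_lo, y_hi = bounds
    xs = [start_xy[0]]
    ys = [start_xy[1]]
    for i in range(n_seg):
        seg = wp_z[i + 1] - wp_z[i]
        tilt = math.radians(rng.uniform(0.0, max_tilt_deg))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        step = seg * math.tan(tilt)
        nx = xs[-1] + step * math.cos(phi)
        ny = ys[-1] + step * math.sin(phi)
        if not (x_lo <= nx <= x_hi):
            nx = xs[-1] - step * math.cos(phi)
        if not (y_lo <= ny <= y_hi):
            ny = ys[-1] - step * math.sin(phi)
        xs.append(min(max(nx, x_lo), x_hi))
        ys.append(min(max(ny, y_lo), y_hi))
    cx = CubicSpline(wp_z, xs)(z_um)
    cy = CubicSpline(wp_z, ys)(z_um)
    return np.clip(cx, x_lo, x_hi), np.clip(cy, y_lo, y_hi)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _outer_radius_bound(spec: AxonSpec) -> float:
    r_max = spec.base_radius_um * (1.0 + abs(spec.radius_variation))
    t_max = spec.thickness_slope * 2.0 * r_max + spec.thickness_intercept_um
    t_max += 4.0 * spec.thickness_noise_sd_um
    return r_max + DECOMPACTION_WIDENING * t_max


def _grid_cells(
    config: PhantomConfig,
) -> list[tuple[float, float, float, float, float, float]]:
    """Assign each axon a square XY cell; returns (cx, cy, x_lo, x_hi, y_lo, y_hi)."""
    nz, ny, nx = config.shape
    width_x = nx * config.spacing.dx_um
    width_y = ny * config.spacing.dy_um
    n = config.n_axons
    side = int(math.ceil(math.sqrt(n)))
    pitch_x = width_x / side
    pitch_y = width_y / side
    max_outer = max(_outer_radius_bound(spec) for spec in config.axons)
    if min(pitch_x, pitch_y) < 2.0 * max_outer:
        raise ValueError(
            f"{n} axons with outer radius up to {max_outer:.2f} µm do not fit "
            f"in a {width_x:.2f} x {width_y:.2f} µm field"
        )
    cells = []
    for i in range(n):
        gx, gy = i % side, i // side
        cx = (gx + 0.5) * pitch_x
        cy = (gy + 0.5) * pitch_y
        margin = max_outer + 2 * config.spacing.dx_um
        cells.append(
            (
                cx,
                cy,
                gx * pitch_x + margin,
                (gx + 1) * pitch_x - margin,
                gy * pitch_y + margin,
                (gy + 1) * pitch_y - margin,
            )
        )
    return cells


def _child_rng(seed: int, axon_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, axon_index, stream]))


def generate_phantom(config: PhantomConfig) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterize the configured axons into a label stack with truth tables.

    Raises :class:`PhantomOverlapError` if two structures would claim the
    same voxel, and ValueError if any designed radius falls below 2 in-plane
    voxels (too thin to measure reliably).
    """
    nz, ny, nx = config.shape
    sp = config.spacing
    z_um = (np.arange(nz) + 0.5) * sp.dz_um
    xs = (np.arange(nx) + 0.5) * sp.dx_um
    ys = (np.arange(ny) + 0.5) * sp.dy_um

    if config.n_axons == 0:
        empty_cols_p = ["axon_id", "z_index", "z_um", "cx_um", "cy_um",
                        "radius_um", "thickness_um", "decompacted_fraction"]
        return (
            LabelVolume(stack=np.zeros(config.shape, dtype=np.uint16), spacing=sp),
            PhantomTruth(
                profiles=pd.DataFrame(columns=empty_cols_p),
                nodes=pd.DataFrame(columns=["axon_id", "center_z_um", "gap_um"]),
                mitos=pd.DataFrame(
                    columns=["mito_id", "axon_id", "center_z_um", "span_um",
                             "first_slice", "last_slice"]
                ),
            ),
        )

    cells = _grid_cells(config)
    stack = np.zeros(config.shape, dtype=np.uint16)

    profile_rows = []
    node_rows = []
    mito_rows = []

    # per axon: (cx(z), cy(z), r(z), myelin thickness(z), decomp fraction(z),
    # sector start(z))
    designs = []
    for i, spec in enumerate(config.axons):
        axon_id = i + 1
        ccx, ccy, x_lo, x_hi, y_lo, y_hi = cells[i]
        rng_geom = _child_rng(config.seed, i, _GEOM)
        cx, cy = _random_walk_centerline(
            rng_geom, z_um, (ccx, ccy), (x_lo, x_hi, y_lo, y_hi), spec.max_tilt_deg
        )
        phase = spec.radius_phase + rng_geom.uniform(0.0, 2.0 * math.pi)
        radius = spec.base_radius_um * (
            1.0
            + spec.radius_variation
            * np.sin(2.0 * math.pi * z_um / spec.radius_period_um + phase)
        )
        if radius.min() < 2.0 * max(sp.dx_um, sp.dy_um):
            raise ValueError(
                f"axon {axon_id}: designed radius {radius.min():.3f} µm is below "
                f"the 2-voxel floor"
            )
        thickness = spec.thickness_slope * 2.0 * radius + spec.thickness_intercept_um
        if spec.thickness_noise_sd_um > 0:
            rng_noise = _child_rng(config.seed, i, _NOISE)
            thickness = thickness + spec.thickness_noise_sd_um * rng_noise.standard_normal(nz)
        thickness = np.clip(thickness, 2.0 * max(sp.dx_um, sp.dy_um), None)

        myelinated = np.ones(nz, dtype=bool)
        for node_z, gap in spec.nodes:
            myelinated &= np.abs(z_um - node_z) > gap / 2.0
            node_rows.append({"axon_id": axon_id, "center_z_um": node_z, "gap_um": gap})

        decomp_fraction = np.zeros(nz)
        sector_start = np.zeros(nz)
        rng_sector = _child_rng(config.seed, i, _SECTOR)
        for z0, z1, frac in spec.decompaction_spans:
            theta0 = rng_sector.uniform(0.0, 2.0 * math.pi)
            in_span = (z_um >= z0) & (z_um <= z1) & myelinated
            decomp_fraction[in_span] = frac
            sector_start[in_span] = theta0

        thickness = np.where(myelinated, thickness, 0.0)
        designs.append((cx, cy, radius, thickness, decomp_fraction, sector_start))
        for iz in range(nz):
            profile_rows.append(
                {
                    "axon_id": axon_id,
                    "z_index": iz,
                    "z_um": z_um[iz],
                    "cx_um": cx[iz],
                    "cy_um": cy[iz],
                    "radius_um": radius[iz],
                    "thickness_um": thickness[iz],
                    "decompacted_fraction": decomp_fraction[iz],
                }
            )

    # rasterize slice by slice; each axon writes into a cropped window
    X, Y = np.meshgrid(xs, ys)  # (ny, nx), X varies along columns
    for iz in range(nz):
        plane = stack[iz]
        for i in range(config.n_axons):
            axon_id = i + 1
            cx, cy, radius, thickness, dfrac, sect0 = designs[i]
            r = radius[iz]
            t = thickness[iz]
            outer = r + DECOMPACTION_WIDENING * max(t, 0.0)
            j0 = max(0, int((cy[iz] - outer) / sp.dy_um) - 1)
            j1 = min(ny, int((cy[iz] + outer) / sp.dy_um) + 2)
            k0 = max(0, int((cx[iz] - outer) / sp.dx_um) - 1)
            k1 = min(nx, int((cx[iz] + outer) / sp.dx_um) + 2)
            Xw = X[j0:j1, k0:k1] - cx[iz]
            Yw = Y[j0:j1, k0:k1] - cy[iz]
            d = np.hypot(Xw, Yw)
            axon_mask = d <= r
            win = plane[j0:j1, k0:k1]
            if t > 0:
                frac = dfrac[iz]
                if frac > 0:
                    theta = np.mod(np.arctan2(Yw, Xw) - sect0[iz], 2.0 * math.pi)
                    in_sector = theta < 2.0 * math.pi * frac
                    compact = (d > r) & (d <= r + t) & ~in_sector
                    decomp = (d > r) & (d <= r + DECOMPACTION_WIDENING * t) & in_sector
                else:
                    compact = (d > r) & (d <= r + t)
                    decomp = np.zeros_like(compact)
                if win[axon_mask | compact | decomp].any():
                    raise PhantomOverlapError(
                        f"axon {axon_id} overlaps existing labels at z={iz}"
                    )
                win[compact] = axon_id + COMPACT_OFFSET
                win[decomp] = axon_id + DECOMPACTED_OFFSET
            elif win[axon_mask].any():
                raise PhantomOverlapError(
                    f"axon {axon_id} overlaps existing labels at z={iz}"
                )
            win[axon_mask] = axon_id

    # mitochondria: interior ellipsoids overwriting axon voxels
    mito_id = 0
    for i, spec in enumerate(config.axons):
        axon_id = i + 1
        cx, cy, radius, _, _, _ = designs[i]
        for mz, span in spec.mitochondria:
            mito_id += 1
            label = MITO_BASE + mito_id
            half = span / 2.0
            in_span = [
                iz for iz in range(nz) if abs(z_um[iz] - mz) <= half
            ]
            if not in_span:
                continue
            mr_max = min(config.mito_radius_um, 0.45 * radius[in_span].min())
            first = last = None
            for iz in in_span:
                u = (z_um[iz] - mz) / half if half > 0 else 0.0
                mr = mr_max * math.sqrt(max(0.0, 1.0 - u * u))
                if mr < max(sp.dx_um, sp.dy_um):
                    continue
                j0 = max(0, int((cy[iz] - mr) / sp.dy_um) - 1)
                j1 = min(ny, int((cy[iz] + mr) / sp.dy_um) + 2)
                k0 = max(0, int((cx[iz] - mr) / sp.dx_um) - 1)
                k1 = min(nx, int((cx[iz] + mr) / sp.dx_um) + 2)
                d = np.hypot(X[j0:j1, k0:k1] - cx[iz], Y[j0:j1, k0:k1] - cy[iz])
                m = d <= mr
                win = stack[iz][j0:j1, k0:k1]
                if not np.all(win[m] == axon_id):
                    raise PhantomOverlapError(
                        f"mitochondrion {mito_id} escapes axon {axon_id} at z={iz}"
                    )
                win[m] = label
                first = iz if first is None else first
                last = iz
            mito_rows.append(
                {
                    "mito_id": label,
                    "axon_id": axon_id,
                    "center_z_um": mz,
                    "span_um": span,
                    "first_slice": first,
                    "last_slice": last,
                }
            )

    truth = PhantomTruth(
        profiles=pd.DataFrame(profile_rows),
        nodes=pd.DataFrame(node_rows, columns=["axon_id", "center_z_um", "gap_um"]),
        mitos=pd.DataFrame(
            mito_rows,
            columns=[
                "mito_id", "axon_id", "center_z_um", "span_um",
                "first_slice", "last_slice",
            ],
        ),
    )
    volume = LabelVolume(stack=stack, spacing=sp)
    return volume, truth


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

#: condition parameters behind the two presets.  "injured" raises decompaction
#: coverage and angular extent past the 40% scoring threshold, lengthens the
#: paranodal gap, shortens nodal mitochondria and weakens the
#: caliber-thickness coupling, mirroring the direction of the injury effects.
PRESET_PARAMS = {
    "normal": dict(
        decompaction_coverage=0.02,
        decompaction_fraction=0.2,
        paranodal_gap_um=1.5,
        paranodal_gap_sd_um=0.3,
        mito_mean_um=1.4,
        mito_sd_um=0.2,
        r2_target=0.45,
    ),
    "injured": dict(
        decompaction_coverage=0.25,
        decompaction_fraction=0.45,
        paranodal_gap_um=3.0,
        paranodal_gap_sd_um=0.5,
        mito_mean_um=0.8,
        mito_sd_um=0.15,
        r2_target=0.25,
    ),
}

# preset-level child streams (disjoint from the generation streams above)
_SHARED, _CONDITION, _SPANS = 101, 102, 103


def thickness_noise_for_r2(
    axons: list[AxonSpec], z_extent_um: float, r2_target: float, n_grid: int = 512
) -> float:
    """Noise SD bringing the diameter-thickness R² on the designed profiles
    to approximately ``r2_target``.

    With thickness = g*d + c + eps, R² = g²·var(d) / (g²·var(d) + var(eps));
    var(d) is evaluated over the designed (noise-free) diameter profiles of
    the whole cohort, so between-axon caliber differences count as signal.
    """
    if not (0.0 < r2_target < 1.0):
        raise ValueError("r2_target must be in (0, 1)")
    z = np.linspace(0.0, z_extent_um, n_grid)
    diameters = []
    slopes = []
    for spec in axons:
        r = spec.base_radius_um * (
            1.0
            + spec.radius_variation
            * np.sin(2.0 * math.pi * z / spec.radius_period_um + spec.radius_phase)
        )
        diameters.append(2.0 * r)
        slopes.append(spec.thickness_slope)
    d = np.concatenate(diameters)
    g = float(np.mean(slopes))
    var_signal = g * g * float(np.var(d))
    return math.sqrt(var_signal * (1.0 - r2_target) / r2_target)


def preset(
    name: str,
    n_axons: int = 1,
    seed: int = 0,
    shape: tuple[int, int, int] = TEST_SHAPE,
    spacing: VoxelSpacing = TEST_SPACING,
) -> PhantomConfig:
    """Build a PhantomConfig for the "normal" or "injured" study condition.

    Axon-level randomness (base caliber, caliber phase, node position,
    mitochondrion placement) is drawn from child generators keyed by
    ``(seed, axon_index)``; the same seed therefore yields matched axons
    across the two presets, differing only in condition parameters.
    """
    if name not in PRESET_PARAMS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESET_PARAMS)}")
    params = PRESET_PARAMS[name]
    z_extent = shape[0] * spacing.dz_um

    axons: list[AxonSpec] = []
    for i in range(n_axons):
        shared = _child_rng(seed, i, _SHARED)
        base_r = shared.uniform(0.38, 0.55)
        period = shared.uniform(14.0, 24.0)
        phase = shared.uniform(0.0, 2.0 * math.pi)
        node_z = shared.uniform(0.35, 0.65) * z_extent
        n_mito = int(shared.integers(1, 3))

        cond = _child_rng(seed, i, _CONDITION)
        gap = float(
            np.clip(
                cond.normal(params["paranodal_gap_um"], params["paranodal_gap_sd_um"]),
                8.0 * spacing.dz_um,
                None,
            )
        )
        mitos = []
        # alternate sides of the node so mitochondrion spans never overlap
        for k in range(n_mito):
            span = float(
                np.clip(
                    cond.normal(params["mito_mean_um"], params["mito_sd_um"]),
                    3.0 * spacing.dz_um,
                    None,
                )
            )
            offset = cond.uniform(2.0, 6.0) * (1 if k % 2 == 0 else -1)
            mz = float(np.clip(node_z + offset, span, z_extent - span))
            mitos.append((mz, span))

        spans_rng = _child_rng(seed, i, _SPANS)
        spans = _decompaction_spans(
            spans_rng,
            z_extent,
            params["decompaction_coverage"],
            params["decompaction_fraction"],
            node_z,
            gap,
        )
        axons.append(
            AxonSpec(
                base_radius_um=base_r,
                radius_variation=0.25,
                radius_period_um=period,
                radius_phase=phase,
                max_tilt_deg=8.0,
                decompaction_spans=spans,
                nodes=[(node_z, gap)],
                mitochondria=mitos,
            )
        )
    noise = thickness_noise_for_r2(axons, z_extent, params["r2_target"])
    axons = [replace(a, thickness_noise_sd_um=noise) for a in axons]
    return PhantomConfig(shape=shape, spacing=spacing, axons=axons, seed=seed)


def _decompaction_spans(
    rng: np.random.Generator,
    z_extent: float,
    coverage: float,
    fraction: float,
    node_z: float,
    gap: float,
) -> list[tuple[float, float, float]]:
    """Spans totalling ``coverage`` of the z-extent, avoiding the node gap."""
    total = coverage * z_extent
    spans: list[tuple[float, float, float]] = []
    n_patches = max(1, int(round(total / 2.5)))
    patch = total / n_patches
    for _ in range(n_patches):
        for _attempt in range(50):
            z0 = rng.uniform(0.0, z_extent - patch)
            z1 = z0 + patch
            clear_of_node = z1 < node_z - gap / 2 - 0.5 or z0 > node_z + gap / 2 + 0.5
            if clear_of_node and all(
                z1 < a0 - 0.5 or z0 > a1 + 0.5 for a0, a1, _ in spans
            ):
                spans.append((z0, z1, fraction))
                break
    return spans
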