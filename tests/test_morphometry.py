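import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonmorph.io import VoxelSpacing
from axonmorph.morphometry import (
    CrossSection,
    brute_force_min_width,
    cross_section,
    cross_sectional_area,
    decompaction_percent,
    fiber_diameter,
    g_ratio,
    measure_cross_section,
    min_caliper_diameter,
    myelin_thickness,
)

SP20 = VoxelSpacing(20, 20, 100)


def ellipse_mask(a_um, b_um, theta, n=192, px_um=0.02):
    ys, xs = np.mgrid[0:n, 0:n]
    x = (xs + 0.5) * px_um - n * px_um / 2
    y = (ys + 0.5) * px_um - n * px_um / 2
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    return (xr / a_um) ** 2 + (yr / b_um) ** 2 <= 1


def annulus_section(inner_um, outer_um, n=192, px_um=0.02, decomp_sector=None):
    """CrossSection with a circular axon and (optionally sectored) annulus."""
    ys, xs = np.mgrid[0:n, 0:n]
    c = n * px_um / 2
    x = (xs + 0.5) * px_um - c
    y = (ys + 0.5) * px_um - c
    d = np.hypot(x, y)
    axon = d <= inner_um
    ring = (d > inner_um) & (d <= outer_um)
    decomp = np.zeros_like(ring)
    if decomp_sector is not None:
        theta0, frac = decomp_sector
        ang = np.mod(np.arctan2(y, x) - theta0, 2 * math.pi)
        decomp = ring & (ang < 2 * math.pi * frac)
    return CrossSection(
        axon_id=1, z_index=0, axon_mask=axon,
        compact_mask=ring & ~decomp, decompacted_mask=decomp,
        centroid_um=(c, c), spacing=VoxelSpacing(px_um * 1000, px_um * 1000, 100),
    )


class TestArea:
    def test_voxel_count_arithmetic(self):
        """100 voxels at 20x20 nm make 0.04 µm²."""
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        cs = CrossSection(1, 0, mask, np.zeros_like(mask), np.zeros_like(mask),
                          (0.1, 0.1), SP20)
        assert cross_sectional_area(cs) == pytest.approx(0.04)

    def test_disk_closed_form(self):
        cs = annulus_section(0.5, 0.5)
        bound = 2 * 4e-4 + 2 * math.pi * 0.5 * 0.02
        assert abs(cross_sectional_area(cs) - math.pi * 0.25) <= bound

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            CrossSection(1, 0, np.zeros((4, 4), bool), np.zeros((4, 4), bool),
                         np.zeros((4, 4), bool), (0, 0), SP20)


class TestMinCaliper:
    def test_rectangle_short_side(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:35] = True  # 10 x 30 voxels
        assert min_caliper_diameter(mask, SP20) == pytest.approx(0.2)

    def test_single_voxel(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        sp = VoxelSpacing(20, 30, 100)
        assert min_caliper_diameter(mask, sp) == pytest.approx(0.02)

    @pytest.mark.parametrize("theta", [0.0, 0.4, 1.1, 2.0])
    def test_rotated_ellipse_minor_axis(self, theta):
        # centre-inside rasterization covers the ellipse with whole voxel
        # squares, so the width can exceed 2b by up to the voxel footprint
        # (dx|cos| + dy|sin| <= sqrt(2) px) in the minimum direction
        mask = ellipse_mask(1.0, 0.4, theta)
        assert min_caliper_diameter(mask, SP20) == pytest.approx(
            0.8, abs=0.02 * math.sqrt(2)
        )

    def test_matches_sweep_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = ellipse_mask(rng.uniform(0.3, 1.2), rng.uniform(0.3, 1.2),
                                rng.uniform(0, math.pi))
            exact = min_caliper_diameter(mask, SP20)
            sweep = brute_force_min_width(mask, SP20, refine=True)
            assert exact == pytest.approx(sweep, abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_never_exceeds_grid_sweep(self, seed):
        """The exact minimum width can never exceed any directional width."""
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24), bool)
        pts = rng.integers(4, 20, size=(rng.integers(2, 12), 2))
        mask[pts[:, 0], pts[:, 1]] = True
        exact = min_caliper_diameter(mask, SP20)
        assert exact <= brute_force_min_width(mask, SP20) + 1e-9

    def test_obliquity_invariance(self):
        """A 40°-tilted 0.5 µm cylinder still measures 1.0 µm minimum
        diameter, even though its section is a stretched ellipse."""
        r = 0.5
        tilt = math.radians(40)
        mask = ellipse_mask(r / math.cos(tilt), r, 0.7)
        assert min_caliper_diameter(mask, SP20) == pytest.approx(1.0, abs=0.02)


class TestMyelinThickness:
    def test_annulus_closed_form(self):
        cs = annulus_section(0.5, 0.8)
        assert myelin_thickness(cs) == pytest.approx(0.3, abs=0.02)

    def test_no_myelin_returns_zero(self):
        cs = annulus_section(0.5, 0.5)
        assert myelin_thickness(cs) == 0.0

    def test_partial_wrap_below_half_is_nodal(self):
        cs = annulus_section(0.5, 0.8)
        n = cs.axon_mask.shape[0]
        ys, xs = np.mgrid[0:n, 0:n]
        c = cs.centroid_um[0]
        theta = np.arctan2((ys + 0.5) * 0.02 - c, (xs + 0.5) * 0.02 - c)
        keep = theta < (-math.pi + 2 * math.pi * 0.4)  # keep 40% of the ring
        cs.compact_mask &= keep
        assert myelin_thickness(cs) == 0.0

    def test_decompacted_sector_does_not_raise_minimum(self):
        cs = annulus_section(0.5, 0.8, decomp_sector=(0.3, 0.4))
        # widen the decompacted sector outward by 1.5x as the generator does
        wide = annulus_section(0.5, 0.95, decomp_sector=(0.3, 0.4))
        cs.decompacted_mask |= wide.decompacted_mask
        assert myelin_thickness(cs) == pytest.approx(0.3, abs=0.02)


class TestFiberAndGRatio:
    def test_annulus_fiber_diameter(self):
        cs = annulus_section(0.5, 0.8)
        assert fiber_diameter(cs) == pytest.approx(1.6, abs=0.02)

    def test_unmyelinated_fiber_equals_axon(self):
        cs = annulus_section(0.5, 0.5)
        assert fiber_diameter(cs) == min_caliper_diameter(cs.axon_mask, cs.spacing)

    def test_quotient(self):
        assert g_ratio(1.0, 1.25) == pytest.approx(0.8)
        assert g_ratio(0.7, 0.7) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            g_ratio(1.25, 1.0)
        with pytest.raises(ValueError):
            g_ratio(1.0, 0.0)


class TestDecompaction:
    def test_no_decompaction(self):
        assert decompaction_percent(annulus_section(0.5, 0.8)) == 0.0

    def test_fully_decompacted(self):
        cs = annulus_section(0.5, 0.8, decomp_sector=(0.0, 1.0))
        assert decompaction_percent(cs) == 100.0

    @pytest.mark.parametrize("frac", [0.25, 0.5])
    def test_sector_fraction(self, frac):
        cs = annulus_section(0.5, 0.8, decomp_sector=(1.0, frac))
        assert decompaction_percent(cs) == pytest.approx(100 * frac, abs=2.0)


class TestRotationInvariance:
    def test_quarter_turn_exact(self, straight_phantom):
        _, volume, _ = straight_phantom
        cs = cross_section(volume, 1, 100)
        rot = CrossSection(
            axon_id=1, z_index=100,
            axon_mask=np.rot90(cs.axon_mask).copy(),
            compact_mask=np.rot90(cs.compact_mask).copy(),
            decompacted_mask=np.rot90(cs.decompacted_mask).copy(),
            centroid_um=cs.centroid_um, spacing=cs.spacing,
        )
        ys, xs = np.nonzero(rot.axon_mask)
        rot.centroid_um = ((xs.mean() + 0.5) * 0.02, (ys.mean() + 0.5) * 0.02)
        assert cross_sectional_area(rot) == cross_sectional_area(cs)
        assert min_caliper_diameter(rot.axon_mask, cs.spacing) == pytest.approx(
            min_caliper_diameter(cs.axon_mask, cs.spacing), abs=1e-12
        )
        assert myelin_thickness(rot) == pytest.approx(myelin_thickness(cs),
                                                      abs=0.02)


def test_full_measurement_invariants(straight_phantom):
    """fiber >= axon >= pixel; g in (0,1]; decompaction in [0,100]."""
    _, volume, _ = straight_phantom
    for z in range(0, 200, 10):
        cs = cross_section(volume, 1, z)
        m = measure_cross_section(cs)
        assert m.fiber_diameter_um >= m.axon_diameter_um >= 0.02
        assert 0 < m.g_ratio <= 1
        assert 0 <= m.decompaction_pct <= 100
        assert m.area_um2 > 0
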