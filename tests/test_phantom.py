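import math

import numpy as np
import pytest
from scipy import ndimage

from axonmorph.io import VoxelSpacing
from axonmorph.phantom import (
    AxonSpec,
    PhantomConfig,
    PRESET_PARAMS,
    generate_phantom,
    preset,
    thickness_noise_for_r2,
)


class TestThicknessRule:
    def test_linear_caliber_coupling(self, straight_phantom):
        """A 0.5 µm-radius axon gets a 0.20*1.0 + 0.13 = 0.33 µm sheath."""
        _, _, truth = straight_phantom
        p = truth.axon_profile(1)
        myelinated = p[p.thickness_um > 0]
        assert myelinated.thickness_um.unique() == pytest.approx([0.33])

    def test_thickness_zero_inside_node_gap(self, straight_phantom):
        _, _, truth = straight_phantom
        p = truth.axon_profile(1)
        in_gap = (p.z_um - 10.0).abs() <= 1.0
        assert (p.thickness_um[in_gap] == 0).all()
        assert (p.thickness_um[~in_gap] > 0).all()


class TestDeterminism:
    def test_identical_config_identical_volume(self):
        config = PhantomConfig(
            shape=(40, 128, 128),
            axons=[AxonSpec(base_radius_um=0.4, max_tilt_deg=10.0)],
            seed=5,
        )
        v1, t1 = generate_phantom(config)
        v2, t2 = generate_phantom(config)
        np.testing.assert_array_equal(v1.stack, v2.stack)
        assert t1.profiles.equals(t2.profiles)

    def test_seeds_change_centerline_not_radius_stats(self):
        def run(seed):
            config = PhantomConfig(
                shape=(300, 128, 128),  # 30 µm: three full caliber cycles
                axons=[AxonSpec(base_radius_um=0.4, radius_period_um=10.0,
                                max_tilt_deg=10.0)],
                seed=seed,
            )
            _, truth = generate_phantom(config)
            return truth.axon_profile(1)

        a, b = run(1), run(2)
        assert not np.allclose(a.cx_um, b.cx_um)
        # same design distribution: radii agree in mean and spread
        assert a.radius_um.mean() == pytest.approx(b.radius_um.mean(), rel=0.05)
        assert a.radius_um.std() == pytest.approx(b.radius_um.std(), rel=0.2)


class TestRasterization:
    def test_class_disjointness_and_mito_containment(self, straight_phantom):
        _, volume, _ = straight_phantom
        axon = volume.class_mask("axon")
        compact = volume.class_mask("compact_myelin")
        decomp = volume.class_mask("decompacted_myelin")
        mito = volume.class_mask("mitochondrion")
        assert not (axon & compact).any()
        assert not (axon & decomp).any()
        assert not (compact & decomp).any()
        assert not (mito & (compact | decomp)).any()
        # mitochondria live strictly inside the axon: hole-filling the axon
        # mask swallows every mitochondrion voxel
        for z in np.flatnonzero(mito.any(axis=(1, 2))):
            filled = ndimage.binary_fill_holes(axon[z])
            assert (filled[mito[z]]).all()

    def test_area_consistent_with_design_radius(self, straight_phantom):
        """Rasterized axon area tracks pi*r^2 within the discretization bound."""
        _, volume, truth = straight_phantom
        sp = volume.spacing
        px = sp.pixel_area_um2
        p = truth.axon_profile(1)
        for z in range(0, 200, 25):
            n_vox = int(np.count_nonzero(volume.stack[z] == 1)
                        + np.count_nonzero(volume.class_mask("mitochondrion", z)))
            r = p.radius_um[z]
            bound = 2 * px + 2 * math.pi * r * max(sp.dx_um, sp.dy_um)
            assert abs(n_vox * px - math.pi * r**2) <= bound

    def test_zero_axons_gives_empty_volume(self):
        config = PhantomConfig(shape=(10, 32, 32), axons=[], seed=0)
        volume, truth = generate_phantom(config)
        assert volume.stack.sum() == 0
        assert truth.profiles.empty and truth.nodes.empty and truth.mitos.empty

    def test_radius_floor_enforced(self):
        config = PhantomConfig(
            shape=(10, 64, 64),
            spacing=VoxelSpacing(20, 20, 100),
            axons=[AxonSpec(base_radius_um=0.03, radius_variation=0.0)],
        )
        with pytest.raises(ValueError, match="floor"):
            generate_phantom(config)

    def test_overcrowded_field_rejected(self):
        config = PhantomConfig(
            shape=(10, 64, 64),  # 1.28 µm field cannot hold 4 myelinated axons
            axons=[AxonSpec(base_radius_um=0.4) for _ in range(4)],
        )
        with pytest.raises(ValueError, match="fit"):
            generate_phantom(config)


class TestPresets:
    def test_normal_decompaction_coverage(self):
        config = preset("normal", seed=0)
        z_extent = config.z_extent_um()
        covered = sum(z1 - z0 for z0, z1, _ in config.axons[0].decompaction_spans)
        assert covered == pytest.approx(0.02 * z_extent, rel=0.2)

    def test_injured_gap_exceeds_normal(self):
        for seed in range(5):
            g_n = preset("normal", seed=seed).axons[0].nodes[0][1]
            g_i = preset("injured", seed=seed).axons[0].nodes[0][1]
            assert g_i > g_n

    def test_injured_mitochondria_shorter(self):
        spans_n = [s for _, s in preset("normal", n_axons=10, seed=1).axons[0].mitochondria]
        spans_i = [s for _, s in preset("injured", n_axons=10, seed=1).axons[0].mitochondria]
        assert np.mean(spans_i) < np.mean(spans_n)

    def test_matched_geometry_across_conditions(self):
        """Same seed -> same axon caliber and node position in both groups."""
        a = preset("normal", seed=9).axons[0]
        b = preset("injured", seed=9).axons[0]
        assert a.base_radius_um == b.base_radius_um
        assert a.nodes[0][0] == b.nodes[0][0]

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="sham"):
            preset("sham")

    def test_injured_noise_exceeds_normal(self):
        n = preset("normal", seed=0).axons[0].thickness_noise_sd_um
        i = preset("injured", seed=0).axons[0].thickness_noise_sd_um
        assert i > n > 0


def test_noise_sd_hits_r2_target():
    """Designed noise yields the requested R² on the design itself."""
    axons = [AxonSpec(base_radius_um=r, radius_phase=p)
             for r, p in [(0.4, 0.0), (0.5, 1.0), (0.45, 2.0)]]
    for target in (0.25, 0.45):
        sd = thickness_noise_for_r2(axons, 40.0, target)
        z = np.linspace(0, 40.0, 2000)
        rng = np.random.default_rng(0)
        d = np.concatenate(
            [2 * a.base_radius_um
             * (1 + a.radius_variation * np.sin(2 * np.pi * z / a.radius_period_um
                                                + a.radius_phase))
             for a in axons]
        )
        y = 0.2 * d + 0.13 + rng.normal(0, sd, size=d.size)
        r = np.corrcoef(d, y)[0, 1]
        assert r**2 == pytest.approx(target, abs=0.06)
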