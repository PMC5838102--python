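import numpy as np
import pytest

from axonmorph.io import VoxelSpacing
from axonmorph.phantom import AxonSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """One straight axon, constant radius 0.5 µm, with a node (gap 2 µm),
    one mitochondrion (span 1 µm) and a half-circumference decompaction
    patch — the basic known-geometry fixture."""
    config = PhantomConfig(
        shape=(200, 192, 192),
        spacing=VoxelSpacing(20, 20, 100),
        axons=[
            AxonSpec(
                base_radius_um=0.5,
                radius_variation=0.0,
                max_tilt_deg=0.0,
                nodes=[(10.0, 2.0)],
                mitochondria=[(5.0, 1.0)],
                decompaction_spans=[(14.0, 16.0, 0.5)],
            )
        ],
        seed=1,
    )
    volume, truth = generate_phantom(config)
    return config, volume, truth


@pytest.fixture(scope="session")
def three_axon_phantom():
    """Three small tortuous axons sharing one volume."""
    spec = dict(base_radius_um=0.28, radius_variation=0.2, max_tilt_deg=5.0)
    config = PhantomConfig(
        shape=(60, 160, 160),
        spacing=VoxelSpacing(20, 20, 100),
        axons=[AxonSpec(**spec) for _ in range(3)],
        seed=3,
    )
    volume, truth = generate_phantom(config)
    return config, volume, truth


def disk_mask(shape, center_yx, radius_px):
    ys, xs = np.ogrid[: shape[0], : shape[1]]
    return (ys - center_yx[0]) ** 2 + (xs - center_yx[1]) ** 2 <= radius_px**2
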