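import dataclasses

import numpy as np
import pytest

from tracenet import gabor, network as nw, stimuli


@pytest.fixture(scope="session")
def flag_set():
    """Small flag corpus: 4 countries x 5 windspeeds x 2 views at 64 px."""
    return stimuli.generate_flag_set(4, image_size=64, seed=1)


@pytest.fixture(scope="session")
def figure_set():
    """Figure corpus: 3 individuals x 3 poses x 12 views at 64 px."""
    return stimuli.generate_figure_set(3, n_views=12, image_size=64, seed=1)


@pytest.fixture(scope="session")
def tiny_bank():
    spec = gabor.GaborBankSpec(
        image_size=32,
        orientations=(0.0, 90.0),
        spatial_frequencies=(0.25, 0.125),
        phases=(0.0, 90.0),
        grid_stride=8,
    )
    return gabor.build_gabor_bank(spec)


@pytest.fixture(scope="session")
def small_network(tiny_bank):
    """An 8x8-per-layer hierarchy matched to the tiny Gabor bank."""
    configs = [
        nw.LayerConfig(8, 8, 20, convergence_radius=1.6),
        nw.LayerConfig(8, 8, 20, convergence_radius=4.5),
        nw.LayerConfig(8, 8, 20, convergence_radius=5.5),
        nw.LayerConfig(8, 8, 20, convergence_radius=7.0),
    ]
    return nw.init_network(
        configs,
        tiny_bank.layout.grid_shape,
        tiny_bank.layout.channels_per_position,
        seed=11,
    )
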