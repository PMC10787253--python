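"""Shared fixtures: small synthetic slides generated once per session.

Slides are kept small (512 px base) so the whole suite runs quickly; the
generator itself is exercised at other sizes in its own tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from histotile import SynthParams, generate_slide, write_pyramidal_tiff


@pytest.fixture(scope="session")
def small_slide():
    """A 512x512 two-level slide, uniform 0.5 nuclei coverage."""
    params = SynthParams(
        base_size=(512, 512),
        downsamples=(1, 4),
        nuclei_density_map=np.full((2, 2), 0.5),
        seed=7,
    )
    return generate_slide(params)


@pytest.fixture(scope="session")
def small_pyramid(small_slide):
    return small_slide[0]


@pytest.fixture(scope="session")
def ground_truth(small_slide):
    return small_slide[1]


@pytest.fixture(scope="session")
def slide_tiff(small_pyramid, tmp_path_factory):
    """The small slide written out as a pyramidal TIFF."""
    path = tmp_path_factory.mktemp("slides") / "small.tiff"
    write_pyramidal_tiff(small_pyramid, path)
    return path


@pytest.fixture(scope="session")
def blank_slide():
    """A 256x256 three-level slide with no nuclei."""
    params = SynthParams(
        base_size=(256, 256),
        downsamples=(1, 2, 4),
        nuclei_density_map=np.zeros((1, 1)),
        seed=0,
    )
    return generate_slide(params)
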