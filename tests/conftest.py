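import numpy as np
import pytest

from ciliaquant import DetectionParams, SceneSpec, render_stack
from ciliaquant.detection import extract_maxima, filter_stack


@pytest.fixture(scope="session")
def noiseless_scene():
    """A 4-cell, 30-centrioles-per-cell noiseless scene shared across tests."""
    spec = SceneSpec(seed=1)
    channels, truth = render_stack(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def detected_noiseless(noiseless_scene):
    """Centrin detections on the noiseless scene with default parameters."""
    _, channels, truth = noiseless_scene
    params = DetectionParams()
    spots = extract_maxima(filter_stack(channels["centrin"], params), params)
    return spots, truth, params
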