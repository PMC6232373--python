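import numpy as np
import pytest

from neuroscreen.detection import DetectionParams, detect_neurites, segment_somata, trace_and_link
from neuroscreen.synthetic import SceneSpec, generate_culture_image


@pytest.fixture(scope="session")
def culture_scene():
    """One default sparse-culture scene with ground truth."""
    spec = SceneSpec()
    stack, truth = generate_culture_image(spec, seed=42)
    return spec, stack, truth


@pytest.fixture(scope="session")
def detection_results(culture_scene):
    """Full detection chain on the default scene."""
    spec, stack, truth = culture_scene
    params = DetectionParams()
    soma_mask, stubs = segment_somata(stack, params)
    skeleton = detect_neurites(stack, soma_mask, params)
    neurites, cells, qc = trace_and_link(skeleton, soma_mask, params, spec.pixel_size_um)
    return {
        "params": params,
        "soma_mask": soma_mask,
        "stubs": stubs,
        "skeleton": skeleton,
        "neurites": neurites,
        "cells": cells,
        "qc": qc,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
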