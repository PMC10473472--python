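import numpy as np
import pytest

from lentikit.synthetic_data import SceneSpec, generate_surface_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default scene (mature-fruit conditions), shared across tests."""
    spec = SceneSpec(seed=42)
    bf, fl, truth = generate_surface_scene(spec)
    return spec, bf, fl, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def match_to_truth(regions, truth):
    """Pair each detected region with the nearest planted lenticel."""
    pairs = []
    for reg in regions:
        x, y = reg.centroid_mm
        planted = min(
            truth.lenticels, key=lambda l: (l.x_mm - x) ** 2 + (l.y_mm - y) ** 2
        )
        pairs.append((reg, planted))
    return pairs
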