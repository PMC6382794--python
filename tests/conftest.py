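import math

import numpy as np
import pytest

from copemorph import Configuration, LandmarkScheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_scheme():
    return LandmarkScheme(name="tri", k=3)


@pytest.fixture
def square_scheme():
    return LandmarkScheme(name="sq", k=4, symmetry="matching",
                          adjacency=((0, 1), (1, 2), (2, 3), (3, 0)))


@pytest.fixture
def octagon_scheme():
    """Eight landmarks on a closed outline (used widely as a generic shape)."""
    return LandmarkScheme(name="oct", k=8, symmetry="matching",
                          adjacency=tuple((i, (i + 1) % 8) for i in range(8)))


def octagon(aspect=0.7):
    ang = 2 * math.pi * np.arange(8) / 8
    pts = np.stack([np.cos(ang), aspect * np.sin(ang)], axis=1)
    return pts - pts.mean(axis=0)


@pytest.fixture
def octagon_coords():
    return octagon()


def random_config(rng, k=8, scale=1.0, name="s", structure="oct", side="none",
                  image_rep=1, digit_rep=1):
    coords = rng.normal(0.0, 1.0, (k, 2)) * scale
    return Configuration(specimen_id=name, structure=structure, side=side,
                         image_rep=image_rep, digit_rep=digit_rep, coords=coords)


def similarity_transform(coords, angle, scale, shift):
    rot = np.array([[math.cos(angle), math.sin(angle)],
                    [-math.sin(angle), math.cos(angle)]])
    return scale * coords @ rot + np.asarray(shift)
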