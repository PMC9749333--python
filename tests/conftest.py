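import numpy as np
import pandas as pd
import pytest

from mpis.features import feature_catalog
from mpis.synthetic import ShapeSpec, TextureParams, gen_slide


@pytest.fixture(scope="session")
def catalog_ids():
    return [d.canonical_id for d in feature_catalog()]


@pytest.fixture(scope="session")
def small_slide():
    """512x512 slide: dark blobby tumor disc on a lighter textured tissue."""
    tumor = TextureParams(pattern="blobs", intensity_low=40,
                          intensity_high=120, seed=1)
    background = TextureParams(pattern="gaussian_field", intensity_low=150,
                               intensity_high=220, seed=2)
    shape = ShapeSpec(kind="disc", center=(256, 256), radius=160)
    slide, tumor_mask, tissue_mask = gen_slide(tumor, background, (512, 512),
                                               shape)
    return slide, tumor_mask, tissue_mask


def random_masked_tile(rng, max_side=8, n_gray=16):
    """A random quantized tile with a random (nonempty) validity mask."""
    from mpis.features import QuantizedTile
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = rng.integers(1, n_gray + 1, size=(h, w))
    valid = rng.random((h, w)) < 0.8
    if not valid.any():
        valid[0, 0] = True
    return QuantizedTile(levels=levels, valid=valid, n_gray=n_gray)
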