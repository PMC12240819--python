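"""Shared desk-size landscape configuration for the example scripts."""

import math

from coretrans import LandscapeConfig


def small(**overrides) -> LandscapeConfig:
    base = dict(
        grid_rows=24, grid_cols=24, n_regions=4, species_per_region=60,
        range_size_mu=math.log(45.0), range_size_sigma=0.5, seed=7,
    )
    base.update(overrides)
    return LandscapeConfig(**base)
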