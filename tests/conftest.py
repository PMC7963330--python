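import dataclasses

import numpy as np
import pytest

from astroglia_age.presets import (AstrocytePreset, CaMoviePreset,
                                   EphysPreset, LtpPreset)


@pytest.fixture(scope="session")
def mini_astro_preset():
    """Small, fast astrocyte preset for structural tests: shallow tree,
    no leaflet blobs, quarter-size field of view."""
    return AstrocytePreset(
        n_primary=7, branch_length_mean=9.0, branch_length_sd=1.0,
        length_draw_mean=None, branch_order_depth=1, bifurcation_prob=0.0,
        walk_jitter=0.1, domain_radius=13.0, domain_z_radius=6.0,
        soma_radius=3.5, leaflet_vf=0.005, haze_sleeve_radius=2.0,
        shape=(16, 160, 160))


@pytest.fixture(scope="session")
def quiet_ephys_preset():
    return dataclasses.replace(EphysPreset(), noise_sigma=0.0,
                               cap_transient_amp=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
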