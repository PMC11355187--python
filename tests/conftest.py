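"""Shared fixtures: session-scoped synthetic renders reused across tests.

The default geometry/config pair is the package's reference study condition;
the "fast" config uses a coarser 0.3 mm pitch so that sweeps stay cheap
while exercising the identical code path.
"""

from __future__ import annotations

import numpy as np
import pytest

from phantomqc import (PhantomGeometry, SimulationConfig, analyze_image,
                       locate_inserts, render_phantom)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def fast_config():
    """Coarse-pitch configuration for quick renders."""
    return SimulationConfig(pixel_spacing_mm=0.3, seed=11)


@pytest.fixture(scope="session")
def sharp_noiseless(geometry):
    """Criterion-grade slanted edge: sigma 0.5 mm, pitch 0.15 mm, no noise."""
    cfg = SimulationConfig(psf_sigma_mm=0.5, noise_gain=0.0, read_noise_sd=0.0)
    return render_phantom(geometry, cfg) + (cfg,)


@pytest.fixture(scope="session")
def noisy_default(geometry):
    cfg = SimulationConfig(seed=7)
    return render_phantom(geometry, cfg) + (cfg,)


@pytest.fixture(scope="session")
def noisy_default_loc(noisy_default):
    image, _, _ = noisy_default
    return locate_inserts(image)


@pytest.fixture(scope="session")
def noisy_default_iq(noisy_default, noisy_default_loc):
    image, _, _ = noisy_default
    return analyze_image(image, noisy_default_loc)


@pytest.fixture(scope="session")
def fast_noiseless(geometry, fast_config):
    cfg = SimulationConfig(pixel_spacing_mm=0.3, noise_gain=0.0,
                           read_noise_sd=0.0)
    return render_phantom(geometry, cfg) + (cfg,)
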