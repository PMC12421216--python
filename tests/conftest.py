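"""Shared fixtures: the default dynamic phantom and its reconstructions.

The heavier objects (60-frame phantom, k-space, kernel reconstructions at
several reduction factors) are session-scoped so the motility, quality, and
acceptance tests share one computation.
"""

import numpy as np
import pytest

from gastrokt.phantom import PhantomConfig, TissueProperties, generate_phantom, phantom_to_kspace
from gastrokt.pipeline import default_phantom_series
from gastrokt.recon import reconstruct_undersampled
from gastrokt.sampling import SamplingPattern


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_tissue():
    return TissueProperties()


@pytest.fixture(scope="session")
def default_phantom(default_config, default_tissue):
    """Noiseless 60-frame default phantom at gated frame times, with truth."""
    series, truth = default_phantom_series(
        n_frames=60, config=default_config, tissue=default_tissue, return_truth=True
    )
    return series, truth


@pytest.fixture(scope="session")
def default_kspace(default_phantom):
    series, _ = default_phantom
    return phantom_to_kspace(series)


@pytest.fixture(scope="session")
def recon_by_reduction(default_kspace):
    """k-t reconstructions of the default phantom at R in {2, 3, 11}, ACS = 12."""
    out = {}
    for r in (2, 3, 11):
        pattern = SamplingPattern(n_pe=default_kspace.n_pe, n_acs=12, reduction=r)
        img, report = reconstruct_undersampled(default_kspace, pattern)
        out[r] = (img, report)
    return out


@pytest.fixture(scope="session")
def static_tube_config():
    """A straight static tube: the ellipsoids are shrunk inside the tube so the
    lumen is a pure cylinder along the antral axis (radius 3 mm)."""
    return PhantomConfig(
        fundus_center=(10.0, 10.0, 3.0),
        fundus_semiaxes=(0.5, 0.5, 0.5),
        corpus_center=(12.0, 10.0, 3.0),
        corpus_semiaxes=(0.5, 0.5, 0.5),
        antrum_axis=((4.0, 10.0, 3.0), (29.0, 10.0, 3.0)),
        antrum_radius=2.6,
        contraction_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def static_tube(static_tube_config):
    series, truth = generate_phantom(
        static_tube_config, TissueProperties(), np.arange(8) * 2.0, return_truth=True
    )
    return series, truth
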