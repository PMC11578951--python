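import numpy as np
import pytest

from braincontrol import pipeline as pl


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic study (24 STN / 15 GPi / 29 HC, 90 nodes)."""
    cfg = pl.validate_config({"seed": 11, "cohort": {"include_motion": False}})
    return pl.simulate_stage(cfg)


@pytest.fixture(scope="session")
def default_profiles(default_cohort):
    """Connectivity → controllability profiles and deltas for the shared cohort."""
    fcs = pl.compute_connectivity(default_cohort, pl.ProcessingConfig())
    profiles, deltas = pl.compute_profiles(fcs)
    return profiles, deltas


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_stable_dynamics(rng, n):
    """Random symmetric matrix passed through the package's stabilization."""
    from braincontrol.control import stabilize

    m = rng.standard_normal((n, n))
    c = (m + m.T) / 2.0
    np.fill_diagonal(c, 0.0)
    return stabilize(c)
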