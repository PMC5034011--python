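import numpy as np
import pytest

from plaquefuse.phantom import (default_config, make_phantom_vessel,
                                render_oct_pullback)


@pytest.fixture(scope="session")
def clean_config():
    """Default study phantom without speckle."""
    return default_config(noise=0.0)


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return make_phantom_vessel(clean_config)


@pytest.fixture(scope="session")
def clean_pullback(clean_truth):
    return render_oct_pullback(clean_truth)


@pytest.fixture(scope="session")
def speckle_config():
    """Default study phantom with speckle amplitude 0.2, fixed seed."""
    return default_config(noise=0.2, seed=1)


@pytest.fixture(scope="session")
def speckle_truth(speckle_config):
    return make_phantom_vessel(speckle_config)


@pytest.fixture(scope="session")
def speckle_pullback(speckle_truth):
    return render_oct_pullback(speckle_truth)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One shared full pipeline run on the default phantom."""
    from plaquefuse.pipeline import RunConfig, run_pipeline
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(outdir=str(out), seed=1)
    summary = run_pipeline(cfg)
    return out, summary


def truth_thickness_at_profile(truth, profile):
    """Ground-truth thickness at a measured profile's sample angles."""
    cfg = truth.config
    theta_vessel = (profile.alines * 360.0 / cfg.n_alines
                    + truth.rotation_offset_deg[profile.frame_index])
    return truth.thickness_um(
        np.full(profile.alines.size, truth.frame_z_mm[profile.frame_index]),
        theta_vessel)
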