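import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cortexage import (
    AcquisitionProtocol,
    build_phantom,
    calibrate_aging_model,
    synthesize_acquisition,
)
from cortexage.phantom import crop_phantom
from cortexage.relaxometry import fit_qmaps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def aging_model():
    """Aging model calibrated from the reference cohort statistics."""
    return calibrate_aging_model()


@pytest.fixture(scope="session")
def ref_phantom(aging_model):
    """One mid-age phantom with full cortical texture, cropped to the head."""
    ph = build_phantom(45.0, 1, aging_model, seed=11)
    return crop_phantom(ph)


@pytest.fixture(scope="session")
def noiseless_bundle(ref_phantom):
    proto = AcquisitionProtocol().noiseless()
    return synthesize_acquisition(ref_phantom, proto, seed=21)


@pytest.fixture(scope="session")
def noiseless_qmaps(ref_phantom, noiseless_bundle):
    return fit_qmaps(noiseless_bundle, csf_mask=ref_phantom.ventricle_mask)


@pytest.fixture(scope="session")
def noisy_subject(aging_model):
    """A phantom plus SNR-50 bundle and fitted maps (default protocol)."""
    ph = crop_phantom(build_phantom(52.0, 0, aging_model, seed=31))
    bundle = synthesize_acquisition(ph, AcquisitionProtocol(), seed=32)
    qmaps = fit_qmaps(
        bundle, csf_mask=ph.ventricle_mask, floor=3.0 * bundle.noise_sd
    )
    return ph, bundle, qmaps


@pytest.fixture(scope="session")
def recovery():
    """The 20-seed closed-loop recovery experiment at the study scale."""
    from cortexage.closedloop import run_recovery_experiment

    return run_recovery_experiment(base_seed=1234, n_seeds=20, n_subjects=40)


@pytest.fixture(scope="session")
def template_phantom(aging_model):
    """Template ribbon: reference-age phantom without subject variation."""
    import dataclasses

    from cortexage import GeometryConfig

    geo = dataclasses.replace(
        GeometryConfig(),
        center_jitter_vox=0.0,
        rotation_max_deg=0.0,
        scale_sd=0.0,
        sex_scale_effect=0.0,
    )
    ph = build_phantom(45.0, 0, aging_model.noise_free(), geo, seed=0)
    return ph
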