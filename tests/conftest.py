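import pytest
from hypothesis import HealthCheck, settings

from skindx.labels import DiagnosisClass
from skindx.synthdata import SynthConfig, generate_case, generate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synth_config():
    """Default study-condition generator config with a fixed seed."""
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def masked_signal_config():
    """Mask-only-signal conditions: nest sub-type invisible in RGB."""
    return SynthConfig(seed=11, decoy_contrast=0.0,
                       class_proportions=(0.25, 0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def t1b_case(synth_config):
    return generate_case(synth_config, DiagnosisClass.T1b, 3)


@pytest.fixture(scope="session")
def mmd_case(synth_config):
    return generate_case(synth_config, DiagnosisClass.MMD, 1)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, masked_signal_config):
    """16-case on-disk dataset (4 per class) for IO-level tests."""
    root = tmp_path_factory.mktemp("ds16")
    manifest = generate_dataset(masked_signal_config, 16, root)
    return root, manifest
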