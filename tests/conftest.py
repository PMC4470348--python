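import pytest

from unwindfit import GeneratorSpec, fit_joint, generate_dataset

# Fixed seed for the session-wide reference experiment; any seed works,
# the recovery tolerances are far wider than the seed-to-seed scatter.
REFERENCE_SEED = 1234


@pytest.fixture(scope="session")
def reference_dataset():
    """Synthetic triplicate dataset mirroring the 11-donor X-ray design."""
    return generate_dataset(GeneratorSpec(seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def reference_fit(reference_dataset):
    """Joint fit of the reference dataset (shared B, per-donor P0/beta)."""
    return fit_joint(reference_dataset)
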