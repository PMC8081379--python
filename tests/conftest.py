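import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from platmut import synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_reference():
    """100 kb single-contig genome with ~30% gene coverage."""
    return sd.make_reference(100_000, gene_fraction=0.3, gc=0.45, seed=11)


@pytest.fixture(scope="session")
def default_signatures():
    return sd.platinum_like_signature(), sd.background_signature()


@pytest.fixture(scope="session")
def small_cohort(small_reference, default_signatures):
    """A small simulated cohort: truth table plus counts, reused across tests."""
    direct, background = default_signatures
    design = sd.default_design(seed=11, clones_per_group=2, n_control_clones=2)
    truth = sd.plant_mutations(small_reference, design, direct, background)
    counts = sd.emit_counts(small_reference, truth, design, noise_sites=5000)
    return design, truth, counts
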