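import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neosep.classify import classify_samples, composite_groups, dedup_episodes, qc_filter
from neosep.simulate import generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (samples, ground truth), fixed seed."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def deduped(cohort):
    """Classified, QC-filtered, episode-deduplicated sample table."""
    samples, _ = cohort
    return dedup_episodes(qc_filter(classify_samples(samples)))


@pytest.fixture(scope="session")
def flow_set(deduped):
    """Composite Sepsis + No-Sepsis samples entering the cellular screen."""
    groups = composite_groups(deduped)
    return pd.concat([groups["Sepsis"], groups["NoSepsis"]])
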