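import pytest
from hypothesis import HealthCheck, settings

from pearpollen import FloweringStage, StageCounts, load_reference

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def chojuro():
    return load_reference("Chojuro")


@pytest.fixture(scope="session")
def shinko():
    return load_reference("Shinko")


@pytest.fixture(scope="session")
def nepal():
    return load_reference("Nepal")


@pytest.fixture
def detected_counts():
    """Per-stage counts of the worked-example branch as detected (42 flowers)."""
    return StageCounts.from_sequence([13, 9, 16, 3, 1])


@pytest.fixture
def actual_counts():
    """Visually counted per-stage numbers of the same branch set (62 flowers)."""
    return StageCounts.from_sequence([19, 13, 28, 2, 0])


@pytest.fixture
def stages():
    return list(FloweringStage)
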