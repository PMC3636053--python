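import pytest

from pspnet import simulate
from pspnet.datatypes import DetectionProfile, FeatureSet


@pytest.fixture(scope="session")
def preset():
    """The default synthetic study, generated once per session."""
    return simulate.hcc_like(seed=7)


@pytest.fixture
def toy_profiles():
    """2+2 cohort with hand-written detections and ratios."""
    return [
        DetectionProfile("a1", "mod", {"A", "B", "C"}, {"A": 1.2, "B": 0.5}),
        DetectionProfile("a2", "mod", {"A", "B"}, {"A": 1.1}),
        DetectionProfile("b1", "poor", {"C", "D"}, {"C": 2.0}),
        DetectionProfile("b2", "poor", {"D", "E"}, {"D": 1.0}),
    ]


@pytest.fixture
def toy_features():
    return [
        FeatureSet("F1", {"A", "B", "C", "D"}, kind="complex"),
        FeatureSet("F2", {"C", "D", "E", "F", "G"}, kind="complex"),
    ]
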