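import numpy as np
import pytest

from evimap.datamodel import BibRecord, Dataset, EffectRecord


@pytest.fixture
def toy_dataset() -> Dataset:
    """Six effects from four studies over intervention x outcome, with species."""
    effects = [
        EffectRecord("s1", "e1", yi=0.5, vi=0.04, species="A",
                     moderators={"intervention": "CM", "outcome": "QoL"}),
        EffectRecord("s1", "e2", yi=0.3, vi=0.05, species="A",
                     moderators={"intervention": "CM", "outcome": "QoL"}),
        EffectRecord("s2", "e3", yi=0.1, vi=0.02, species="B",
                     moderators={"intervention": "PSM", "outcome": "QoL"}),
        EffectRecord("s3", "e4", yi=-0.2, vi=0.03, species="B",
                     moderators={"intervention": "PSM", "outcome": "AQLQ"}),
        EffectRecord("s4", "e5", yi=0.7, vi=0.06, species="C",
                     moderators={"intervention": "CM", "outcome": "AQLQ"}),
        EffectRecord("s4", "e6", yi=0.4, vi=0.02, species="C",
                     moderators={"intervention": "CM"}),  # missing outcome
    ]
    return Dataset(effects=effects)


@pytest.fixture
def toy_bibliography() -> list[BibRecord]:
    return [
        BibRecord("s1", authors=["smith j", "doe a", "lee c"], year=2019,
                  doi="10.1/s1", countries=["US"], references=["r1", "r2", "r3"]),
        BibRecord("s2", authors=["doe a", "lee c"], year=2020,
                  doi="10.1/s2", countries=["US", "GB"], references=["r2", "r3"]),
        BibRecord("s3", authors=["lee c"], year=2021,
                  doi="10.1/s3", countries=["GB"], references=["r4"]),
        BibRecord("s4", authors=["park m", "kim y"], year=2021,
                  doi="10.1/s4", countries=["KR"], references=["r1", "r4"]),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
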