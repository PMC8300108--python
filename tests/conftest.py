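import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ekss.core import EKSSConfig
from ekss.energy import RequirementConfig
from ekss.microbiome import AbundanceTable


@pytest.fixture
def req_config():
    return RequirementConfig()


@pytest.fixture
def ekss_config():
    return EKSSConfig()


@pytest.fixture
def tiny_table():
    """Four taxa x four samples, two phyla, with labels."""
    counts = pd.DataFrame(
        {
            "s1": [30, 20, 40, 10],
            "s2": [25, 25, 30, 20],
            "s3": [10, 60, 20, 10],
            "s4": [5, 60, 15, 10],
        },
        index=pd.Index(
            [
                "d__Bacteria;p__Firmicutes;c__Clostridia;o__O;f__F;g__GenusA",
                "d__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__O;f__F;g__GenusB",
                "d__Bacteria;p__Firmicutes;c__Bacilli;o__O;f__F;g__GenusC",
                "d__Bacteria;p__Proteobacteria;c__Gamma;o__O;f__F;g__GenusD",
            ],
            name="lineage",
        ),
    )
    labels = pd.Series(
        {"s1": "EK", "s2": "EK", "s3": "HK", "s4": "HK"}, name="group"
    )
    return AbundanceTable(counts=counts, sample_labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
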