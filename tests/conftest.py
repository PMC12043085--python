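import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ieilgl.config import RunConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


def make_germline_row(**overrides) -> dict:
    """A germline variant row passing every filter unless overridden."""
    row = {
        "patient_id": "P001", "gene": "AIRE", "hgvs": "c.100A>G",
        "consequence": "missense", "population_af": 0.005, "acmg": "VUS",
        "zygosity": "het", "vaf": 0.47, "depth": 60, "alt_reads": 28,
        "in_repetitive_region": False, "matches_somatic_call": False,
    }
    row.update(overrides)
    return row


@pytest.fixture
def germline_row():
    return make_germline_row


@pytest.fixture
def small_panel() -> pd.DataFrame:
    return pd.DataFrame({
        "gene": ["AIRE", "BACH2", "PRF1", "TCIRG1", "STK4"],
        "iuis_category": ["immune_dysregulation", "immune_dysregulation",
                          "immune_dysregulation", "phagocyte", "combined_TB"],
        "inheritance": ["AD_AR", "AD", "AR", "AD_AR", "AR"],
        "onset": ["adult", "adult", "adult", "early", "early"],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
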