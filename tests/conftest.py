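import pandas as pd
import pytest

from pmrisk import default_config, huludao
from pmrisk.deposition import default_df_table


@pytest.fixture(scope="session")
def table1_samples() -> pd.DataFrame:
    """Exact-mean pseudo-samples for XP, DD and the pooled study area."""
    return huludao.pseudo_samples()


@pytest.fixture(scope="session")
def two_site_samples() -> pd.DataFrame:
    """Pseudo-samples for the two physical sites only (no pooled row)."""
    return huludao.pseudo_samples(("XP", "DD"))


@pytest.fixture()
def config():
    return default_config()


@pytest.fixture(scope="session")
def df_table() -> pd.DataFrame:
    return default_df_table()


@pytest.fixture(scope="session")
def reported_doses() -> pd.DataFrame:
    return huludao.reported_dose_table()
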