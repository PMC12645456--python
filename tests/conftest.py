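import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from seismobiome import synthetic
from seismobiome.community import OtuTable
from seismobiome.geochem import AnalyteTable


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic input bundle shared across tests."""
    return synthetic.simulate_bundle(seed=0)


@pytest.fixture(scope="session")
def table1_sulfide():
    """Unfiltered / filtered sulfide (µM) by Julian day, as printed in the study table."""
    days = [147, 174, 237, 279, 307]
    unfilt = [10.3, 44.8, 57.8, 62.5, 43.2]
    filt = [3.1, 26.6, 44.3, 49.0, 34.4]
    return pd.DataFrame({"HS_unfilt": unfilt, "HS_filt": filt}, index=days)


@pytest.fixture(scope="session")
def table1_h2():
    """Dissolved H2 (µM) by Julian day; maximum 44.0 on day 237."""
    return pd.Series([30.6, 26.7, 44.0, 41.6, 23.4], index=[147, 174, 237, 279, 307])


@pytest.fixture()
def small_otu_table():
    """5 OTUs × 3 days with known singleton and annotation structure."""
    days = [147, 174, 237]
    ab = pd.DataFrame(
        {
            147: [10.0, 5.0, 0.0, 1.0, 2.0],
            174: [8.0, 0.0, 3.0, 1.5, 0.0],
            237: [12.0, 0.0, 4.0, 0.5, 0.0],
        },
        index=[f"otu{i}" for i in range(5)],
    )[days]
    ann = pd.DataFrame(
        {
            "autotroph": [True, False, True, False, False],
            "nife_hydrogenases": [1, 0, 0, 0, 0],
            "fefe_hydrogenases": [2, 0, 0, 0, 1],
            "taxonomy": ["a", "b", "c", "d", "e"],
        },
        index=ab.index,
    )
    return OtuTable(abundance=ab, annotations=ann)


def make_analyte_table(values: dict, index, bd: dict | None = None, pairs: dict | None = None):
    """Helper: build an AnalyteTable from plain dicts; NaN cells count as BD."""
    df = pd.DataFrame(values, index=index, dtype=float)
    mask = df.isna()
    if bd:
        for col, flags in bd.items():
            mask[col] = np.asarray(flags, dtype=bool)
    return AnalyteTable(values=df.where(~mask), bd_mask=mask, filtered_variant_map=pairs or {})
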