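import numpy as np
import pandas as pd
import pytest

from ringsense.ring_io import RingSeries
from ringsense.synthetic_data import generate_study_fixture


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Small synthetic study bundle (6 species x 5 trees x 50 years)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_study_fixture(11, outdir, scale="small")


@pytest.fixture
def constant_series():
    return RingSeries("CONST", np.arange(1960, 2010), np.ones(50), "CONS", "CONST")


def make_series(series_id, first_year, widths, species="TEST", tree=None, to_pith=True):
    widths = np.asarray(widths, dtype=float)
    years = np.arange(first_year, first_year + len(widths))
    return RingSeries(series_id, years, widths, species, tree or series_id, to_pith)


def make_monthly_frame(years, tmean=10.0, precip=70.0, frost=0, pet=None):
    """Uniform monthly climate frame for hand-built fixtures."""
    rows = []
    for yr in years:
        for mo in range(1, 13):
            row = {"year": yr, "month": mo, "tmean": tmean, "precip": precip,
                   "frost_days": frost}
            if pet is not None:
                row["pet"] = pet
                row["d"] = precip - pet
            rows.append(row)
    return pd.DataFrame(rows)
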