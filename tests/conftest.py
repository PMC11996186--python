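import pandas as pd
import pytest

from aicm import brazil2015
from aicm.case_selection import link_ans, select_ans, select_sus
from aicm.synthetic_data import MarginSpec, generate_ans, generate_dataset, generate_sus

SEED = 20150


@pytest.fixture(scope="session")
def national_spec() -> MarginSpec:
    """Default study conditions: the 2015 national margins, exact mode."""
    return MarginSpec(seed=SEED)


@pytest.fixture(scope="session")
def sus_microdata(national_spec):
    return generate_sus(national_spec)


@pytest.fixture(scope="session")
def ans_microdata(national_spec):
    return generate_ans(national_spec)


@pytest.fixture(scope="session")
def ans_linkage(ans_microdata):
    cons, det = ans_microdata
    return link_ans(cons, det, year=brazil2015.YEAR)


@pytest.fixture(scope="session")
def sus_counts(sus_microdata):
    return select_sus(sus_microdata, year=brazil2015.YEAR)


@pytest.fixture(scope="session")
def ans_counts_icd(ans_linkage):
    return select_ans(ans_linkage, mode="icd_only")


@pytest.fixture(scope="session")
def ans_counts_both(ans_linkage):
    return select_ans(ans_linkage, mode="icd_or_procedure")


@pytest.fixture(scope="session")
def ans_counts_fine(ans_linkage):
    return select_ans(ans_linkage, mode="icd_or_procedure", fine=True)


@pytest.fixture(scope="session")
def dataset_dir(national_spec, tmp_path_factory):
    """The five-file CSV dataset of a full national run."""
    outdir = tmp_path_factory.mktemp("national")
    generate_dataset(national_spec, outdir)
    return outdir


def make_sus_frame(rows):
    """Build a small admissions frame from (region, age, diags, year) tuples."""
    out = []
    for region, age, diags, year in rows:
        diags = (list(diags) + [""] * 5)[:5]
        out.append([region, age, *diags, year])
    return pd.DataFrame(
        out,
        columns=["region", "age", "diag1", "diag2", "diag3", "diag4", "diag5",
                 "year"],
    )


def make_cons_frame(rows):
    """Build a consolidated-events frame from (event_id, region, band, icds, year)."""
    out = []
    for event_id, region, band, icds, year in rows:
        icds = (list(icds) + [""] * 4)[:4]
        out.append([event_id, region, band, *icds, year])
    return pd.DataFrame(
        out,
        columns=["event_id", "region", "age_band", "icd1", "icd2", "icd3",
                 "icd4", "year"],
    )


def make_det_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "procedure_code"])
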