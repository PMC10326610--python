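import numpy as np
import pandas as pd
import pytest

from ednadiv import (
    CommunityMatrix,
    SampleInfo,
    load_historical_checklist,
    load_table1_fixture,
)
from ednadiv.otu import AnnotatedOtuTable, OtuRow

#: Section codes in the order of the bundled survey table.
SECTIONS = ["HJD", "PD", "YZD", "DF", "WJD", "SFY", "GPT", "SL", "ST", "PS", "YP", "FL"]


@pytest.fixture(scope="session")
def survey():
    """The bundled 97-species x 12-section reference survey."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def survey_matrix(survey):
    return survey[0]


@pytest.fixture(scope="session")
def survey_records(survey):
    return survey[1]


@pytest.fixture(scope="session")
def historical_checklist():
    return load_historical_checklist()


@pytest.fixture
def small_matrix():
    """3 taxa x 4 samples: 2 sections x 2 replicates."""
    counts = pd.DataFrame(
        {
            "A_r1": [5, 0, 2],
            "A_r2": [3, 1, 0],
            "B_r1": [0, 4, 4],
            "B_r2": [2, 2, 2],
        },
        index=pd.Index(["t1", "t2", "t3"], name="taxon_id"),
    )
    samples = [
        SampleInfo("A_r1", "A", 1),
        SampleInfo("A_r2", "A", 2),
        SampleInfo("B_r1", "B", 1),
        SampleInfo("B_r2", "B", 2),
    ]
    return CommunityMatrix(counts, samples)


def make_otu_table(rows, n_samples=2, sections=None):
    """Build an AnnotatedOtuTable from (otu_id, counts, taxon, ident, ev, target)."""
    if sections is None:
        samples = [SampleInfo(f"s{i + 1}", f"s{i + 1}") for i in range(n_samples)]
    else:
        samples = [
            SampleInfo(f"{sec}_r{r + 1}", sec, r + 1)
            for sec, reps in sections
            for r in range(reps)
        ]
    return AnnotatedOtuTable(
        [OtuRow(*row) for row in rows],
        samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
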