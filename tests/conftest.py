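import numpy as np
import pandas as pd
import pytest

from daphnofit.datatypes import LifeHistoryRecord, OtuTable


@pytest.fixture
def toy_otu_table():
    """3 samples x 4 OTUs with full taxonomy and metadata."""
    counts = pd.DataFrame(
        [[10, 5, 0, 1], [8, 0, 4, 2], [0, 6, 3, 1]],
        index=["s1", "s2", "s3"],
        columns=["OTU1", "OTU2", "OTU3", "OTU4"],
    )
    taxonomy = pd.DataFrame(
        {"phylum": ["P1", "P1", "P2", "P2"],
         "family": ["F1", "F1", "F2", "F3"],
         "genus": ["G1", "G2", "G3", "G3"]},
        index=counts.columns)
    meta = pd.DataFrame(
        {"treatment": [0.0, 0.1, 1.0], "clutch": [1, 1, 2], "day": [9, 9, 12]},
        index=counts.index)
    return OtuTable(counts, taxonomy, meta)


def make_record(i="a", treatment=0.0, last_day=21, event=False,
                clutches=(), lengths=()):
    return LifeHistoryRecord(individual_id=i, treatment=treatment,
                             last_day=last_day, event=event,
                             clutches=clutches, lengths=lengths)


@pytest.fixture
def five_animal_cohort():
    """Deaths at days 2 and 4, one censor at day 3, two censored at 21."""
    return [
        make_record("a", last_day=2, event=True),
        make_record("b", last_day=4, event=True),
        make_record("c", last_day=3, event=False),
        make_record("d", last_day=21, event=False),
        make_record("e", last_day=21, event=False),
    ]
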