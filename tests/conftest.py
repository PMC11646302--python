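import logging

import numpy as np
import pandas as pd
import pytest

from otucurate import synthetic
from otucurate.filtering import OtuAnnotation, OtuTable

logging.getLogger("otucurate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-spec synthetic dataset shared across read-only tests."""
    return synthetic.generate_dataset(synthetic.CommunitySpec(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_dataset):
    d = tmp_path_factory.mktemp("fixture")
    synthetic.write_fixture(default_dataset, d)
    return d


@pytest.fixture
def toy_table():
    """3 OTUs x (2 samples as replicate pairs + 2 negatives)."""
    counts = pd.DataFrame(
        {
            "s1_A": [3, 0, 0],
            "s1_B": [4, 7, 0],
            "s2_A": [10, 2, 1],
            "s2_B": [5, 3, 1],
            "n1": [2, 0, 5],
            "n2": [4, 0, 3],
        },
        index=["otuA", "otuB", "otuC"],
        dtype=np.int64,
    )
    return OtuTable(counts, {"s1": ("s1_A", "s1_B"), "s2": ("s2_A", "s2_B")}, ["n1", "n2"])


def make_annotation(otu_id, species="", order="Diptera", family="Famidae",
                    klass="Insecta", sequence="ATT" * 68 + "A"):
    genus = species.split(" ")[0] if species else ""
    return OtuAnnotation(otu_id, sequence, {
        "phylum": "Arthropoda", "class": klass, "order": order,
        "family": family, "genus": genus, "species": species,
    })
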