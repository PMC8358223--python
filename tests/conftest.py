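import numpy as np
import pandas as pd
import pytest

from pantrait.datatypes import FunctionTable
from pantrait.simulate import study_config


@pytest.fixture
def rng():
    return np.random.default_rng(20210603)


@pytest.fixture
def small_function_table() -> FunctionTable:
    rows = [
        ("g1", "carbohydrates", "fermentation", "mixed acid", "acetate kinase"),
        ("g1", "carbohydrates", "fermentation", "mixed acid", "acetate kinase"),
        ("g1", "carbohydrates", "no subcategory", "orphan sugars", "sugar kinase X"),
        ("g1", "nitrogen metabolism", "ammonia assimilation", "nitrosative stress", "flavohemoglobin"),
        ("g2", "nucleosides and nucleotides", "detoxification", "nudix", "adp-ribose hydrolase"),
        ("g2", "nucleosides and nucleotides", "no subcategory", "orphans", "mystery nucleotidase"),
        ("g2", "nucleosides and nucleotides", "purines", "purine biosynthesis", "amidophosphoribosyltransferase"),
        ("g2", "virulence, disease and defense", "resistance", "beta-lactamase", "penicillinase"),
        ("g2", "amino acids and derivatives", "histidine metabolism", "his operon", "histidinol dehydrogenase"),
    ]
    return FunctionTable(
        pd.DataFrame(rows, columns=["genome_id", "category", "subcategory", "subsystem", "role"])
    )


@pytest.fixture(scope="session")
def sim_config():
    return study_config(seed=7)


@pytest.fixture(scope="session")
def sim_tree(sim_config):
    from pantrait.simulate import simulate_tree

    return simulate_tree(sim_config)
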