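import pandas as pd
import pytest

from droughtrank import datasets
from droughtrank.trait_io import TraitDescriptor, trait_table_from_frame


@pytest.fixture(scope="session")
def table2_ci():
    """Published comprehensive-index triples, indexed by treatment."""
    return datasets.load_comprehensive_indices()


@pytest.fixture(scope="session")
def table2_published():
    """Published membership values, D values and ranks."""
    return datasets.load_published_scores()


@pytest.fixture(scope="session")
def table2_weights():
    """Published index weights (0.770, 0.140, 0.09)."""
    return datasets.load_index_weights()


@pytest.fixture
def small_trait_table():
    """3 treatments x 2 traits x 3 replicates with hand-checkable values."""
    rows = []
    values = {
        ("A", "growth"): [1.0, 2.0, 3.0],
        ("B", "growth"): [5.0, 5.0, 5.0],
        ("C", "growth"): [7.0, 8.0, 9.0],
        ("A", "damage"): [9.0, 9.5, 10.0],
        ("B", "damage"): [6.0, 6.0, 6.0],
        ("C", "damage"): [1.0, 2.0, 3.0],
    }
    for (treatment, trait), vals in values.items():
        for i, v in enumerate(vals, start=1):
            rows.append((treatment, f"r{i}", trait, v))
    frame = pd.DataFrame(rows, columns=["treatment", "replicate", "trait", "value"])
    traits = [
        TraitDescriptor("growth", "g", "benefit"),
        TraitDescriptor("damage", "nmol g-1", "cost"),
    ]
    return trait_table_from_frame(frame, traits)
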