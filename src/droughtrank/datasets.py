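"""Loaders for the small packaged reference tables.

Two published tables from the motivating study ship with the package as
plain CSV: the photosynthetic summary (mean ± SE per treatment and
gas-exchange trait) and the comprehensive-evaluation table (per-treatment
comprehensive indices CI1-CI3 with the published membership values, index
weights, D values and ranks).  They serve as worked examples and as the
ground truth for reproduction tests; the full 18-trait replicate-level
matrix was never published and is therefore not packaged.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_photosynthesis_summary",
    "load_comprehensive_indices",
    "load_published_scores",
    "load_index_weights",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("droughtrank.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_photosynthesis_summary() -> pd.DataFrame:
    """Published gas-exchange summary: treatment, trait, mean, se, stars.

    Nine treatments (eight fungal inoculation strains plus the
    non-inoculated control CK) by four traits: net photosynthetic rate (Pn),
    stomatal conductance (Gs), intercellular CO2 concentration (Ci),
    transpiration rate (Tr); n = 3 replicates behind each mean.
    """
    return _read("table1_photosynthesis.csv")


def load_comprehensive_indices() -> pd.DataFrame:
    """Published CI1-CI3 per treatment, indexed by treatment label."""
    return _read("table2_comprehensive_indices.csv").set_index("treatment")


def load_published_scores() -> pd.DataFrame:
    """Published membership values, D values and ranks, indexed by treatment."""
    return _read("table2_published_scores.csv").set_index("treatment")


def load_index_weights() -> list[float]:
    """Published index weights for the three retained components."""
    return _read("table2_index_weights.csv")["weight"].tolist()
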