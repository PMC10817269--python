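"""Reading, validation and summarisation of trait tables."""

import numpy as np
import pandas as pd
import pytest

from droughtrank import datasets
from droughtrank.trait_io import (
    SchemaError,
    TraitDescriptor,
    read_trait_table,
    trait_table_from_frame,
    treatment_means,
)


def _write_long(tmp_path, df, name="traits.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def long_frame():
    rows = [
        (t, f"r{r}", trait, 10.0 * i + r)
        for i, t in enumerate(["A", "B", "C"])
        for r in (1, 2, 3)
        for trait in ("x", "y")
    ]
    return pd.DataFrame(rows, columns=["treatment", "replicate", "trait", "value"])


class TestReadTraitTable:
    def test_long_roundtrip(self, tmp_path, long_frame):
        table = read_trait_table(_write_long(tmp_path, long_frame))
        assert table.treatments == ["A", "B", "C"]
        assert table.trait_names == ["x", "y"]
        assert len(table.data) == 18

    def test_column_mapping(self, tmp_path, long_frame):
        renamed = long_frame.rename(columns={"treatment": "strain", "value": "obs"})
        path = _write_long(tmp_path, renamed)
        schema = {"columns": {"treatment": "strain", "value": "obs"}}
        table = read_trait_table(path, schema)
        assert table.treatments == ["A", "B", "C"]

    def test_wide_format_matches_long(self, tmp_path, long_frame):
        wide = long_frame.pivot_table(
            index=["treatment", "replicate"], columns="trait", values="value"
        ).reset_index()
        path = tmp_path / "wide.csv"
        wide.to_csv(path, index=False)
        table = read_trait_table(path, {"format": "wide"})
        means = treatment_means(table).mean
        expected = treatment_means(
            trait_table_from_frame(long_frame)
        ).mean
        pd.testing.assert_frame_equal(
            means.sort_index(axis=1), expected.sort_index(axis=1)
        )

    def test_missing_column_named_in_error(self, tmp_path, long_frame):
        path = _write_long(tmp_path, long_frame.drop(columns=["value"]))
        with pytest.raises(SchemaError, match="value"):
            read_trait_table(path)

    def test_non_numeric_value_reports_row(self, tmp_path, long_frame):
        bad = long_frame.astype({"value": object})
        bad.loc[4, "value"] = "oops"
        with pytest.raises(SchemaError, match="row 4"):
            read_trait_table(_write_long(tmp_path, bad))

    def test_duplicate_triple_rejected(self, tmp_path, long_frame):
        dup = pd.concat([long_frame, long_frame.iloc[[0]]])
        with pytest.raises(SchemaError, match="duplicated"):
            read_trait_table(_write_long(tmp_path, dup))

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError, match="empty"):
            read_trait_table(path)

    def test_duplicate_wide_trait_column_rejected(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text("treatment,replicate,x,x\nA,r1,1,2\nB,r1,3,4\n")
        with pytest.raises(SchemaError, match="duplicated trait column"):
            read_trait_table(path, {"format": "wide"})

    def test_single_treatment_rejected(self, tmp_path, long_frame):
        solo = long_frame[long_frame["treatment"] == "A"]
        with pytest.raises(SchemaError, match="2 treatments"):
            read_trait_table(_write_long(tmp_path, solo))

    def test_orientation_from_schema(self, tmp_path, long_frame):
        schema = {
            "traits": [
                {"name": "x", "orientation": "benefit"},
                {"name": "y", "orientation": "cost", "unit": "nmol"},
            ]
        }
        table = read_trait_table(_write_long(tmp_path, long_frame), schema)
        signs = table.orientation_signs()
        assert signs["x"] == 1.0 and signs["y"] == -1.0

    def test_bad_orientation_rejected(self):
        with pytest.raises(SchemaError, match="orientation"):
            TraitDescriptor("x", orientation="sideways")


class TestTreatmentMeans:
    def test_published_summary_cell(self):
        """The packaged gas-exchange fixture carries mean 3.58, se 0.12 for
        the top-ranked strain's net photosynthetic rate — the convention the
        summariser must reproduce from replicates."""
        summary = datasets.load_photosynthesis_summary()
        row = summary.query("treatment == 'Jacg121' and trait == 'Pn'").iloc[0]
        assert row["mean"] == 3.58 and row["se"] == 0.12
        # reconstruct replicates with exactly that mean and SE, re-summarise
        m, se = row["mean"], row["se"]
        sd = se * np.sqrt(3)
        reps = np.array([m - sd, m, m + sd])  # sample sd of (m-d, m, m+d) is d
        frame = pd.DataFrame(
            {
                "treatment": ["Jacg121"] * 3 + ["CK"] * 3,
                "replicate": ["r1", "r2", "r3"] * 2,
                "trait": "Pn",
                "value": np.concatenate([reps, [1.08] * 3]),
            }
        )
        mm = treatment_means(trait_table_from_frame(frame))
        assert mm.mean.loc["Jacg121", "Pn"] == pytest.approx(3.58)
        assert mm.se.loc["Jacg121", "Pn"] == pytest.approx(0.12)

    def test_hand_arithmetic(self, small_trait_table):
        mm = treatment_means(small_trait_table)
        assert mm.mean.loc["A", "growth"] == pytest.approx(2.0)
        # sd(1,2,3) = 1 -> se = 1/sqrt(3)
        assert mm.se.loc["A", "growth"] == pytest.approx(0.57735, abs=1e-4)
        assert mm.n.loc["A", "growth"] == 3

    def test_constant_replicates_zero_se(self, small_trait_table):
        mm = treatment_means(small_trait_table)
        assert mm.mean.loc["B", "growth"] == 5.0
        assert mm.se.loc["B", "growth"] == 0.0

    def test_row_permutation_invariance(self, small_trait_table):
        shuffled = trait_table_from_frame(
            small_trait_table.data.sample(frac=1.0, random_state=7),
            small_trait_table.traits,
        )
        a, b = treatment_means(small_trait_table), treatment_means(shuffled)
        pd.testing.assert_frame_equal(
            a.mean.sort_index().sort_index(axis=1),
            b.mean.sort_index().sort_index(axis=1),
        )

    def test_single_replicate_se_undefined(self):
        frame = pd.DataFrame(
            {
                "treatment": ["A", "B"],
                "replicate": ["r1", "r1"],
                "trait": ["x", "x"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.warns(UserWarning, match="SE is undefined"):
            mm = treatment_means(trait_table_from_frame(frame))
        assert np.isnan(mm.se.loc["A", "x"])
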