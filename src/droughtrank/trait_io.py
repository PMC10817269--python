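"""Reading and summarising treatment × replicate × trait tables.

The evaluation pipeline consumes replicate-level physiological measurements
(water contents, gas-exchange parameters, osmolytes, antioxidant enzyme
activities, ...) recorded for a set of treatments — typically fungal
inoculation strains plus a non-inoculated control — with a small number of
biological replicates each.  This module reads such tables from CSV/TSV in
long or wide layout, validates them into a :class:`TraitTable`, and collapses
replicates into the treatment-mean matrix (:class:`MeanMatrix`) that the
scoring stages operate on.

Long format is canonical: one row per (treatment, replicate, trait) with a
numeric value.  A wide table (one column per trait) is converted to long form
before validation, so both layouts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitDescriptor",
    "TraitTable",
    "MeanMatrix",
    "SchemaError",
    "read_trait_table",
    "trait_table_from_frame",
    "treatment_means",
    "load_schema",
]

#: columns of the canonical long layout
LONG_COLUMNS = ("treatment", "replicate", "trait", "value")

VALID_ORIENTATIONS = frozenset({"benefit", "cost"})


class SchemaError(ValueError):
    """Input file or column-mapping config violates the expected schema."""


@dataclass(frozen=True)
class TraitDescriptor:
    """A measured trait: its name, unit string, and scoring orientation.

    ``orientation`` is ``"benefit"`` when larger values indicate better
    performance under stress (photosynthetic rate, proline, ...) and
    ``"cost"`` when smaller values do (e.g. malondialdehyde, a lipid
    peroxidation marker).  The orientation is used by the synthetic-data
    generator and to orient principal-component signs; it must be declared
    explicitly because it cannot be inferred from the numbers.
    """

    name: str
    unit: str = ""
    orientation: str = "benefit"

    def __post_init__(self) -> None:
        if self.orientation not in VALID_ORIENTATIONS:
            raise SchemaError(
                f"trait {self.name!r}: orientation must be one of "
                f"{sorted(VALID_ORIENTATIONS)}, got {self.orientation!r}"
            )


@dataclass
class TraitTable:
    """Validated replicate-level measurements in long form.

    Attributes
    ----------
    data : pandas.DataFrame
        Long-format frame with columns ``treatment, replicate, trait, value``;
        exactly one row per (treatment, replicate, trait) triple.
    traits : list of TraitDescriptor
        One descriptor per unique trait, in first-appearance order.
    """

    data: pd.DataFrame
    traits: list[TraitDescriptor] = field(default_factory=list)

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data["treatment"]))

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def orientation_signs(self) -> pd.Series:
        """+1 for benefit traits, -1 for cost traits, indexed by trait name."""
        return pd.Series(
            {t.name: 1.0 if t.orientation == "benefit" else -1.0 for t in self.traits},
            name="orientation_sign",
        )


@dataclass
class MeanMatrix:
    """Treatment × trait summary: mean, standard error and replicate count.

    ``se`` is the sample standard deviation (n − 1 denominator) divided by
    √n — the "mean ± SE" convention.  Cells with a single replicate carry
    ``se = NaN`` as an undefined marker.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n: pd.DataFrame

    @property
    def treatments(self) -> list[str]:
        return list(self.mean.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.mean.columns)


def load_schema(path) -> dict:
    """Load a YAML/JSON column-mapping config for :func:`read_trait_table`."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError(f"schema file {path} must contain a mapping")
    return schema


def _validate_long(df: pd.DataFrame, traits: list[TraitDescriptor]) -> TraitTable:
    if df.empty:
        raise SchemaError("trait table is empty")
    dup = df.duplicated(subset=["treatment", "replicate", "trait"])
    if dup.any():
        rows = df.loc[dup, ["treatment", "replicate", "trait"]].iloc[0]
        raise SchemaError(
            "duplicated (treatment, replicate, trait) triple: "
            f"({rows['treatment']}, {rows['replicate']}, {rows['trait']})"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"non-numeric value {df['value'].iloc[idx]!r} at input row {idx}")
    if values.isna().any():
        idx = int(np.flatnonzero(values.isna())[0])
        raise SchemaError(f"missing value at input row {idx}")
    df = df.assign(value=values.astype(float))

    if len(df["treatment"].unique()) < 2:
        raise SchemaError("need at least 2 treatments")

    # every treatment must cover every trait with >= 1 replicate
    counts = df.pivot_table(
        index="treatment", columns="trait", values="value", aggfunc="size", fill_value=0
    )
    if (counts == 0).any().any():
        t, tr = next(
            (t, tr) for t in counts.index for tr in counts.columns if counts.loc[t, tr] == 0
        )
        raise SchemaError(f"treatment {t!r} has no replicate for trait {tr!r}")

    names = list(dict.fromkeys(df["trait"]))
    by_name = {t.name: t for t in traits}
    descriptors = [by_name.get(n, TraitDescriptor(n)) for n in names]
    return TraitTable(data=df.reset_index(drop=True), traits=descriptors)


def trait_table_from_frame(
    df: pd.DataFrame, traits: list[TraitDescriptor] | None = None
) -> TraitTable:
    """Validate an in-memory long-format frame into a :class:`TraitTable`."""
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return _validate_long(df[list(LONG_COLUMNS)].copy(), traits or [])


def read_trait_table(path, schema: dict | None = None) -> TraitTable:
    """Read a trait table from CSV/TSV and validate it.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.  Tab delimiters are detected
        from a ``.tsv`` suffix or may be forced with ``schema["sep"]``.
    schema : dict, optional
        Column-mapping config.  Keys (all optional):

        ``format``
            ``"long"`` (default) or ``"wide"``.  Wide format has one row per
            (treatment, replicate) and one column per trait.
        ``columns``
            mapping from canonical names (``treatment``, ``replicate``,
            ``trait``, ``value``) to the file's column names.
        ``traits``
            list of ``{name, unit, orientation}`` mappings declaring trait
            metadata; orientation ∈ {benefit, cost}.
        ``sep``
            field delimiter override.

    Returns
    -------
    TraitTable

    Raises
    ------
    SchemaError
        on a missing column, non-numeric or missing value, duplicated
        (treatment, replicate, trait) triple, or an empty file.
    """
    schema = dict(schema or {})
    sep = schema.get("sep")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc

    colmap = schema.get("columns", {})
    fmt = schema.get("format", "long")
    traits = [
        TraitDescriptor(
            name=str(t["name"]),
            unit=str(t.get("unit", "")),
            orientation=str(t.get("orientation", "benefit")),
        )
        for t in schema.get("traits", [])
    ]

    if fmt == "long":
        rename = {colmap.get(c, c): c for c in LONG_COLUMNS}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df.rename(columns=rename)
        return _validate_long(df[list(LONG_COLUMNS)].copy(), traits)

    if fmt == "wide":
        id_cols = [colmap.get("treatment", "treatment"), colmap.get("replicate", "replicate")]
        missing = [c for c in id_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        # pandas de-duplicates repeated header names on read, so duplicate
        # trait columns must be caught from the raw header line
        with open(path) as fh:
            header = [h.strip() for h in fh.readline().rstrip("\n").split(sep)]
        seen, dups = set(), []
        for c in header:
            if c in seen:
                dups.append(c)
            seen.add(c)
        if dups:
            raise SchemaError(f"duplicated trait column name(s): {', '.join(dups)}")
        trait_cols = [c for c in df.columns if c not in id_cols]
        if not trait_cols:
            raise SchemaError("wide table has no trait columns")
        long = df.melt(
            id_vars=id_cols, value_vars=trait_cols, var_name="trait", value_name="value"
        ).rename(columns={id_cols[0]: "treatment", id_cols[1]: "replicate"})
        return _validate_long(long[list(LONG_COLUMNS)], traits)

    raise SchemaError(f"unknown format {fmt!r}; expected 'long' or 'wide'")


def treatment_means(table: TraitTable) -> MeanMatrix:
    """Collapse replicates into mean ± SE per (treatment, trait) cell.

    SE uses the n − 1 sample standard deviation divided by √n; with a single
    replicate it is reported as NaN (undefined) and a warning is emitted.
    """
    grouped = table.data.groupby(["treatment", "trait"], sort=False)["value"]
    mean = grouped.mean().unstack("trait")
    sd = grouped.std(ddof=1).unstack("trait")
    n = grouped.size().unstack("trait")

    order_t, order_x = table.treatments, table.trait_names
    mean = mean.reindex(index=order_t, columns=order_x)
    sd = sd.reindex(index=order_t, columns=order_x)
    n = n.reindex(index=order_t, columns=order_x).astype(int)

    se = sd / np.sqrt(n)
    if (n == 1).any().any():
        import warnings

        warnings.warn(
            "single-replicate cell(s): SE is undefined (reported as NaN)",
            stacklevel=2,
        )
    return MeanMatrix(mean=mean, se=se, n=n)
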