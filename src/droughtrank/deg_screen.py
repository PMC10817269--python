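"""Fold-change screening of differential-expression tables and set overlaps.

A gene is called differentially expressed when |log2 fold change| meets the
threshold (default 2, i.e. a four-fold change, boundary inclusive) and — if a
significance level is given and the table carries adjusted p values — its
padj falls below that level.  Direction follows the sign of the log2 fold
change, conventionally drought over well-watered.  Pairwise overlaps of DEG
id sets give the usual Venn tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DEGSummary", "OverlapResult", "screen_degs", "overlap"]


@dataclass(frozen=True)
class DEGSummary:
    n_up: int
    n_down: int
    n_total_degs: int
    n_input: int

    def __post_init__(self) -> None:
        assert self.n_up + self.n_down == self.n_total_degs <= self.n_input


@dataclass(frozen=True)
class OverlapResult:
    size_a: int
    size_b: int
    shared: int
    only_a: int
    only_b: int


def screen_degs(
    records: pd.DataFrame,
    lfc_threshold: float = 2.0,
    alpha: float | None = None,
) -> tuple[DEGSummary, pd.DataFrame]:
    """Screen a gene table for DEGs by |log2FC| ≥ threshold (and padj < alpha).

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``gene`` (unique ids), ``log2fc`` (finite), optional ``padj``.
    lfc_threshold : float
        Positive |log2FC| cutoff; genes exactly at the cutoff are retained.
    alpha : float, optional
        If given, additionally require ``padj < alpha`` (the table must then
        carry a ``padj`` column).

    Returns
    -------
    (DEGSummary, DataFrame)
        The tallies and the DEG rows, each labelled ``direction`` up/down.
    """
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0")
    missing = [c for c in ("gene", "log2fc") if c not in records.columns]
    if missing:
        raise ValueError(f"gene table missing column(s): {', '.join(missing)}")
    if records["gene"].duplicated().any():
        dup = records.loc[records["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id: {dup}")
    lfc = records["log2fc"].to_numpy(dtype=float)
    if not np.all(np.isfinite(lfc)):
        raise ValueError("log2fc contains non-finite values")

    keep = np.abs(lfc) >= lfc_threshold
    if alpha is not None:
        if "padj" not in records.columns:
            raise ValueError("alpha given but table has no 'padj' column")
        keep &= records["padj"].to_numpy(dtype=float) < alpha

    degs = records.loc[keep].copy()
    degs["direction"] = np.where(degs["log2fc"] > 0, "up", "down")
    n_up = int((degs["direction"] == "up").sum())
    n_down = int((degs["direction"] == "down").sum())
    summary = DEGSummary(
        n_up=n_up, n_down=n_down, n_total_degs=n_up + n_down, n_input=len(records)
    )
    return summary, degs


def overlap(a, b) -> OverlapResult:
    """Venn tallies for two DEG id sets."""
    a, b = set(a), set(b)
    shared = len(a & b)
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        shared=shared,
        only_a=len(a) - shared,
        only_b=len(b) - shared,
    )
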