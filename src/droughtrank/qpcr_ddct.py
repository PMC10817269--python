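"""Relative gene expression by the Livak 2^-ddCt method.

For a target gene and an internal reference gene (here typically an
aquaporin gene, AQP), each replicate r yields

    dCt_r   = Ct_target,r − Ct_reference,r
    ddCt_r  = dCt_r − mean(dCt over control replicates)
    fold_r  = 2^(−ddCt_r)

and the reported fold change is the mean of the per-replicate fold values,
with its sample standard error — the "mean ± SE of 2^-ddCt" convention.
Averaging on the fold scale (rather than 2^(−mean ddCt)) is the default;
the geometric alternative is available via ``aggregate="mean_ddct"``.

Amplification efficiency is fixed at 2 per the Livak assumption; no
standard-curve correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RelativeExpression", "relative_expression", "validate_ct_table"]

CT_COLUMNS = ("group", "gene", "replicate", "ct")


@dataclass(frozen=True)
class RelativeExpression:
    """Fold change of a target gene in a treated group relative to control."""

    gene: str
    treated: str
    control: str
    fold_change: float
    se: float
    n: int
    #: per-replicate fold values in the treated group (basis of mean and SE)
    replicate_folds: tuple = ()
    #: two-sided t-test p for treated vs control per-replicate folds, if computable
    p_value: float | None = None


def validate_ct_table(ct: pd.DataFrame, reference: str, groups=None) -> pd.DataFrame:
    """Check Ct positivity and reference-gene coverage of every replicate."""
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
    if (ct["ct"] <= 0).any():
        row = ct[ct["ct"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive Ct {row['ct']} for gene {row['gene']} "
            f"({row['group']}, replicate {row['replicate']})"
        )
    sub = ct if groups is None else ct[ct["group"].isin(groups)]
    have_ref = set(
        map(tuple, sub.loc[sub["gene"] == reference, ["group", "replicate"]].to_numpy())
    )
    for g, r in set(map(tuple, sub[["group", "replicate"]].to_numpy())):
        if (g, r) not in have_ref:
            raise ValueError(
                f"reference gene {reference!r} missing in group {g!r}, replicate {r!r}"
            )
    return ct


def _delta_ct(ct: pd.DataFrame, group: str, target: str, reference: str) -> pd.Series:
    sub = ct[ct["group"] == group]
    tgt = sub[sub["gene"] == target].set_index("replicate")["ct"]
    ref = sub[sub["gene"] == reference].set_index("replicate")["ct"]
    if tgt.empty:
        raise ValueError(f"target gene {target!r} absent from group {group!r}")
    dct = (tgt - ref).dropna()
    if dct.empty:
        raise ValueError(
            f"no replicate carries both {target!r} and {reference!r} in group {group!r}"
        )
    return dct


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control: str,
    treated: str,
    *,
    aggregate: str = "mean_fold",
) -> RelativeExpression:
    """2^-ddCt fold change of ``target`` in ``treated`` relative to ``control``.

    Parameters
    ----------
    ct : pandas.DataFrame
        Long table with columns ``group, gene, replicate, ct``.
    aggregate : str
        ``"mean_fold"`` (default): mean over replicates of 2^-ddCt, SE on the
        same values.  ``"mean_ddct"``: 2^(−mean ddCt), the geometric-mean
        form; SE is still reported from the per-replicate fold values.

    Evaluating the control group against itself returns fold change 1 under
    ``mean_ddct`` exactly, and under ``mean_fold`` up to replicate spread.
    """
    validate_ct_table(ct, reference, groups={control, treated})
    dct_control = _delta_ct(ct, control, target, reference)
    dct_treated = _delta_ct(ct, treated, target, reference)

    baseline = dct_control.mean()
    folds_treated = np.power(2.0, -(dct_treated - baseline)).to_numpy()
    folds_control = np.power(2.0, -(dct_control - baseline)).to_numpy()

    n = len(folds_treated)
    if aggregate == "mean_fold":
        fold = float(folds_treated.mean())
    elif aggregate == "mean_ddct":
        fold = float(2.0 ** -(dct_treated.mean() - baseline))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")

    se = float(folds_treated.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    p = None
    if n > 1 and len(folds_control) > 1 and (
        folds_treated.std(ddof=1) > 0 or folds_control.std(ddof=1) > 0
    ):
        p = float(stats.ttest_ind(folds_treated, folds_control).pvalue)

    return RelativeExpression(
        gene=target,
        treated=treated,
        control=control,
        fold_change=fold,
        se=se,
        n=n,
        replicate_folds=tuple(folds_treated),
        p_value=p,
    )
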