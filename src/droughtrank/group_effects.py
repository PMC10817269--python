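"""Treatment-versus-control effect reporting.

Given replicate values for an inoculated treatment and the non-inoculated
control, this module computes the percent change of means, a two-group
significance test, and the conventional star annotation.  Three test methods
are available:

``rank_sum_exact``
    Wilcoxon rank-sum (Mann-Whitney U) with the null distribution obtained by
    enumerating all C(n_a + n_b, n_a) assignments of the observed midranks to
    the two groups.  Feasible and the default for small groups; with tied
    values the enumeration uses the midranks as they stand.
``rank_sum_asymptotic``
    Normal approximation to the rank-sum statistic with the standard tie
    correction and no continuity correction.
``t_test``
    Classical two-sided two-sample Student's t with pooled variance
    (``welch=True`` switches to the unequal-variance form).

With n = 3 per group the exact two-sided rank-sum p cannot fall below
2/20 = 0.1, so small-sample significance claims require either the
asymptotic path or a t test; both are provided and the method used is
recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "EffectResult",
    "percent_change",
    "compare_groups",
    "star_annotation",
    "mann_whitney_u",
    "effect_table",
    "EXACT_GROUP_SIZE_CUTOFF",
]

#: both groups at or below this size -> exact enumeration by default
EXACT_GROUP_SIZE_CUTOFF = 8

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class EffectResult:
    """One treatment-vs-control comparison for one trait."""

    trait: str
    treatment: str
    control: str
    percent_change: float
    method: str
    statistic: float
    p_value: float
    stars: str
    degenerate: bool = False


def percent_change(mean_treatment: float, mean_control: float) -> float:
    """Signed percent change of the treatment mean relative to control.

    ``100 * (treatment - control) / control``; negative when the treatment
    mean is below the control mean.
    """
    if mean_control == 0:
        raise ZeroDivisionError("percent change undefined: control mean is 0")
    return 100.0 * (mean_treatment - mean_control) / mean_control


def star_annotation(p: float) -> str:
    """Map a p value to the conventional significance stars.

    Strict thresholds: ``***`` for p < 0.001, ``**`` for p < 0.01, ``*`` for
    p < 0.05, otherwise the empty string.  Values exactly at a threshold do
    not earn the star.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def mann_whitney_u(a, b) -> float:
    """U statistic for group ``a``: pairwise count of a_i < b_j plus half-ties.

    Equivalently the rank-sum of ``a`` minus its minimum; kept as the direct
    pairwise count so it can serve as its own brute-force definition.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    less = (a[:, None] < b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(less + 0.5 * ties)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Pools both samples, assigns midranks, and enumerates every
    C(n_a + n_b, n_a) way of labelling the pooled midranks as group a.  The
    two-sided p is the fraction of assignments whose rank-sum deviates from
    its null mean by at least the observed deviation.
    """
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    observed = ranks[:n_a].sum()
    center = n_a * (n_a + n_b + 1) / 2.0
    obs_dev = abs(observed - center)

    total = comb(n_a + n_b, n_a)
    extreme = 0
    for idx in combinations(range(n_a + n_b), n_a):
        dev = abs(ranks[list(idx)].sum() - center)
        if dev >= obs_dev - 1e-12:
            extreme += 1
    return float(observed), extreme / total


def _asymptotic_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction, no continuity correction."""
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    rank_sum = ranks[:n_a].sum()
    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(rank_sum), 1.0
    z = (rank_sum - mean) / np.sqrt(var)
    return float(rank_sum), float(2.0 * stats.norm.sf(abs(z)))


def compare_groups(
    a,
    b,
    method: str = "rank_sum",
    *,
    welch: bool = False,
    exact_cutoff: int = EXACT_GROUP_SIZE_CUTOFF,
    trait: str = "",
    treatment: str = "",
    control: str = "",
) -> EffectResult:
    """Two-sided comparison of treatment replicates ``a`` against control ``b``.

    Parameters
    ----------
    a, b : array-like
        Replicate values; ``b`` is the control group (the percent-change
        baseline).
    method : str
        ``"rank_sum"`` (exact when both groups ≤ ``exact_cutoff``, else
        asymptotic), ``"rank_sum_exact"``, ``"rank_sum_asymptotic"`` or
        ``"t_test"``.
    welch : bool
        For ``t_test``, use the unequal-variance (Welch) form instead of the
        pooled-variance form.

    Notes
    -----
    When every value in both groups is identical the comparison is degenerate:
    p = 1 is returned with ``degenerate=True``.  A t test on groups with zero
    within-group variance but different means is likewise flagged degenerate
    (p = 0 in that limit).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method.startswith("rank_sum"):
        if len(a) < 1 or len(b) < 1:
            raise ValueError("rank-sum test needs >= 1 value per group")
    elif method == "t_test":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t test needs >= 2 values per group")
    else:
        raise ValueError(f"unknown method {method!r}")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = percent_change(mean_a, mean_b) if mean_b != 0 else float("nan")

    degenerate = False
    if a.min() == a.max() == b.min() == b.max():
        # every value identical across both groups
        resolved = method if method != "rank_sum" else "rank_sum_exact"
        return EffectResult(
            trait, treatment, control, pct, resolved, 0.0, 1.0, "", degenerate=True
        )

    if method == "rank_sum":
        method = (
            "rank_sum_exact"
            if max(len(a), len(b)) <= exact_cutoff
            else "rank_sum_asymptotic"
        )

    if method == "rank_sum_exact":
        statistic, p = _exact_rank_sum_p(a, b)
    elif method == "rank_sum_asymptotic":
        statistic, p = _asymptotic_rank_sum_p(a, b)
    else:  # t_test
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # distinct constant groups: infinite t in the limit
            degenerate = True
            statistic, p = float("inf") * np.sign(mean_a - mean_b), 0.0
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            statistic, p = float(res.statistic), float(res.pvalue)

    p = min(max(p, 0.0), 1.0)
    return EffectResult(
        trait=trait,
        treatment=treatment,
        control=control,
        percent_change=pct,
        method=method,
        statistic=statistic,
        p_value=p,
        stars=star_annotation(p),
        degenerate=degenerate,
    )


def effect_table(table, control: str, method: str = "rank_sum", **kwargs):
    """Compare every treatment against ``control`` for every trait.

    Parameters
    ----------
    table : TraitTable
        Replicate-level measurements.
    control : str
        Label of the control treatment (e.g. the non-inoculated group).

    Returns
    -------
    pandas.DataFrame
        One row per (treatment, trait) with percent change, statistic,
        p value and stars.
    """
    import pandas as pd

    df = table.data
    if control not in set(df["treatment"]):
        raise ValueError(f"control treatment {control!r} not present")
    rows = []
    for trait in table.trait_names:
        sub = df[df["trait"] == trait]
        ctrl_vals = sub.loc[sub["treatment"] == control, "value"].to_numpy()
        for treatment in table.treatments:
            if treatment == control:
                continue
            vals = sub.loc[sub["treatment"] == treatment, "value"].to_numpy()
            res = compare_groups(
                vals, ctrl_vals, method, trait=trait, treatment=treatment,
                control=control, **kwargs,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
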