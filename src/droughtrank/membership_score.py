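"""Membership scoring, contribution-rate weights, D values and ranking.

This is the composite statistic the package exists for.  Each comprehensive
index column CI_j is mapped onto [0, 1] with the min-max membership function

    μ(X_j) = (CI_j − CI_min) / (CI_max − CI_min),

where CI_min and CI_max are the column extremes across treatments, so the
worst treatment on a component scores 0 and the best scores 1.  Components
are weighted by their share of the retained variance,

    W_j = P_j / Σ P_j        (P_j the contribution rate, retained j only),

and the drought-tolerance score of a treatment is the weighted sum

    D = Σ_j μ(X_j) · W_j,

which lies in [0, 1] whenever the weights sum to 1.  Treatments are ranked
by descending D (rank 1 = most tolerant); ties share the smaller rank
(competition ranking).

Membership is relative to the treatments in the run: adding or removing a
treatment changes the column extremes and therefore every μ and D.  That is
inherent to the method, not an implementation artifact.

Weights can be recomputed from contribution rates or supplied externally
(e.g. the rounded weights printed in a published table); supplied weights
need only sum to 1 within 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import pca_ci
from .trait_io import TraitTable, treatment_means

__all__ = [
    "Weights",
    "DroughtScore",
    "EvaluationReport",
    "membership",
    "weights",
    "d_value",
    "rank_treatments",
    "evaluate_from_ci",
    "run_full_evaluation",
]


@dataclass(frozen=True)
class Weights:
    """Per-component index weights W_j.

    ``source`` records whether the weights were recomputed from contribution
    rates (then they sum to 1 exactly) or supplied from a printed table (then
    the sum is only required to be within [0.98, 1.02], absorbing published
    rounding).
    """

    values: np.ndarray
    source: str = "recomputed_from_rates"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(vals) == 0:
            raise ValueError("empty weight vector")
        if np.any(vals < 0):
            raise ValueError("weights must be non-negative")
        total = vals.sum()
        if self.source == "recomputed_from_rates":
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"recomputed weights must sum to 1, got {total}")
        elif not 0.98 <= total <= 1.02:
            raise ValueError(f"supplied weights sum {total:.4f} outside [0.98, 1.02]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DroughtScore:
    """D values and competition ranks per treatment (rank 1 = most tolerant)."""

    d: pd.Series
    rank: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"D": self.d, "rank": self.rank})


@dataclass
class EvaluationReport:
    """Everything the end-to-end evaluation produces, stage by stage."""

    means: object
    pca: pca_ci.PCAResult | None
    ci: pd.DataFrame
    mu: pd.DataFrame
    weights: Weights
    score: DroughtScore
    config: dict = field(default_factory=dict)

    def summary(self, decimals: int = 3) -> pd.DataFrame:
        """Table-2-style summary: CI columns, μ columns, D and rank.

        Display rounding only; internal values keep full precision.
        """
        out = pd.concat(
            [
                self.ci.round(decimals),
                self.mu.rename(columns=lambda c: c.replace("CI", "mu")).round(decimals),
                self.score.d.round(decimals).rename("D"),
                self.score.rank.rename("rank"),
            ],
            axis=1,
        )
        return out


def membership(ci: pd.DataFrame) -> pd.DataFrame:
    """Min-max membership μ(X_j) of each CI column across treatments.

    Raises
    ------
    ValueError
        when a column is constant (CI_max = CI_min), naming the component.
    """
    lo, hi = ci.min(), ci.max()
    flat = hi - lo
    dead = flat[flat == 0]
    if len(dead):
        raise ValueError(
            f"degenerate CI column(s) with max = min: {', '.join(map(str, dead.index))}"
        )
    mu = (ci - lo) / flat
    return mu.rename(columns=lambda c: str(c).replace("CI", "mu"))


def weights(rates: Sequence[float], source: str = "recomputed_from_rates") -> Weights:
    """W_j = P_j / Σ P_j over the retained components only."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) == 0:
        raise ValueError("empty contribution-rate list")
    if np.any(rates <= 0):
        raise ValueError("contribution rates must be positive")
    return Weights(values=rates / rates.sum(), source=source)


def d_value(mu: pd.DataFrame, w: Weights | Sequence[float]) -> DroughtScore:
    """Weighted membership sum D = Σ_j μ(X_j)·W_j with descending-D ranks."""
    if not isinstance(w, Weights):
        w = Weights(values=np.asarray(w, dtype=float), source="supplied")
    if mu.shape[1] != len(w):
        raise ValueError(
            f"dimension mismatch: {mu.shape[1]} membership columns vs {len(w)} weights"
        )
    d = pd.Series(mu.to_numpy() @ w.values, index=mu.index, name="D")
    return DroughtScore(d=d, rank=_competition_ranks(d))


def _competition_ranks(d: pd.Series) -> pd.Series:
    # descending D; ties share the smaller rank ("1224" ranking)
    ranks = rankdata(-d.to_numpy(), method="min").astype(int)
    return pd.Series(ranks, index=d.index, name="rank")


def rank_treatments(scores: DroughtScore) -> pd.DataFrame:
    """Report ordered by descending D; ties break on label order for display."""
    frame = scores.to_frame()
    # stable sort after an index sort -> ties appear in label order
    return frame.sort_index(kind="stable").sort_values("D", ascending=False, kind="stable")


def evaluate_from_ci(
    ci: pd.DataFrame, w: Weights | Sequence[float]
) -> EvaluationReport:
    """Short-circuit entry: score precomputed comprehensive indices.

    Used to reproduce a published CI table without rerunning the PCA, e.g.
    when only the CI columns and the printed weights are available.
    """
    if not isinstance(w, Weights):
        w = Weights(values=np.asarray(w, dtype=float), source="supplied")
    mu = membership(ci)
    score = d_value(mu, w)
    return EvaluationReport(
        means=None, pca=None, ci=ci, mu=mu, weights=w, score=score,
        config={"entry": "from_ci", "weight_source": w.source},
    )


def run_full_evaluation(
    table: TraitTable,
    *,
    policy: str = "fixed_k",
    k: int = 3,
    threshold: float = 85.0,
    weight_source: str = "recomputed_from_rates",
    supplied_weights: Sequence[float] | None = None,
) -> EvaluationReport:
    """End-to-end evaluation: means → z-scores → PCA → CI → μ → W → D → rank.

    Parameters
    ----------
    table : TraitTable
        Replicate-level measurements.
    policy, k, threshold
        Component-retention policy (see :func:`droughtrank.pca_ci.select_components`).
    weight_source : str
        ``"recomputed_from_rates"`` derives W_j from the retained contribution
        rates; ``"supplied"`` uses ``supplied_weights`` as-is.

    The report is deterministic for a fixed input table and configuration.
    """
    means = treatment_means(table)
    z = pca_ci.standardize(means)
    # cost-type traits enter negated so every component, under the
    # largest-|loading|-positive sign rule, points toward better performance;
    # a z column stays zero-mean unit-variance under negation
    z = z * table.orientation_signs().reindex(z.columns).to_numpy()
    res = pca_ci.pca(z)
    k_used = pca_ci.select_components(res, policy, k=k, threshold=threshold)
    ci = pca_ci.comprehensive_indices(z, res, k_used)
    mu = membership(ci)
    if weight_source == "supplied":
        if supplied_weights is None:
            raise ValueError("weight_source='supplied' needs supplied_weights")
        w = Weights(values=np.asarray(supplied_weights, dtype=float), source="supplied")
    else:
        w = weights(res.contribution_rates[:k_used])
    score = d_value(mu, w)
    config = {
        "policy": policy,
        "k": k_used,
        "threshold": threshold,
        "weight_source": w.source,
    }
    return EvaluationReport(
        means=means, pca=res, ci=ci, mu=mu, weights=w, score=score, config=config
    )
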