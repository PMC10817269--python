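"""Synthetic trait, Ct, and differential-expression tables with known truth.

Every pipeline stage can be exercised without external data: the generators
plant a known signal — a per-treatment tolerance scalar, a fold change, a
DEG label — and emit tables in exactly the schemas the readers consume.

The trait generator follows a latent-factor model.  Each treatment t carries
a tolerance scalar δ_t and each trait a sensitivity; a measurement is

    value(t, r, trait) = baseline + sign · effect · scale · δ_t + ε,
    ε ~ Normal(0, σ · scale),

where ``sign`` is +1 for benefit traits and −1 for cost traits (a
lipid-peroxidation marker falls as tolerance rises), ``scale`` is the
trait's natural spread, ``effect`` the planted effect size in scale units
per unit δ, and σ the replicate noise as a fraction of scale.  At σ = 0 the
trait matrix is an exact monotone image of δ, so the full evaluation must
recover the planted ordering; as σ grows, recovery degrades — the basis of
the parameter-recovery checks.  A second latent factor (independent of δ)
can be switched on to give the trait matrix rank > 1 and exercise
multi-component retention; a heavy-tailed noise option exercises the rank
tests.

The default dimensions mirror the motivating study: 9 treatments (8
inoculation strains plus a non-inoculated control) × 18 traits × 3
replicates, with a trait panel patterned on its measurement set (water
contents, four gas-exchange parameters, osmolytes, MDA, and antioxidant
enzymes in shoot and root).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trait_io import TraitDescriptor, TraitTable, trait_table_from_frame

__all__ = [
    "SimulationConfig",
    "default_trait_panel",
    "simulate_trait_table",
    "simulate_ct_table",
    "simulate_de_table",
]


def default_trait_panel() -> list[tuple[str, str, str, float, float]]:
    """(name, unit, orientation, baseline, scale) for the default 18 traits."""
    panel = [
        ("shoot_water_content", "%", "benefit", 70.0, 6.0),
        ("root_water_content", "%", "benefit", 60.0, 6.0),
        ("Pn", "umol m-2 s-1", "benefit", 1.1, 0.9),
        ("Gs", "mol m-2 s-1", "benefit", 0.010, 0.012),
        ("Ci", "umol mol-1", "benefit", 160.0, 55.0),
        ("Tr", "mmol m-2 s-1", "benefit", 0.9, 0.45),
    ]
    for tissue in ("shoot", "root"):
        panel += [
            (f"{tissue}_Pro", "ug g-1", "benefit", 80.0, 60.0),
            (f"{tissue}_SP", "mg g-1", "benefit", 12.0, 2.0),
            (f"{tissue}_MDA", "nmol g-1", "cost", 25.0, 6.0),
            (f"{tissue}_CAT", "U g-1 min-1", "cost", 180.0, 60.0),
            (f"{tissue}_POD", "U g-1 min-1", "benefit", 300.0, 90.0),
            (f"{tissue}_SOD", "U g-1", "benefit", 220.0, 50.0),
        ]
    return panel


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generators.

    Attributes
    ----------
    n_treatments, n_traits, n_replicates : int
        Table dimensions; defaults 9 × 18 × 3.
    tolerance : ndarray or None
        Planted per-treatment tolerance δ_t.  Default: evenly spaced from 1
        (first treatment, most tolerant) down to 0 (the control, labelled
        ``CK``, least tolerant).
    effect_size : float
        Trait shift per unit δ, in units of the trait's scale.  Default 1.0:
        the most and least tolerant treatments sit one scale apart.
    noise_sd : float
        Replicate noise SD as a fraction of the trait scale.  Default 0.05,
        a replicate scatter of a few percent of the between-treatment spread,
        comparable to the small standard errors typical of n = 3 physiology
        panels.
    n_factors : int
        1 (default) for a single latent tolerance axis; 2 adds an independent
        nuisance factor loading on every other trait so the trait matrix has
        rank > 1.
    heavy_tailed : bool
        Replace Gaussian replicate noise with a t(3) distribution.
    seed : int
        Seed for all randomness.
    """

    n_treatments: int = 9
    n_traits: int = 18
    n_replicates: int = 3
    tolerance: np.ndarray | None = None
    effect_size: float = 1.0
    noise_sd: float = 0.05
    n_factors: int = 1
    heavy_tailed: bool = False
    seed: int = 0
    treatment_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_treatments, self.n_traits, self.n_replicates) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_factors not in (1, 2):
            raise ValueError("n_factors must be 1 or 2")
        if self.tolerance is None:
            self.tolerance = np.linspace(1.0, 0.0, self.n_treatments)
        self.tolerance = np.asarray(self.tolerance, dtype=float)
        if len(self.tolerance) != self.n_treatments:
            raise ValueError("tolerance length must equal n_treatments")
        if not self.treatment_labels:
            self.treatment_labels = [
                f"S{i + 1}" for i in range(self.n_treatments - 1)
            ] + ["CK"]
        if len(self.treatment_labels) != self.n_treatments:
            raise ValueError("treatment_labels length must equal n_treatments")


def _panel(config: SimulationConfig) -> list[tuple[str, str, str, float, float]]:
    base = default_trait_panel()
    if config.n_traits <= len(base):
        return base[: config.n_traits]
    extra = [
        (f"trait_{i + 1}", "", "benefit" if i % 2 == 0 else "cost", 10.0, 2.0)
        for i in range(config.n_traits - len(base))
    ]
    return base + extra


def simulate_trait_table(config: SimulationConfig) -> tuple[TraitTable, pd.Series]:
    """Generate a replicate-level trait table with planted tolerance signal.

    Returns the validated :class:`~droughtrank.trait_io.TraitTable` and the
    ground-truth δ per treatment (the target of parameter recovery).
    """
    rng = np.random.default_rng(config.seed)
    panel = _panel(config)
    delta = config.tolerance
    labels = config.treatment_labels

    # independent nuisance axis, same for all replicates of a treatment
    nuisance = rng.normal(size=config.n_treatments) if config.n_factors == 2 else None

    rows = []
    for ti, label in enumerate(labels):
        for rep in range(1, config.n_replicates + 1):
            for xi, (name, _unit, orientation, baseline, scale) in enumerate(panel):
                sign = 1.0 if orientation == "benefit" else -1.0
                value = baseline + sign * config.effect_size * scale * delta[ti]
                if nuisance is not None and xi % 2 == 1:
                    value += 0.5 * scale * nuisance[ti]
                if config.noise_sd > 0:
                    draw = (
                        rng.standard_t(df=3)
                        if config.heavy_tailed
                        else rng.standard_normal()
                    )
                    value += config.noise_sd * scale * draw
                rows.append((label, f"r{rep}", name, value))

    frame = pd.DataFrame(rows, columns=["treatment", "replicate", "trait", "value"])
    descriptors = [
        TraitDescriptor(name=n, unit=u, orientation=o) for n, u, o, _, _ in panel
    ]
    table = trait_table_from_frame(frame, descriptors)
    truth = pd.Series(delta, index=labels, name="tolerance")
    return table, truth


def simulate_ct_table(
    fold_changes: dict[str, float],
    *,
    reference: str = "AQP",
    control: str = "WW",
    treated: str = "DS",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    base_ct: float = 22.0,
    reference_ct: float = 18.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate a Ct table whose true fold changes are the given parameters.

    The Livak computation is inverted: the treated target Ct is shifted by
    −log2(fold) relative to the control, so at ``noise_sd = 0`` the
    2^-ddCt estimate recovers each planted fold change exactly.
    """
    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("planted fold changes must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in (control, treated):
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((group, reference, f"r{rep}", reference_ct + noise))
            for gene, fold in fold_changes.items():
                shift = -np.log2(fold) if group == treated else 0.0
                noise = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
                rows.append((group, gene, f"r{rep}", base_ct + shift + noise))
    ct = pd.DataFrame(rows, columns=["group", "gene", "replicate", "ct"])
    return ct, dict(fold_changes)


def simulate_de_table(
    *,
    n_up: int = 30,
    n_down: int = 20,
    n_null: int = 950,
    lfc_threshold: float = 2.0,
    margin: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Generate a gene table with a known number of up/down DEGs.

    Planted DEGs clear ``lfc_threshold`` by at least ``margin``; null genes
    stay below it by at least ``margin``, so the screen recovers the planted
    counts exactly.
    """
    if margin <= 0 or lfc_threshold <= margin:
        raise ValueError("need 0 < margin < lfc_threshold")
    rng = np.random.default_rng(seed)
    lfc = np.concatenate(
        [
            lfc_threshold + margin + rng.exponential(1.0, n_up),
            -(lfc_threshold + margin + rng.exponential(1.0, n_down)),
            rng.uniform(-(lfc_threshold - margin), lfc_threshold - margin, n_null),
        ]
    )
    genes = [f"gene_{i + 1}" for i in range(len(lfc))]
    padj = np.concatenate(
        [
            rng.uniform(0, 0.01, n_up + n_down),
            rng.uniform(0, 1, n_null),
        ]
    )
    table = pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj})
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    truth = {"n_up": n_up, "n_down": n_down, "n_total_degs": n_up + n_down}
    return table, truth
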