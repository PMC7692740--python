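"""Synthetic study generator for the seed-preference analysis.

Emulates the shape of a weed-seed / carabid cafeteria study: ~28 seed
species measured for morphology (dimensions with A >= B >= C, 100-seed mass
proportional to volume, coat thickness and crush strength), categorical
plant family and life-strategy labels, wide chemistry blocks with more
columns than species (35 fatty-acid methyl esters), and consumption by ~37
predator species split into the tribes Harpalini (15), Zabrini (18) and
others (4).

Preference is generated through trait *values*: each predator carries its
own standard-normal weight vector over the standardized columns of every
trait block, the per-block weight inner products are scaled by the block
effect sizes tau_k, Gaussian noise is added, and consumption is
``exp(latent)`` rescaled to count-like magnitudes.  This mirrors the causal
story (predators respond to traits) rather than assuming the distance-level
regression model is literally true; trait-driven blocks nevertheless induce
the distance associations MRM detects.

Two chemistry pairings are built deliberately redundant — volatiles from
dry vs imbibed seeds, and surface fatty acids vs other surface compounds —
so the Mantel collinearity screen has realistic work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import (CategoricalTable, ConsumptionTable, TraitTable,
                     shape_table)

__all__ = ["SyntheticScenario", "generate_seed_traits",
           "generate_consumption", "generate_dataset",
           "DEFAULT_BLOCK_EFFECTS", "EXPLANATORY_BLOCKS"]

EXPLANATORY_BLOCKS = (
    "seed_mass", "seed_dimensions", "seed_shape", "seed_coat",
    "taxonomy", "plant_strategy", "volatiles_dry", "volatiles_imbibed",
    "surface_fatty_acids", "total_fatty_acids", "other_surface_compounds",
)

# default effect sizes: morphology and coat strong drivers, taxonomy and
# ecology moderate, chemistry inert
DEFAULT_BLOCK_EFFECTS = {
    "seed_dimensions": 1.0,
    "seed_coat": 1.0,
    "seed_mass": 0.5,
    "taxonomy": 0.5,
    "plant_strategy": 0.5,
}


@dataclass
class SyntheticScenario:
    """Study dimensions, effect sizes and noise of a simulated cafeteria assay."""

    n_seeds: int = 28
    n_predators: int = 37
    tribe_counts: dict[str, int] = field(
        default_factory=lambda: {"Harpalini": 15, "Zabrini": 18, "other": 4})
    block_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_EFFECTS))
    noise_sd: float = 1.0
    n_families: int = 13
    n_strategies: int = 4
    n_fatty_acids: int = 35
    n_volatiles: int = 30
    n_surface_compounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 4:
            raise ValueError("need at least 4 seed species")
        if sum(self.tribe_counts.values()) != self.n_predators:
            raise ValueError("tribe counts must sum to n_predators")
        if any(v < 0 for v in self.block_effects.values()):
            raise ValueError("block effect scales must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def species_ids(self) -> list[str]:
        return [f"seed_{i:02d}" for i in range(1, self.n_seeds + 1)]

    def predator_ids(self) -> tuple[list[str], dict[str, str]]:
        ids, tribes = [], {}
        for tribe, count in self.tribe_counts.items():
            for i in range(1, count + 1):
                pid = f"{tribe[:4].lower()}_{i:02d}"
                ids.append(pid)
                tribes[pid] = tribe
        return ids, tribes


def _lowrank_block(rng: np.random.Generator, n: int, p: int, rank: int,
                   latent: np.ndarray | None = None,
                   carryover: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Positive block with factor structure; optionally reuse another
    block's latent scores (carryover in [0,1]) to create redundancy."""
    own = rng.standard_normal((n, rank))
    if latent is None:
        scores = own
    else:
        scores = carryover * latent[:, :rank] + np.sqrt(1 - carryover**2) * own
    loadings = rng.standard_normal((rank, p))
    z = scores @ loadings + 0.5 * rng.standard_normal((n, p))
    return scores, np.exp(0.5 * z)


def generate_seed_traits(scenario: SyntheticScenario,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[dict[str, TraitTable], CategoricalTable]:
    """Draw all trait blocks and the categorical table for one study."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    sp = scenario.species_ids()
    n = scenario.n_seeds

    # dimensions in mm: sorted log-normal draws guarantee A >= B >= C
    dims = np.sort(rng.lognormal(mean=0.3, sigma=0.6, size=(n, 3)),
                   axis=1)[:, ::-1]
    dimensions = TraitTable("seed_dimensions", pd.DataFrame(
        dims, index=sp, columns=["A", "B", "C"]))

    # 100-seed mass in g proportional to volume times a log-normal density
    volume = dims.prod(axis=1)
    density = rng.lognormal(mean=np.log(0.3), sigma=0.6, size=n)
    mass = TraitTable("seed_mass", pd.DataFrame(
        {"mass_100_seeds": volume * density}, index=sp))

    # coat thickness (mm) and crush strength (N) share a defence factor
    defence = rng.standard_normal(n)
    thickness = np.exp(np.log(0.05) + 0.5 * defence +
                       0.3 * rng.standard_normal(n))
    strength = np.exp(np.log(10.0) + 0.8 * defence +
                      0.5 * rng.standard_normal(n))
    coat = TraitTable("seed_coat", pd.DataFrame(
        {"coat_thickness": thickness, "coat_strength": strength}, index=sp))

    shape = shape_table(dimensions)

    def chem(name: str, p: int, prefix: str, latent=None, carryover=0.0):
        scores, values = _lowrank_block(rng, n, p, rank=4, latent=latent,
                                        carryover=carryover)
        cols = [f"{prefix}_{i:02d}" for i in range(1, p + 1)]
        return scores, TraitTable(name, pd.DataFrame(values, index=sp,
                                                     columns=cols))

    tfa_scores, total_fa = chem("total_fatty_acids",
                                scenario.n_fatty_acids, "fame")
    osc_scores, other_surface = chem("other_surface_compounds",
                                     scenario.n_surface_compounds, "osc")
    # surface fatty acids echo the other-surface-compound profile
    _, surface_fa = chem("surface_fatty_acids", scenario.n_fatty_acids,
                         "sfame", latent=osc_scores, carryover=0.85)
    vd_scores, volatiles_dry = chem("volatiles_dry", scenario.n_volatiles,
                                    "vod")
    # imbibed seeds release a correlated but germination-shifted profile
    _, volatiles_imbibed = chem("volatiles_imbibed", scenario.n_volatiles,
                                "voi", latent=vd_scores, carryover=0.85)

    families = rng.choice(
        [f"family_{i:02d}" for i in range(1, scenario.n_families + 1)],
        size=n)
    strategies = rng.choice(
        ["annual", "biennial", "annual-biennial", "perennial"]
        [:scenario.n_strategies], size=n)
    categorical = CategoricalTable("ecology", pd.DataFrame(
        {"family": families, "strategy": strategies}, index=sp))

    blocks = {t.name: t for t in (
        mass, dimensions, shape, coat, total_fa, other_surface, surface_fa,
        volatiles_dry, volatiles_imbibed)}
    return blocks, categorical


def _standardized_columns(blocks: dict[str, TraitTable],
                          categorical: CategoricalTable,
                          ) -> dict[str, np.ndarray]:
    """Z-scored numeric columns per block; categoricals one-hot encoded."""
    out: dict[str, np.ndarray] = {}
    for name, table in blocks.items():
        X = table.data.to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        out[name] = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    mapping = {"taxonomy": "family", "plant_strategy": "strategy"}
    for block_name, col in mapping.items():
        onehot = pd.get_dummies(categorical.data[col]).to_numpy(dtype=float)
        sd = onehot.std(axis=0, ddof=0)
        keep = sd > 0
        out[block_name] = (onehot[:, keep] - onehot[:, keep].mean(axis=0)) / sd[keep]
    return out


def generate_consumption(blocks: dict[str, TraitTable],
                         categorical: CategoricalTable,
                         scenario: SyntheticScenario,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[ConsumptionTable, dict]:
    """Trait-driven raw consumption plus the ground-truth effect record.

    latent(c, s) = sum_k tau_k * <b_ck, z_k(s)> + eps(c, s); raw consumption
    is exp(latent) rescaled so each predator's most consumed seed is 100
    (count-like magnitudes; the scaling is cosmetic and removed again by
    standardization).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed + 1))
    z = _standardized_columns(blocks, categorical)
    pred_ids, tribes = scenario.predator_ids()
    n, m = scenario.n_seeds, scenario.n_predators

    eta = scenario.noise_sd * rng.standard_normal((n, m))
    for name, tau in scenario.block_effects.items():
        if name not in z:
            raise KeyError(f"unknown block in block_effects: {name!r}")
        weights = rng.standard_normal((z[name].shape[1], m))
        if tau > 0:
            eta += tau * (z[name] @ weights)

    raw = np.exp(eta - eta.max(axis=0, keepdims=True)) * 100.0
    table = ConsumptionTable(
        pd.DataFrame(raw, index=blocks["seed_dimensions"].species,
                     columns=pred_ids),
        standardized=False, tribes=tribes)
    truth = {
        "block_effects": {k: float(v) for k, v in
                          scenario.block_effects.items()},
        "driver_blocks": sorted(k for k, v in scenario.block_effects.items()
                                if v > 0),
        "noise_sd": scenario.noise_sd,
        "seed": scenario.seed,
    }
    return table, truth


def generate_dataset(scenario: SyntheticScenario,
                     ) -> tuple[dict[str, TraitTable], CategoricalTable,
                                ConsumptionTable, dict]:
    """Full study draw: trait blocks, categorical table, raw consumption,
    ground truth."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_traits, rng_cons = (np.random.default_rng(c) for c in ss.spawn(2))
    blocks, categorical = generate_seed_traits(scenario, rng_traits)
    consumption, truth = generate_consumption(blocks, categorical, scenario,
                                              rng_cons)
    return blocks, categorical, consumption, truth
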