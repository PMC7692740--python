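"""End-to-end orchestration of the seed-preference analysis.

The sequence mirrors the study design: build one distance matrix per
candidate data block (Bray-Curtis for standardized preferences, Mahalanobis
for multivariate trait blocks, absolute difference for 100-seed mass,
simple matching for family and life strategy), screen the explanatory
candidates for redundancy with pairwise Mantel tests, then fit three MRM
models that differ only in their response matrix — preferences of the full
predator set, of Harpalini only, and of Zabrini only — with the same
retained explanatory set, and partition each model's explained variance.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from . import __version__
from .distances import (DistanceMatrix, bray_curtis_matrix,
                        categorical_distance, mahalanobis_matrix,
                        univariate_distance)
from .io import (read_categorical_csv, read_consumption_csv, read_trait_csv,
                 write_report)
from .mantel import mantel_test
from .mrm import MRMFit, VariancePartition, mrm_fit, variance_partition
from .traits import (CategoricalTable, ConsumptionTable, TraitTable,
                     standardize_consumption)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ScreenLog", "ModelResult", "AnalysisResult",
           "build_candidate_matrices", "screen_collinearity",
           "run_full_analysis"]

DEFAULT_MODELS: dict[str, list[str] | None] = {
    "full": None,            # every predator column
    "Harpalini": ["Harpalini"],
    "Zabrini": ["Zabrini"],
}


@dataclass
class AnalysisConfig:
    """Knobs of one analysis run; every threshold and seed is explicit."""

    inputs: dict[str, str] = field(default_factory=dict)
    screen_threshold: float = 0.05
    n_perm_mantel: int = 999
    n_perm_mrm: int = 9999
    alpha: float = 0.1
    seed: int = 0
    mahalanobis_ridge: float | None = None
    wide_block_ridge: float = 1.0
    use_ranks: bool = False
    models: dict[str, list[str] | None] = field(
        default_factory=lambda: dict(DEFAULT_MODELS))

    def __post_init__(self) -> None:
        for name, value in (("screen_threshold", self.screen_threshold),
                            ("alpha", self.alpha)):
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("rng seed must be set explicitly")

    @classmethod
    def from_dict(cls, cfg: dict) -> "AnalysisConfig":
        return cls(**cfg)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenLog:
    """Every Mantel decision of the collinearity screen."""

    threshold: float
    n_permutations: int
    pairs: list[dict] = field(default_factory=list)
    response_correlations: dict[str, float] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelResult:
    name: str
    fit: MRMFit
    partition: VariancePartition

    def to_dict(self) -> dict:
        return {
            "term_names": list(self.fit.term_names),
            "coefficients": self.fit.coefficients,
            "intercept": self.fit.intercept,
            "r_squared": self.fit.r_squared,
            "term_p_values": self.fit.term_p_values,
            "model_p_value": self.fit.model_p_value,
            "n_permutations": self.fit.n_permutations,
            "alpha": self.fit.alpha,
            "significant_terms": list(self.fit.significant_terms),
            "partition": {
                "unique_r2": self.partition.unique_r2,
                "collinearity_r2": self.partition.collinearity_r2,
                "total_r2": self.partition.total_r2,
            },
        }


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    screen: ScreenLog
    models: dict[str, ModelResult]

    def to_report(self) -> dict:
        return {
            "version": __version__,
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "screen": self.screen.to_dict(),
            "models": {name: m.to_dict() for name, m in self.models.items()},
        }


def _check_alignment(species_sets: dict[str, set[str]]) -> None:
    ref_name = next(iter(species_sets))
    ref = species_sets[ref_name]
    for name, s in species_sets.items():
        if s != ref:
            only_ref = sorted(ref - s)
            only_other = sorted(s - ref)
            raise ValueError(
                f"species sets differ between {ref_name!r} and {name!r}: "
                f"only in {ref_name}: {only_ref}; only in {name}: {only_other}")


def build_candidate_matrices(blocks: dict[str, TraitTable],
                             categorical: CategoricalTable,
                             consumption: ConsumptionTable,
                             ridge: float | None = None,
                             wide_block_ridge: float = 1.0,
                             ) -> tuple[DistanceMatrix,
                                        dict[str, DistanceMatrix]]:
    """One validated distance matrix per candidate block.

    Returns the Bray-Curtis response (all predators) and the explanatory
    set keyed by block name.  Metric dispatch: single numeric column ->
    absolute difference; several columns -> Mahalanobis; categorical
    columns -> simple matching (one matrix per attribute: family ->
    'taxonomy', strategy -> 'plant_strategy').

    Blocks with at least as many columns as species minus one have a
    covariance that is singular by dimension; whitening such a block with a
    pseudo-inverse collapses all pairwise distances to one constant (the
    species form a regular simplex), so these blocks get a ridge
    (``wide_block_ridge``, by default equal weight on the diagonal) that
    interpolates toward standardized Euclidean distance.
    """
    if not consumption.standardized:
        consumption = standardize_consumption(consumption)
    species_sets = {name: set(t.species) for name, t in blocks.items()}
    species_sets[categorical.name] = set(categorical.species)
    species_sets["consumption"] = set(consumption.species)
    _check_alignment(species_sets)

    explanatory: dict[str, DistanceMatrix] = {}
    for name, table in blocks.items():
        n, p = table.data.shape
        if p == 1:
            explanatory[name] = univariate_distance(
                table.data.iloc[:, 0], block_name=name)
        else:
            block_ridge = ridge
            if block_ridge is None and p >= n - 1:
                block_ridge = wide_block_ridge
                logger.info("block %s has %d columns for %d species: "
                            "singular covariance, using ridge %.3g",
                            name, p, n, block_ridge)
            explanatory[name] = mahalanobis_matrix(table, ridge=block_ridge)
    cat_map = {"family": "taxonomy", "strategy": "plant_strategy"}
    for col in categorical.data.columns:
        block_name = cat_map.get(col, col)
        explanatory[block_name] = categorical_distance(
            categorical.data[col], block_name=block_name)
    response = bray_curtis_matrix(consumption, block_name="preferences")
    logger.info("built %d candidate matrices (1 response + %d explanatory)",
                len(explanatory) + 1, len(explanatory))
    return response, explanatory


def screen_collinearity(response: DistanceMatrix,
                        explanatory: dict[str, DistanceMatrix],
                        threshold: float = 0.05,
                        n_permutations: int = 999,
                        seed: int | None = None,
                        ) -> tuple[dict[str, DistanceMatrix], ScreenLog]:
    """Drop redundant explanatory matrices via pairwise Mantel tests.

    While any retained pair is significantly correlated (p <= threshold),
    the pair with the smallest p is resolved by excluding its member with
    the weaker marginal Mantel correlation to the response (ties broken by
    label order, the lexicographically later name is dropped).  The
    response is never excluded.  Retaining everything is a valid outcome.
    """
    if len(explanatory) < 2:
        raise ValueError("need at least 2 explanatory matrices to screen")
    names = sorted(explanatory)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def next_seed() -> int:
        return int(rng.integers(2 ** 31))

    log = ScreenLog(threshold=threshold, n_permutations=n_permutations)
    for name in names:
        res = mantel_test(explanatory[name], response,
                          n_permutations=n_permutations, seed=next_seed())
        log.response_correlations[name] = res.r
    pair_results = {}
    for a, b in combinations(names, 2):
        res = mantel_test(explanatory[a], explanatory[b],
                          n_permutations=n_permutations, seed=next_seed())
        pair_results[(a, b)] = res
        log.pairs.append({"a": a, "b": b, "r": res.r, "p": res.p_value})

    retained = set(names)
    while True:
        significant = [(pair, res) for pair, res in pair_results.items()
                       if pair[0] in retained and pair[1] in retained
                       and res.p_value <= threshold]
        if not significant:
            break
        (a, b), res = min(significant,
                          key=lambda item: (item[1].p_value, item[0]))
        ra, rb = log.response_correlations[a], log.response_correlations[b]
        drop, keep = (a, b) if (ra, b) < (rb, a) else (b, a)
        retained.discard(drop)
        log.exclusions.append({
            "excluded": drop, "kept": keep, "r": res.r, "p": res.p_value,
            "rule": "weaker marginal Mantel correlation to response",
            "response_r_excluded": log.response_correlations[drop],
            "response_r_kept": log.response_correlations[keep],
        })
        logger.info("screen: excluded %s (pair with %s, r=%.3f, p=%.4g)",
                    drop, keep, res.r, res.p_value)
    log.retained = [n for n in names if n in retained]
    return {n: explanatory[n] for n in log.retained}, log


def _load_tables(config: AnalysisConfig,
                 ) -> tuple[dict[str, TraitTable], CategoricalTable,
                            ConsumptionTable]:
    inputs = config.inputs
    if "consumption" not in inputs:
        raise ValueError("config.inputs must name a 'consumption' CSV")
    consumption = read_consumption_csv(inputs["consumption"],
                                       inputs.get("predator_metadata"))
    categorical = read_categorical_csv(inputs["categorical"])
    blocks = {}
    for name, path in inputs.items():
        if name in ("consumption", "predator_metadata", "categorical"):
            continue
        blocks[name] = read_trait_csv(path, name)
    return blocks, categorical, consumption


def run_full_analysis(config: AnalysisConfig,
                      tables: tuple[dict[str, TraitTable], CategoricalTable,
                                    ConsumptionTable] | None = None,
                      out_dir: str | Path | None = None,
                      make_figure: bool = False) -> AnalysisResult:
    """Screen once on the full-predator response, then fit every configured
    model with the same retained explanatory set.

    ``tables`` may be passed in memory (blocks, categorical, consumption);
    otherwise they are read from ``config.inputs``.  Each model rebuilds the
    Bray-Curtis response from its own predator subset.
    """
    if tables is None:
        tables = _load_tables(config)
    blocks, categorical, consumption = tables
    if not consumption.standardized:
        consumption = standardize_consumption(consumption)

    ss = np.random.SeedSequence(config.seed)
    seed_screen, seed_models = (int(c.generate_state(1)[0] % (2 ** 31))
                                for c in ss.spawn(2))

    response, explanatory = build_candidate_matrices(
        blocks, categorical, consumption, ridge=config.mahalanobis_ridge,
        wide_block_ridge=config.wide_block_ridge)
    retained, screen_log = screen_collinearity(
        response, explanatory, threshold=config.screen_threshold,
        n_permutations=config.n_perm_mantel, seed=seed_screen)

    known_tribes = set(consumption.tribes.values())
    model_rng = np.random.default_rng(seed_models)
    models: dict[str, ModelResult] = {}
    for name, tribes in config.models.items():
        if tribes is None:
            subset = consumption
        else:
            unknown = sorted(set(tribes) - known_tribes)
            if unknown:
                raise ValueError(f"model {name!r}: unknown tribe {unknown}")
            cols = [p for p in consumption.predators
                    if consumption.tribes.get(p) in tribes]
            if len(cols) < 2:
                raise ValueError(f"model {name!r}: fewer than 2 predators")
            subset = consumption.subset_predators(cols)
        resp = bray_curtis_matrix(subset, block_name=f"preferences_{name}")
        terms = [retained[t] for t in screen_log.retained]
        fit = mrm_fit(resp, terms, n_permutations=config.n_perm_mrm,
                      alpha=config.alpha,
                      seed=int(model_rng.integers(2 ** 31)),
                      use_ranks=config.use_ranks)
        part = variance_partition(resp, terms, fit=fit,
                                  use_ranks=config.use_ranks)
        models[name] = ModelResult(name, fit, part)
        logger.info("model %s: R^2 = %.4f (p = %.4g)", name, fit.r_squared,
                    fit.model_p_value)

    result = AnalysisResult(config, screen_log, models)
    if out_dir is not None:
        write_report(result.to_report(), out_dir, make_figure=make_figure)
    return result
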