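"""Seed morphology indices and consumption standardization.

Seeds are described by three principal dimensions measured with a calliper:
``A`` (the longest dimension), ``B`` (the longest dimension perpendicular to
A in the same plane) and ``C`` (the longest dimension perpendicular to the
A-B plane), so a well-measured seed satisfies ``A >= B >= C > 0``.  From
these, four dimensionless/volumetric descriptors are computed:

* shape variance ``Vs`` — population variance of ``(A/A, B/A, C/A)``;
  0 for a sphere, approaching 2/9 for a thin disc or needle,
* flatness ``FI = (A + B) / (2 C)`` — 1 for a sphere, large for discs,
* eccentricity ``EI = A / B`` — 1 for round seeds, >2 for spindles,
* volume ``V = A * B * C`` in mm^3.

Consumption in a multi-choice (cafeteria) assay is recorded per predator
species as non-negative counts over seed species; to remove the effect of
predator body size each predator column is rescaled to the proportion of
that predator's most consumed seed, giving standardized preferences in
``[0, 1]`` with a per-column maximum of exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "CategoricalTable",
    "ConsumptionTable",
    "standardize_consumption",
    "aggregate_replicates",
    "shape_index",
    "flatness_index",
    "eccentricity_index",
    "seed_volume",
    "shape_table",
]


def _check_species_index(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{what}: duplicate species_id {dups}")
    if df.empty:
        raise ValueError(f"{what}: empty table")


@dataclass
class TraitTable:
    """One named block of continuous traits, species in rows."""

    name: str
    data: pd.DataFrame  # index: species_id; columns: named traits

    def __post_init__(self) -> None:
        _check_species_index(self.data, f"trait block {self.name!r}")
        non_numeric = [c for c in self.data.columns
                       if not pd.api.types.is_numeric_dtype(self.data[c])]
        if non_numeric:
            raise ValueError(
                f"trait block {self.name!r}: non-numeric columns {non_numeric}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


@dataclass
class CategoricalTable:
    """Categorical seed attributes (plant family, life strategy)."""

    name: str
    data: pd.DataFrame  # index: species_id; columns: categorical attributes

    def __post_init__(self) -> None:
        _check_species_index(self.data, f"categorical block {self.name!r}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ConsumptionTable:
    """Seed species x predator species consumption.

    ``standardized`` distinguishes raw counts from per-predator proportions
    of the most consumed seed.
    """

    data: pd.DataFrame  # index: seed species_id; columns: predator ids
    standardized: bool = False
    tribes: dict[str, str] = field(default_factory=dict)  # predator -> tribe

    def __post_init__(self) -> None:
        _check_species_index(self.data, "consumption table")
        if (self.data.values < 0).any():
            bad = self.data.columns[(self.data.values < 0).any(axis=0)]
            raise ValueError(f"negative consumption in columns {list(bad)}")
        if self.standardized and np.nanmax(self.data.values, initial=0.0) > 1 + 1e-12:
            raise ValueError("standardized consumption must lie in [0, 1]")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def predators(self) -> list[str]:
        return list(self.data.columns)

    def subset_predators(self, predators: list[str]) -> "ConsumptionTable":
        missing = [p for p in predators if p not in self.data.columns]
        if missing:
            raise KeyError(f"unknown predator columns {missing}")
        return ConsumptionTable(
            self.data[list(predators)].copy(), self.standardized,
            {p: t for p, t in self.tribes.items() if p in predators})


def standardize_consumption(raw: ConsumptionTable) -> ConsumptionTable:
    """Rescale each predator column to the proportion of its most consumed seed.

    All-zero predator columns have an undefined divisor and are dropped with
    a warning.  Idempotent on already-standardized nonzero columns.
    """
    if raw.data.empty:
        raise ValueError("empty consumption table")
    values = raw.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("consumption must be non-negative")
    col_max = values.max(axis=0)
    zero = col_max == 0
    if zero.any():
        dropped = list(raw.data.columns[zero])
        warnings.warn(f"dropping all-zero predator columns: {dropped}")
        logger.warning("dropped all-zero predator columns: %s", dropped)
    keep = ~zero
    if not keep.any():
        raise ValueError("all predator columns are zero")
    std = values[:, keep] / col_max[keep]
    out = pd.DataFrame(std, index=raw.data.index,
                       columns=raw.data.columns[keep])
    tribes = {p: t for p, t in raw.tribes.items() if p in out.columns}
    return ConsumptionTable(out, standardized=True, tribes=tribes)


def aggregate_replicates(measurements: pd.DataFrame,
                         expected_species: list[str] | None = None,
                         ) -> pd.DataFrame:
    """Collapse per-seed replicate measurements to per-species means.

    ``measurements`` holds one row per replicate seed with a ``species_id``
    column plus numeric measurement columns (e.g. dimensions from five seeds
    per species, coat thickness from 5 seeds x 10 sections).  If
    ``expected_species`` is given, species without any replicate raise an
    error naming them.
    """
    if "species_id" not in measurements.columns:
        raise ValueError("measurements need a 'species_id' column")
    value_cols = [c for c in measurements.columns
                  if c not in ("species_id", "replicate_id")]
    means = measurements.groupby("species_id")[value_cols].mean()
    means.index.name = "species_id"
    if expected_species is not None:
        missing = sorted(set(expected_species) - set(means.index))
        if missing:
            raise ValueError(f"no replicates for species: {missing}")
    # warn, not error, on dimension-order violations: measurement noise in
    # real tables can put B marginally above A
    if {"A", "B", "C"} <= set(means.columns):
        bad = means.index[(means["B"] > means["A"]) | (means["C"] > means["B"])]
        if len(bad):
            warnings.warn(
                f"dimension ordering A >= B >= C violated for {list(bad)}")
    return means


def _as_float(x, name: str, positive: bool = True):
    x = np.asarray(x, dtype=float)
    if positive and np.any(x <= 0):
        raise ValueError(f"{name} must be > 0")
    return x


def shape_index(A, B, C):
    """Shape variance Vs: population variance (n=3) of (A/A, B/A, C/A).

    0 for a perfect sphere (A=B=C); supremum 2/9 for degenerate shapes.
    """
    A = _as_float(A, "A")
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    x = np.stack(np.broadcast_arrays(A / A, B / A, C / A))
    return np.var(x, axis=0)  # divide by n = 3


def flatness_index(A, B, C):
    """Flatness FI = (A + B) / (2 C); 1 for a sphere."""
    C = _as_float(C, "C")
    return (np.asarray(A, float) + np.asarray(B, float)) / (2.0 * C)


def eccentricity_index(A, B):
    """Eccentricity EI = A / B; 1 for round seeds."""
    B = _as_float(B, "B")
    return np.asarray(A, float) / B


def seed_volume(A, B, C):
    """Seed volume V = A * B * C in mm^3."""
    A = _as_float(A, "A")
    B = _as_float(B, "B")
    C = _as_float(C, "C")
    return A * B * C


def shape_table(dimensions: TraitTable) -> TraitTable:
    """Derive the seed-shape block (Vs, FI, EI, V) from a dimensions block."""
    d = dimensions.data
    for col in ("A", "B", "C"):
        if col not in d.columns:
            raise ValueError(f"dimensions block lacks column {col!r}")
    out = pd.DataFrame({
        "Vs": shape_index(d["A"], d["B"], d["C"]),
        "FI": flatness_index(d["A"], d["B"], d["C"]),
        "EI": eccentricity_index(d["A"], d["B"]),
        "V": seed_volume(d["A"], d["B"], d["C"]),
    }, index=d.index)
    return TraitTable("seed_shape", out)
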