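"""CSV readers/writers, config parsing and report emission.

All tables use one CSV dialect: comma-separated, UTF-8, ``.`` decimal,
first column ``species_id``.  Distance matrices round-trip both as square
labeled CSVs and as long-format ``(i, j, distance)`` tables.  Reports are
written as JSON (sorted keys, no timestamps — byte-identical for identical
config and seed) plus a plain-text table; an optional SVG renders the
variance-partition bars with significance stars at p < 0.1 (*), < 0.05 (**)
and < 0.001 (***).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .distances import DistanceMatrix, validate_distance_matrix
from .traits import CategoricalTable, ConsumptionTable, TraitTable

__all__ = [
    "read_trait_csv", "write_trait_csv",
    "read_categorical_csv", "write_categorical_csv",
    "read_consumption_csv", "write_consumption_csv",
    "read_distance_csv", "write_distance_csv", "write_distance_long_csv",
    "read_config_yaml", "write_config_yaml",
    "write_report", "significance_stars",
]


def _read_species_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what}: no such file {path}")
    df = pd.read_csv(path)
    if df.columns[0] != "species_id":
        raise ValueError(f"{what}: first column must be 'species_id', "
                         f"got {df.columns[0]!r}")
    return df.set_index("species_id")


def read_trait_csv(path: str | Path, name: str,
                   columns: list[str] | None = None) -> TraitTable:
    """Read one continuous trait block; optionally select/validate columns."""
    df = _read_species_csv(path, f"trait block {name!r}")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"trait block {name!r}: missing columns "
                             f"{missing} in {path}")
        df = df[columns]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"trait block {name!r}: non-numeric value at "
                f"species {bad[0]!r}, column {col!r}")
        df[col] = coerced
    return TraitTable(name, df)


def write_trait_csv(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="species_id")


def read_categorical_csv(path: str | Path,
                         name: str = "ecology") -> CategoricalTable:
    df = _read_species_csv(path, f"categorical block {name!r}")
    return CategoricalTable(name, df.astype(str))


def write_categorical_csv(table: CategoricalTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="species_id")


def read_consumption_csv(path: str | Path,
                         metadata_path: str | Path | None = None,
                         standardized: bool = False) -> ConsumptionTable:
    """Read a seed x predator consumption table.

    ``metadata_path`` points to a sidecar CSV with columns
    ``predator_id,tribe`` mapping each predator to Harpalini/Zabrini/other.
    """
    df = _read_species_csv(path, "consumption table")
    tribes: dict[str, str] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        for col in ("predator_id", "tribe"):
            if col not in meta.columns:
                raise ValueError(f"predator metadata: missing column {col!r}")
        tribes = dict(zip(meta["predator_id"].astype(str),
                          meta["tribe"].astype(str)))
        unknown = [p for p in df.columns if p not in tribes]
        if unknown:
            raise ValueError(f"predators without tribe metadata: {unknown}")
    return ConsumptionTable(df.astype(float), standardized=standardized,
                            tribes=tribes)


def write_consumption_csv(table: ConsumptionTable, path: str | Path,
                          metadata_path: str | Path | None = None) -> None:
    table.data.to_csv(path, index_label="species_id")
    if metadata_path is not None:
        pd.DataFrame({"predator_id": list(table.tribes),
                      "tribe": list(table.tribes.values())}
                     ).to_csv(metadata_path, index=False)


def read_distance_csv(path: str | Path, metric_name: str = "",
                      block_name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_distance_matrix(
        DistanceMatrix.from_dataframe(df, metric_name, block_name))


def write_distance_csv(D: DistanceMatrix, path: str | Path) -> None:
    D.to_dataframe().to_csv(path, index_label="species_id")


def write_distance_long_csv(D: DistanceMatrix, path: str | Path) -> None:
    D.to_long().to_csv(path, index=False)


def read_config_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_config_yaml(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def _format_model_text(name: str, model: dict) -> list[str]:
    lines = [f"Model: {name}",
             f"  R^2 = {model['r_squared']:.4f}  "
             f"(permutation p = {model['model_p_value']:.4g})"]
    lines.append(f"  {'term':<28}{'coef':>12}{'p':>10}{'unique R^2':>12}  sig")
    part = model["partition"]["unique_r2"]
    for term in model["term_names"]:
        p = model["term_p_values"][term]
        lines.append(f"  {term:<28}{model['coefficients'][term]:>12.5f}"
                     f"{p:>10.4g}{part[term]:>12.4f}  "
                     f"{significance_stars(p)}")
    lines.append(f"  shared (collinearity) R^2 = "
                 f"{model['partition']['collinearity_r2']:.4f}")
    lines.append("")
    return lines


def write_report(report: dict, out_dir: str | Path,
                 make_figure: bool = False) -> dict[str, Path]:
    """Write JSON + text report (and optionally an SVG partition figure).

    The JSON is the authoritative artifact; every number in the text table
    comes from it.  Figures are excluded from determinism guarantees.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"json": out_dir / "report.json", "text": out_dir / "report.txt"}
    with open(paths["json"], "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = ["Seed-preference distance-matrix analysis",
             f"software version: {report.get('version', '?')}",
             f"rng seed: {report.get('seed')}", ""]
    screen = report.get("screen", {})
    if screen:
        lines.append(f"Collinearity screen (Mantel, "
                     f"{screen.get('n_permutations')} permutations, "
                     f"threshold p <= {screen.get('threshold')}):")
        for exc in screen.get("exclusions", []):
            lines.append(f"  excluded {exc['excluded']} "
                         f"(correlated with {exc['kept']}: "
                         f"r = {exc['r']:.3f}, p = {exc['p']:.4g})")
        if not screen.get("exclusions"):
            lines.append("  no matrices excluded")
        lines.append(f"  retained: {', '.join(screen.get('retained', []))}")
        lines.append("")
    for name, model in report.get("models", {}).items():
        lines.extend(_format_model_text(name, model))
    lines.append("significance: * p < 0.1, ** p < 0.05, *** p < 0.001")
    paths["text"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    if make_figure:
        paths["figure"] = out_dir / "partition.svg"
        _partition_figure(report, paths["figure"])
    return paths


def _partition_figure(report: dict, path: Path) -> None:
    """Horizontal stacked bars: per-term unique R^2 plus the shared share."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = report.get("models", {})
    fig, axes = plt.subplots(len(models), 1,
                             figsize=(7, 2.2 * max(len(models), 1)),
                             squeeze=False)
    for ax, (name, model) in zip(axes.ravel(), models.items()):
        part = model["partition"]
        terms = list(model["term_names"]) + ["collinearity"]
        widths = [part["unique_r2"][t] for t in model["term_names"]]
        widths.append(part["collinearity_r2"])
        labels = [f"{t} {significance_stars(model['term_p_values'][t])}"
                  for t in model["term_names"]] + ["collinearity"]
        left = 0.0
        for w, lab in zip(widths, labels):
            ax.barh([0], [max(w, 0.0)], left=left, label=lab)
            left += max(w, 0.0)
        ax.set_title(f"{name}: R^2 = {model['r_squared']:.3f}")
        ax.set_yticks([])
        ax.set_xlabel("proportion of explained variance")
        ax.legend(fontsize=6, ncol=2, loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
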