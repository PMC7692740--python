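"""Convert every data block written by 01_simulate.py into its distance
matrix: Bray-Curtis for standardized preferences, Mahalanobis for
multivariate trait blocks (ridge-regularized where the covariance is
singular by dimension), absolute difference for 100-seed mass, and simple
matching for family and life strategy.

Outputs: results/distances/<block>.csv (square) and <block>_long.csv.
"""

from pathlib import Path

from seedpref.io import (read_categorical_csv, read_consumption_csv,
                         read_trait_csv, write_distance_csv,
                         write_distance_long_csv)
from seedpref.pipeline import build_candidate_matrices
from seedpref.synthetic import EXPLANATORY_BLOCKS
from seedpref.traits import standardize_consumption

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA, OUT = ROOT / "data", ROOT / "distances"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    blocks = {name: read_trait_csv(DATA / f"{name}.csv", name)
              for name in EXPLANATORY_BLOCKS
              if (DATA / f"{name}.csv").exists()}
    categorical = read_categorical_csv(DATA / "categorical.csv")
    consumption = standardize_consumption(read_consumption_csv(
        DATA / "consumption.csv", DATA / "predator_metadata.csv"))

    response, explanatory = build_candidate_matrices(blocks, categorical,
                                                     consumption)
    for name, D in {"preferences": response, **explanatory}.items():
        write_distance_csv(D, OUT / f"{name}.csv")
        write_distance_long_csv(D, OUT / f"{name}_long.csv")
        print(f"{name:<26} {D.metric_name:<20} n={D.n} "
              f"mean d={D.condensed().mean():.3f}")
    print(f"\nwrote {1 + len(explanatory)} distance matrices to {OUT}")


if __name__ == "__main__":
    main()
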