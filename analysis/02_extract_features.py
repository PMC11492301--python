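"""Extract spatial (GLCM texture) and temporal (Dice) features per field.

Reads the plans written by 01_simulate_study.py, rasterizes each beam's
control points, builds the MU-weighted edge-enhanced integrated fluence and
computes the direction-averaged texture features plus the adjacent-CP Dice.
Writes results/features.csv (one row per field).
"""

from pathlib import Path

from mlcqa.geometry import hd120
from mlcqa.pipeline import expand_paths, tabulate_features

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = tabulate_features(expand_paths(str(ROOT / "study" / "plans")), hd120())
    table.to_csv(ROOT / "features.csv", index=False, float_format="%.6f")
    print(f"{len(table)} fields -> {ROOT / 'features.csv'}")
    summary = table[["contrast", "correlation", "energy", "entropy", "homogeneity", "dice"]]
    print(summary.agg(["mean", "std"]).round(4).to_string())


if __name__ == "__main__":
    main()
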