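"""Reduce dynalog files to per-file deviation statistics and summarize the
MLC wear series.

Writes results/deviations.csv (one row per dynalog file: mean/max absolute
deviation, fraction of samples above 1 mm) and results/wear.csv (one row
per session x bank: raw and first-session-normalized parameters).
"""

from pathlib import Path

from mlcqa.geometry import hd120
from mlcqa.pipeline import expand_paths, tabulate_deviations, tabulate_wear

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    dev = tabulate_deviations(expand_paths(str(ROOT / "study" / "dynalog")), hd120())
    dev.to_csv(ROOT / "deviations.csv", index=False, float_format="%.6f")
    print(f"{len(dev)} dynalog files -> {ROOT / 'deviations.csv'}")
    print(f"  mean |deviation| {dev.mean_abs_dev.mean():.3f} mm, "
          f"max {dev.max_abs_dev.max():.2f} mm, "
          f"{100 * dev.frac_above_threshold.mean():.1f}% of samples beyond 1 mm")

    wear = tabulate_wear(expand_paths(str(ROOT / "study" / "init")), hd120())
    wear.to_csv(ROOT / "wear.csv", index=False, float_format="%.6f")
    drifting = [c for c in ("BL_norm", "MSC_norm", "LO_norm", "CO_norm")]
    last = wear.groupby("bank").tail(1)[drifting]
    print(f"{len(wear)} session-bank records -> {ROOT / 'wear.csv'}")
    print("  final normalized drifts (per bank):")
    print(last.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
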