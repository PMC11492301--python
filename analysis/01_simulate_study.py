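"""Generate the synthetic VMAT QA cohort used by the downstream analyses.

Writes plans (JSON), dynalog files, init wear files and the planted truth
table under results/study/, at the desk scale of 5 treatments x 10 wear
sessions x 2 fields x 2 banks = 200 dynalog files.
"""

from pathlib import Path

from mlcqa.synthetic import SimulationConfig, synth_study, write_study

SEED = 20
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    study = synth_study(config)
    write_study(study, OUT)
    dev = study.table.deviation_mm
    print(f"study written to {OUT}")
    print(f"  {config.n_files} dynalog files, {config.n_treatments} plans, "
          f"{2 * config.n_sessions} init files")
    print(f"  mean |deviation| {dev.mean():.3f} mm (range {dev.min():.3f}-{dev.max():.3f})")
    print(f"  field Dice {study.field_features.dice.mean():.3f} "
          f"+/- {study.field_features.dice.std():.3f}")


if __name__ == "__main__":
    main()
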