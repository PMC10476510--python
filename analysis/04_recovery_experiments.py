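"""Validate the inference machinery by simulation.

Two experiments at the study's scale (218 tips, 20 My, 13 areas,
published best-fit rates):

1. parameter recovery — simulate under the best-supported constraint
   scenario and refit it, summarising the accuracy of the dispersal and
   extinction rate estimates;
2. model-selection recovery — simulate under the Owen Stanleys
   constraints and let it compete with current connectivity, recording
   how often AIC picks the generating model.
"""

import json
from pathlib import Path

import decranges as dr

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    models = dr.builtin_hypotheses()
    areas = models["j"].space.areas
    root = dr.RangeState((next(i for i, a in enumerate(areas) if a.code == "E"),))
    params = dr.DecParams(0.0094, 0.021)

    cfg = dr.SimulationConfig(
        model=models["j"], params=params, root_range=root,
        seed=SEED, n_tips=218, replicates=20,
    )
    table, summary = dr.recovery_experiment(cfg, [models["j"]])
    table.to_csv(BASE / "parameter_recovery.tsv", sep="\t", index=False)
    print("parameter recovery (20 replicates, truth d=0.0094, e=0.021):")
    print(f"  median d-hat: {table.d_hat.median():.4g} "
          f"(median relative error {summary['d_median_rel_error']:.1%})")
    print(f"  median e-hat: {table.e_hat.median():.3g} "
          f"(the extinction rate is weakly identified and collapses toward "
          f"zero once extinct lineages are pruned)")

    cfg_g = dr.SimulationConfig(
        model=models["g"], params=params, root_range=root,
        seed=SEED + 1, n_tips=218, replicates=20,
    )
    _, sel = dr.recovery_experiment(cfg_g, [models["a"], models["g"]])
    freq = sel["selection_frequency"]
    print("\nmodel-selection recovery (20 replicates simulated under "
          f"'{models['g'].name}'):")
    for name, f in freq.items():
        print(f"  {name:35s} AIC-best in {f:.0%} of replicates")

    with open(BASE / "recovery_summary.json", "w") as fh:
        json.dump({"parameter_recovery": summary, "model_selection": sel},
                  fh, indent=2)
    print(f"\nwrote {BASE / 'parameter_recovery.tsv'} and recovery_summary.json")


if __name__ == "__main__":
    main()
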