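"""Recovery of the foveal intensity-thickness correlations.

Draws 200 seeded replicate cohorts with the default coupling (pooled
Pearson r of 0.37 for GEFC and 0.42 for REFC against central retinal
thickness over the 193 diabetic eyes) and summarizes how the sample
correlations distribute around the configured values.
"""

from pathlib import Path

import pandas as pd

from colorfaf.pipeline_cli import replicate_foveal_correlations

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

TARGETS = {"r_gefc": 0.37, "r_refc": 0.42}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reps = replicate_foveal_correlations(replicates=200, base_seed=1)
    rows = []
    for col, target in TARGETS.items():
        r = reps[col]
        rows.append(
            {"component": col.removeprefix("r_").upper(), "configured_rho": target,
             "mean_r": r.mean(), "sd_r": r.std(), "q05": r.quantile(0.05),
             "q95": r.quantile(0.95), "replicates": len(r)}
        )
        print(f"{col}: mean {r.mean():.4f} (target {target}), sd {r.std():.3f}, "
              f"90% interval [{r.quantile(0.05):.3f}, {r.quantile(0.95):.3f}]")
    pd.DataFrame(rows).to_csv(
        RESULTS / "correlation_recovery.csv", index=False, float_format="%.4f"
    )
    print(f"wrote {RESULTS / 'correlation_recovery.csv'}")


if __name__ == "__main__":
    main()
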