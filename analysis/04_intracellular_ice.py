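"""Effect of intracellular ice on solute partitioning and heterogeneity.

Six phantom cells with intracellular ice pockets (target area fractions
0.07-0.12) and six without, analyzed with the intracellular-ice override
enabled.  Tabulates recovered P, ice-area fraction (AIC) and heterogeneity
(CV) against ground truth; writes results/iif_summary.csv.
"""

from pathlib import Path

import pandas as pd

import cryoraman as cr

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = cr.AnalysisConfig(allow_iif=True)
    rows = []
    targets = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12]
    for seed, aic_target in enumerate(targets, start=1):
        scene = cr.generate_scene(
            cr.SceneParams(
                dmso_channel=1.2,
                nucleus_dmso_factor=0.95,
                intracellular_ice_fraction=aic_target,
                seed=seed,
            )
        )
        out = cr.run_analyze(cr.render_cube(scene), config=cfg)
        rows.append(
            {
                "seed": seed,
                "group": "ice" if aic_target > 0 else "no_ice",
                "true_aic": round(scene.true_aic, 4),
                "aic": round(out.result.aic, 4),
                "true_P": round(scene.true_P, 4),
                "P": round(out.result.P, 4),
                "true_cv": round(scene.true_cv, 4),
                "cv": round(out.result.cv_intracellular, 4),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "iif_summary.csv", index=False)
    print(df.to_string(index=False))
    ice = df[df.group == "ice"]
    print(
        f"\nAIC recovered within {abs(ice.aic - ice.true_aic).max():.3f} of truth; "
        f"CV in ice-bearing cells {ice.cv.mean():.2f} vs {df[df.group=='no_ice'].cv.mean():.2f} without "
        f"(zero-solute ice pixels inflate intracellular heterogeneity)."
    )


if __name__ == "__main__":
    main()
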