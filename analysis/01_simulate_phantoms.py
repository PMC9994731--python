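"""Generate the four study-condition phantoms and tabulate their ground truth.

Presets emulate the imaging conditions of the study: near-unity partitioning
(10% DMSO, 1 C/min), strong trapping (1% DMSO, P ~ 0.2), enhanced exclusion
at faster cooling (P ~ 1.3), and fast-cooled cells with intracellular ice.
One example cube is written to scratch/ in the text-table interchange format
(cubes are ~20 MB and regenerated on demand; only the truth table is kept).
"""

from pathlib import Path

import pandas as pd

import cryoraman as cr
from cryoraman.synthetic import PRESETS

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    rows = []
    for name, params in PRESETS.items():
        scene = cr.generate_scene(params.replace(seed=1))
        rows.append(
            {
                "preset": name,
                "true_P": round(scene.true_P, 4),
                "true_cv": round(scene.true_cv, 4),
                "true_aic": round(scene.true_aic, 4),
                "n_cell_px": int(scene.truth_masks.cell.sum()),
                "n_channel_px": int(scene.truth_masks.channel.sum()),
                "n_ice_px": int(scene.truth_masks.ice_extracellular.sum()),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "phantom_truth.csv", index=False)
    print(df.to_string(index=False))

    cube_path = SCRATCH / "baseline_seed1.tsv"
    cr.write_cube(
        cr.render_cube(cr.generate_scene(PRESETS["baseline"].replace(seed=1))),
        cube_path,
        meta={"preset": "baseline", "seed": 1},
    )
    print(f"\nexample cube written to {cube_path}")
    print(f"ground-truth table written to {RESULTS / 'phantom_truth.csv'}")


if __name__ == "__main__":
    main()
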