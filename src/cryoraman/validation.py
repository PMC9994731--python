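"""Cross-validation of the automated partitioning estimate.

The mask-based partitioning ratio is checked two independent ways, mirroring
how an analyst validates the automation on real images: (1) a "hand"
computation averaging well over 50 manually selected interior-cell and
channel pixels, and (2) a line-scan estimate across the cell.  On
ground-truthed phantoms the manual pixels are drawn from the truth masks, so
the comparison exposes any bias the automated segmentation introduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import line_scan_ratio
from .peak_quant import IntensityMap
from .pipeline import run_analyze
from .segmentation import CompartmentMasks
from .spectral_io import AnalysisConfig
from .synthetic import SceneParams, SyntheticScene, generate_scene, render_cube

__all__ = ["PhantomValidation", "manual_region_ratio", "validation_sweep", "SWEEP_RATIOS"]

#: true partitioning ratios of the standard validation sweep
SWEEP_RATIOS = (0.2, 0.5, 1.0, 1.3, 2.0)


def manual_region_ratio(
    dmso_map: IntensityMap | np.ndarray,
    truth_masks: CompartmentMasks,
    rng: np.random.Generator,
    n_pixels: int = 150,
) -> float:
    """Hand-style partitioning estimate from manually selected pixels.

    Draws up to ``n_pixels`` interior cell pixels (one erosion in from the
    membrane, as a careful analyst would select them) and the same number of
    channel pixels from the ground-truth masks, and returns the ratio of the
    channel mean to the cell mean.
    """
    values = dmso_map.values if isinstance(dmso_map, IntensityMap) else np.asarray(dmso_map)
    interior = ndimage.binary_erosion(truth_masks.cell)
    ci_px = np.argwhere(interior)
    co_px = np.argwhere(truth_masks.channel)
    if len(ci_px) < 50 or len(co_px) < 50:
        raise ValueError("need more than 50 selectable pixels per compartment")
    ci_sel = ci_px[rng.choice(len(ci_px), min(n_pixels, len(ci_px)), replace=False)]
    co_sel = co_px[rng.choice(len(co_px), min(n_pixels, len(co_px)), replace=False)]
    c_i = values[ci_sel[:, 0], ci_sel[:, 1]].mean()
    c_o = values[co_sel[:, 0], co_sel[:, 1]].mean()
    return float(c_o / c_i)


@dataclass
class PhantomValidation:
    """Per-phantom comparison of the three estimates of P."""

    seed: int
    true_P: float
    P_auto: float
    P_manual: float
    P_linescan: float

    @property
    def manual_discrepancy(self) -> float:
        """Relative |auto - manual| / manual."""
        return abs(self.P_auto / self.P_manual - 1.0)

    @property
    def linescan_discrepancy(self) -> float:
        return abs(self.P_auto / self.P_linescan - 1.0)

    @property
    def truth_error(self) -> float:
        return abs(self.P_auto / self.true_P - 1.0)


def validation_sweep(
    selection_seed: int = 0,
    n_phantoms: int = 20,
    ratios: tuple[float, ...] = SWEEP_RATIOS,
    config: AnalysisConfig | None = None,
    scene_seeds: list[int] | None = None,
) -> list[PhantomValidation]:
    """Run the standard 20-phantom validation sweep at default noise.

    Phantoms use scene seeds 1..n cycling through ``ratios``;
    ``selection_seed`` drives only the manual pixel selection.
    """
    rng = np.random.default_rng(selection_seed)
    seeds = scene_seeds or list(range(1, n_phantoms + 1))
    out: list[PhantomValidation] = []
    for i, seed in enumerate(seeds):
        scene = generate_scene(
            SceneParams(dmso_channel=ratios[i % len(ratios)], seed=seed)
        )
        result = run_analyze(render_cube(scene), config=config)
        out.append(
            PhantomValidation(
                seed=seed,
                true_P=scene.true_P,
                P_auto=result.result.P,
                P_manual=manual_region_ratio(
                    result.maps["dmso"], scene.truth_masks, rng
                ),
                P_linescan=line_scan_ratio(result.maps["dmso"], result.masks),
            )
        )
    return out
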