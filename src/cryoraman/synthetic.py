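"""Ground-truthed synthetic phantoms of a frozen cell in partially frozen
solution.

A scene is a circular cell (with a nucleus) centered in the raster,
surrounded by extracellular ice crystals separated by unfrozen solution
channels, plus a thin unfrozen halo hugging the cell membrane.  Concentration
fields for the four marker bands are laid over the geometry: DMSO is present
in the cell (lognormal pixel-to-pixel heterogeneity) and in the channels
(flat, or rising away from the ice interface to emulate solute polarization),
and absent from ice; the OH field is high and uniform on ice; amide I marks
the cell body; DNA marks the nucleus.  The true partitioning ratio, CV and
intracellular-ice area fraction are recorded alongside the masks, so every
pipeline stage can be scored against ground truth.

The renderer turns fields into per-pixel spectra: one Gaussian line per band
(SD = 2 axis steps) on a constant baseline, plus signal-proportional noise
and optional single-sample cosmic-ray spikes.  All randomness flows from one
seed through named substreams (geometry, field, noise, spikes).

The extracellular tiling is deliberately smoothed so that no compartment
contains near-isolated pixels: single-pixel protrusions of ice into a channel
(or vice versa) are indistinguishable from cosmic-ray spikes for any local
outlier detector, which real micrographs avoid by virtue of smooth crystal
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import AxisError, GeometryError
from .segmentation import CompartmentMasks
from .spectral_io import (
    BandDefinition,
    SpectralAxis,
    SpectralCube,
    default_axis,
    default_bands,
)

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "render_cube", "PRESETS"]

_SUBSTREAMS = {"geometry": 0, "field": 1, "noise": 2, "spikes": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_SUBSTREAMS[stream],))
    )


@dataclass(frozen=True)
class SceneParams:
    """Everything that defines one phantom.

    dmso_channel / dmso_cell sets the true partitioning ratio (up to the
    heterogeneity draw); heterogeneity_sd is the relative SD of the lognormal
    intracellular DMSO field; intracellular_ice_fraction targets the true AIC
    to within 0.02.  Amplitudes are arbitrary detector-scaled units chosen so
    the four bands sit well above the baseline and noise floor.
    """

    height: int = 45
    width: int = 45
    cell_center: tuple[int, int] | None = None
    cell_radius: float = 10.0
    nucleus_radius: float = 4.0
    n_ice_crystals: int = 6
    channel_width: float = 2.0
    dmso_cell: float = 1.0
    dmso_channel: float = 1.0
    nucleus_dmso_factor: float = 1.0
    intracellular_ice_fraction: float = 0.0
    heterogeneity_sd: float = 0.15
    gradient_toward_ice: bool = False
    noise_sd: float = 0.02
    noise_floor: float = 0.002
    noise_model: str = "gaussian"
    n_spikes: int = 0
    spike_amplitude: float = 20.0
    spike_band: str = "dmso"
    amide_cell: float = 2.0
    amide_background: float = 0.1
    amide_heterogeneity_sd: float = 0.08
    ice_level: float = 3.0
    oh_background: float = 0.3
    dna_nucleus: float = 1.5
    dna_cytosol: float = 0.15
    baseline: float = 0.5
    seed: int = 0

    def replace(self, **kwargs) -> "SceneParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticScene:
    """Ground-truth carrier: geometry, fields, and true summary metrics."""

    params: SceneParams
    truth_masks: CompartmentMasks
    concentration_fields: Mapping[str, np.ndarray]
    true_P: float
    true_cv: float
    true_aic: float

    def recompute_truth(self) -> tuple[float, float, float]:
        """Recompute (P, CV, AIC) from the stored fields and masks."""
        dmso = self.concentration_fields["dmso"]
        cell = self.truth_masks.cell
        c_i = float(dmso[cell].mean())
        c_o = float(dmso[self.truth_masks.channel].mean())
        cv = float(dmso[cell].std(ddof=1) / c_i)
        aic = float(self.truth_masks.ice_intracellular.sum() / cell.sum())
        return c_o / c_i, cv, aic


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


_NEIGHBOR_SHIFTS = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def _neighbor_counts(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(# true neighbors, # available neighbors) per pixel, 8-connectivity."""
    h, w = mask.shape
    true_ct = np.zeros((h, w), dtype=int)
    avail = np.zeros((h, w), dtype=int)
    padded = np.zeros((h + 2, w + 2), dtype=int)
    padded[1:-1, 1:-1] = mask.astype(int)
    ones = np.zeros((h + 2, w + 2), dtype=int)
    ones[1:-1, 1:-1] = 1
    for dr, dc in _NEIGHBOR_SHIFTS:
        true_ct += padded[1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc]
        avail += ones[1 + dr : h + 1 + dr, 1 + dc : w + 1 + dc]
    return true_ct, avail


def _smooth_tiling(ice: np.ndarray, solution: np.ndarray, cell: np.ndarray):
    """Remove near-isolated pixels from the extracellular ice/channel tiling.

    Real crystal boundaries are smooth; raw Voronoi ridges on a pixel grid
    are not, and a pixel whose 8-neighborhood is dominated by the other
    compartment is statistically indistinguishable from a cosmic-ray spike.
    Step 1 shrinks the ice class to a fixed point by removing every ice pixel
    without a neighborhood majority of ice; step 2 flips channel slivers
    buried in ice (minority of solution neighbors) to ice, again to a fixed
    point.  Both steps are monotone, so the procedure terminates, and a
    flipped sliver pixel has an ice majority around it by construction, so
    step 2 preserves the cohesion step 1 established.  Cell pixels are never
    flipped.
    """
    ice = ice.copy()
    while True:
        ice_ct, avail = _neighbor_counts(ice)
        lonely_ice = ice & (ice_ct * 2 < avail)
        if not lonely_ice.any():
            break
        ice &= ~lonely_ice
        solution = solution | lonely_ice
    while True:
        sol_ct, avail = _neighbor_counts(solution & ~ice)
        lonely_channel = solution & ~ice & ~cell & (sol_ct * 2 < avail)
        if not lonely_channel.any():
            break
        ice |= lonely_channel
        solution = solution & ~lonely_channel
    return ice, solution


def _place_ice_pockets(
    cell: np.ndarray,
    center: tuple[int, int],
    cell_radius: float,
    target_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Compact intracellular ice pockets totalling ~target_fraction of the cell.

    Pockets are lattice disks of 21 pixels (radius ~2.5) plus at most one
    13-pixel disk, shapes chosen to be compact (no single-pixel tips), placed
    fully inside the cell without touching its boundary.
    """
    n_cell = int(cell.sum())
    target = int(round(target_fraction * n_cell))
    pockets = np.zeros_like(cell, dtype=bool)
    if target <= 6:
        return pockets
    sizes: list[float] = []  # pocket radii to place
    remaining = target
    while remaining >= 15:
        sizes.append(2.55)  # 21-pixel lattice disk
        remaining -= 21
    if 7 <= remaining:
        sizes.append(2.0)  # 13-pixel lattice disk
    centers: list[tuple[int, int]] = []
    interior_margin = 4.0
    for radius in sizes:
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(cell_radius - interior_margin, 0.5))
            cand = (
                int(round(center[0] + rad * np.sin(ang))),
                int(round(center[1] + rad * np.cos(ang))),
            )
            if all(
                max(abs(cand[0] - c0), abs(cand[1] - c1)) >= 6 for c0, c1 in centers
            ):
                centers.append(cand)
                pockets |= _disk(cell.shape, cand, radius)
                break
        else:  # crowded cell: give up on this pocket
            continue
    return pockets & cell


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Build geometry, masks and concentration fields for one phantom."""
    h, w = params.height, params.width
    center = params.cell_center or ((h - 1) / 2.0, (w - 1) / 2.0)
    border_clearance = min(
        center[0], center[1], h - 1 - center[0], w - 1 - center[1]
    )
    if params.cell_radius + 3 > border_clearance:
        raise GeometryError(
            f"cell radius {params.cell_radius} leaves less than a 3-pixel border margin"
        )
    if params.dmso_cell <= 0 or params.dmso_channel <= 0:
        raise GeometryError("concentrations must be positive")
    if not (0 <= params.intracellular_ice_fraction < 1):
        raise GeometryError("intracellular_ice_fraction must lie in [0, 1)")

    geom = _rng(params.seed, "geometry")
    cell = _disk((h, w), center, params.cell_radius)
    nucleus = _disk((h, w), center, params.nucleus_radius) & cell

    # unfrozen halo hugging the membrane: Chebyshev distance 1 from the cell
    dist_to_cell = ndimage.distance_transform_cdt(~cell, metric="chessboard")
    halo = (dist_to_cell >= 1) & (dist_to_cell <= 1)

    extracellular = ~cell & ~halo
    # Voronoi-like crystal tiling: channels along ridges between crystal seeds
    n_seeds = max(int(params.n_ice_crystals), 2)
    seeds = []
    while len(seeds) < n_seeds:
        cand = geom.uniform(low=(0, 0), high=(h - 1, w - 1), size=2)
        if np.hypot(cand[0] - center[0], cand[1] - center[1]) > params.cell_radius + 2:
            seeds.append(cand)
    seeds = np.asarray(seeds)
    rr, cc = np.mgrid[0:h, 0:w]
    d = np.sqrt(
        (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    )
    d.sort(axis=-1)
    ridge = (d[..., 1] - d[..., 0]) < params.channel_width
    ice_out = extracellular & ~ridge
    solution = ~ice_out  # channel + halo + cell
    ice_out, solution = _smooth_tiling(ice_out, solution, cell)
    ice_out &= ~cell

    pockets = np.zeros_like(cell, dtype=bool)
    if params.intracellular_ice_fraction > 0:
        pockets = _place_ice_pockets(
            cell, (int(round(center[0])), int(round(center[1]))),
            params.cell_radius, params.intracellular_ice_fraction, geom,
        )

    channel = ~cell & ~ice_out
    masks = CompartmentMasks(cell, ice_out, pockets, channel)
    masks.validate()

    # ----- concentration fields -----
    frng = _rng(params.seed, "field")
    dmso = np.zeros((h, w))
    if params.heterogeneity_sd > 0:
        sigma2 = np.log1p(params.heterogeneity_sd**2)
        mu = np.log(params.dmso_cell) - sigma2 / 2.0
        intra = frng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=(h, w))
    else:
        intra = np.full((h, w), params.dmso_cell)
    dmso[cell] = intra[cell]
    dmso[nucleus] *= params.nucleus_dmso_factor
    if params.gradient_toward_ice and ice_out.any():
        gap = ndimage.distance_transform_cdt(~ice_out, metric="chessboard").astype(float)
        g = gap[channel]
        span = g.max() - g.min()
        scale = 0.7 + 0.6 * (g - g.min()) / span if span > 0 else np.ones_like(g)
        dmso[channel] = params.dmso_channel * scale
    else:
        dmso[channel] = params.dmso_channel
    dmso[ice_out] = 0.0
    dmso[pockets] = 0.0

    amide = np.full((h, w), params.amide_background)
    if params.amide_heterogeneity_sd > 0:
        sigma2 = np.log1p(params.amide_heterogeneity_sd**2)
        mu = np.log(params.amide_cell) - sigma2 / 2.0
        amide_in = frng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=(h, w))
    else:
        amide_in = np.full((h, w), params.amide_cell)
    amide[cell] = amide_in[cell]

    oh = np.full((h, w), params.oh_background)
    oh[ice_out | pockets] = params.ice_level

    dna = np.zeros((h, w))
    dna[cell] = params.dna_cytosol
    dna[nucleus] = params.dna_nucleus

    fields = {"dmso": dmso, "amide": amide, "ice": oh, "dna": dna}

    c_i = float(dmso[cell].mean())
    c_o = float(dmso[channel].mean())
    scene = SyntheticScene(
        params=params,
        truth_masks=masks,
        concentration_fields=fields,
        true_P=c_o / c_i,
        true_cv=float(dmso[cell].std(ddof=1) / c_i),
        true_aic=float(pockets.sum() / cell.sum()),
    )
    return scene


def render_cube(
    scene: SyntheticScene,
    axis: SpectralAxis | None = None,
    bands: tuple[BandDefinition, ...] | None = None,
) -> SpectralCube:
    """Render per-pixel spectra from the scene's concentration fields.

    Each band contributes one Gaussian line (SD = 2 axis steps) at its
    literature center, scaled by the local field; a constant baseline and
    signal-proportional noise are added, then cosmic-ray spikes as single
    wavenumber samples at isolated pixels.  Deterministic in the scene seed.
    """
    params = scene.params
    axis = axis or default_axis()
    bands = bands or default_bands()
    wn = axis.wavenumbers_cm1
    for b in bands:
        if b.initial_cm1 < wn[0] or b.initial_cm1 > wn[-1]:
            raise AxisError(f"axis does not span band {b.name!r}")
    h, w = params.height, params.width
    sd = 2.0 * axis.step_cm1
    signal = np.zeros((h, w, len(axis)))
    for b in bands:
        if b.name not in scene.concentration_fields:
            continue
        profile = np.exp(-0.5 * ((wn - b.initial_cm1) / sd) ** 2)
        signal += scene.concentration_fields[b.name][:, :, None] * profile[None, None, :]
    cube_values = signal + params.baseline

    if params.noise_sd > 0:
        nrng = _rng(params.seed, "noise")
        if params.noise_model == "poisson":
            gain = params.noise_sd**2
            cube_values = nrng.poisson(np.maximum(cube_values, 0) / gain) * gain
        else:
            noise_scale = params.noise_sd * signal + params.noise_floor
            cube_values = cube_values + nrng.normal(0.0, 1.0, signal.shape) * noise_scale

    if params.n_spikes > 0:
        srng = _rng(params.seed, "spikes")
        target = next(b for b in bands if b.name == params.spike_band)
        center_idx = axis.index_nearest(target.initial_cm1)
        amp = params.spike_amplitude * max(
            float(f.max()) for f in scene.concentration_fields.values()
        )
        pixels: list[tuple[int, int]] = []
        while len(pixels) < params.n_spikes:
            r, c = int(srng.integers(0, h)), int(srng.integers(0, w))
            if all(max(abs(r - pr), abs(c - pc)) >= 2 for pr, pc in pixels):
                pixels.append((r, c))
        for r, c in pixels:
            k = int(srng.integers(center_idx - 2, center_idx + 3))
            cube_values[r, c, k] += amp

    return SpectralCube(h, w, axis, cube_values)


#: Named parameter sets emulating the study conditions: cells at 10% DMSO and
#: 1 C/min (near-unity partitioning), 1% DMSO (strong trapping, P ~ 0.2),
#: 5 C/min cooling (P ~ 1.3), and fast-cooled cells with intracellular ice.
PRESETS: dict[str, SceneParams] = {
    "baseline": SceneParams(dmso_channel=1.07, nucleus_dmso_factor=0.95),
    "low-dmso": SceneParams(dmso_channel=0.21, nucleus_dmso_factor=0.95),
    "fast-cool": SceneParams(dmso_channel=1.30, nucleus_dmso_factor=0.95),
    "iif": SceneParams(
        dmso_channel=1.20,
        nucleus_dmso_factor=0.95,
        intracellular_ice_fraction=0.08,
    ),
}
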