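"""Compartment segmentation: cell body, extracellular/intracellular ice,
unfrozen channels.

The cell boundary is located on the amide I map by a classical morphological
chain: Sobel gradient magnitude, thresholding at a sensitivity-scaled
automatic level, dilation with two perpendicular line structuring elements,
hole filling, border clearing, and smoothing erosions; the largest surviving
4-connected interior component is the cell.  Ice is thresholded on the OH
map and split by the cell mask; everything extracellular that is not ice is
unfrozen channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, segmentation as sk_seg

from .errors import EmptyChannelError, NoCellError, TooSmallCellError
from .peak_quant import IntensityMap
from .spectral_io import AnalysisConfig

__all__ = [
    "CompartmentMasks",
    "detect_edges",
    "segment_cell",
    "segment_all_cells",
    "segment_ice",
    "derive_channels",
    "segment_compartments",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class CompartmentMasks:
    """Boolean per-pixel maps of the three compartments (plus ice inside the cell).

    The extracellular space partitions exactly into ice and unfrozen channel;
    intracellular ice is a subset of the cell mask.
    """

    cell: np.ndarray
    ice_extracellular: np.ndarray
    ice_intracellular: np.ndarray
    channel: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.cell, self.ice_extracellular,
                                    self.ice_intracellular, self.channel)}
        if len(shapes) != 1:
            raise ValueError("compartment masks must share one shape")

    def validate(self) -> None:
        """Assert the partition invariants; raises AssertionError on violation."""
        assert not np.any(self.cell & self.ice_extracellular)
        assert not np.any(self.cell & self.channel)
        assert not np.any(self.ice_extracellular & self.channel)
        assert np.array_equal(self.channel, ~self.cell & ~self.ice_extracellular)
        assert not np.any(self.ice_intracellular & ~self.cell)

    @property
    def n_cell(self) -> int:
        return int(self.cell.sum())

    @property
    def n_channel(self) -> int:
        return int(self.channel.sum())

    def counts(self) -> dict:
        return {
            "n_cell": int(self.cell.sum()),
            "n_channel": int(self.channel.sum()),
            "n_ice_out": int(self.ice_extracellular.sum()),
            "n_ice_in": int(self.ice_intracellular.sum()),
        }


def _as_values(m: IntensityMap | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, IntensityMap) else np.asarray(m, dtype=float)


def detect_edges(values: np.ndarray, edge_sensitivity: float) -> np.ndarray:
    """Binary edge image: Sobel gradient above a scaled automatic threshold.

    The automatic level is Otsu's threshold on the gradient magnitudes; the
    sensitivity multiplies it, so a higher sensitivity admits fewer edges.
    """
    grad = filters.sobel(values)
    if np.ptp(grad) == 0.0:
        return np.zeros_like(grad, dtype=bool)
    auto = filters.threshold_otsu(grad)
    return grad > edge_sensitivity * auto


def segment_cell(
    amide_map: IntensityMap | np.ndarray, config: AnalysisConfig | None = None
) -> np.ndarray:
    """Cell mask from the amide I intensity map.

    Chain: Sobel edge detection at ``edge_sensitivity`` x automatic threshold;
    dilation with perpendicular line structuring elements (0 and 90 degrees,
    length ``line_strel_length``); hole filling; clearing of border-touching
    components; ``smooth_erosions`` smoothing erosions with a radius-1
    element (``smooth_strel``: 3x3 square or diamond) plus an intensity
    re-classification of the one-pixel boundary band (``boundary_refine``);
    then the largest 4-connected component is kept.  Two square erosions
    cancel the dilation the edge band and line elements introduce, and the
    refinement removes the residual sub-pixel bias, so the recovered outline
    is unbiased on sharp phantoms.
    """
    config = config or AnalysisConfig()
    values = _as_values(amide_map)
    edges = detect_edges(values, config.edge_sensitivity)
    if not edges.any():
        raise NoCellError("no edges detected on the amide map")
    return _largest_interior_component(
        _morphology_chain(edges, values, config), config
    )


def _morphology_chain(
    edges: np.ndarray, values: np.ndarray, config: AnalysisConfig
) -> np.ndarray:

    length = config.line_strel_length
    horiz = np.ones((1, length), dtype=bool)
    vert = np.ones((length, 1), dtype=bool)
    dilated = ndimage.binary_dilation(edges, vert)
    dilated = ndimage.binary_dilation(dilated, horiz)
    filled = ndimage.binary_fill_holes(dilated)
    cleared = sk_seg.clear_border(filled)
    smoothed = cleared
    strel = (
        np.ones((3, 3), dtype=bool)
        if config.smooth_strel == "square"
        else ndimage.generate_binary_structure(2, 1)
    )
    for _ in range(config.smooth_erosions):
        smoothed = ndimage.binary_erosion(smoothed, strel)
    if config.boundary_refine:
        smoothed = _refine_boundary(smoothed, values)
    return smoothed


def _refine_boundary(mask: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Re-classify the one-pixel boundary band by amide intensity.

    Morphological erosion localizes the outline only to about half a pixel;
    each pixel in the band between the eroded and dilated mask is assigned to
    the cell when its amide intensity exceeds the midpoint of the robust
    (median) cell and background levels.  On a sharp boundary this removes
    the residual half-pixel bias of the structuring elements.
    """
    square = np.ones((3, 3), dtype=bool)
    inner = ndimage.binary_erosion(mask, square)
    outer = ndimage.binary_dilation(mask, square)
    if not inner.any() or not (~outer).any():
        return mask
    midpoint = 0.5 * (np.median(values[inner]) + np.median(values[~outer]))
    band = outer & ~inner
    refined = mask.copy()
    refined[band] = values[band] >= midpoint
    return refined


def _largest_interior_component(
    smoothed: np.ndarray, config: AnalysisConfig
) -> np.ndarray:
    labels, n = ndimage.label(smoothed, structure=_FOUR_CONN)
    if n == 0:
        raise NoCellError("no interior component survives the morphology chain")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    cell = labels == best
    if cell.sum() < config.min_cell_pixels:
        raise TooSmallCellError(
            f"largest component has {int(cell.sum())} pixels "
            f"(< {config.min_cell_pixels})"
        )
    return cell


def segment_all_cells(
    amide_map: IntensityMap | np.ndarray, config: AnalysisConfig | None = None
) -> list[np.ndarray]:
    """All interior cell components, largest first.

    Same chain as :func:`segment_cell`, but instead of keeping only the
    largest component, every 4-connected interior component of at least
    ``min_cell_pixels`` is returned — for rasters that captured several
    cells.
    """
    config = config or AnalysisConfig()
    values = _as_values(amide_map)
    edges = detect_edges(values, config.edge_sensitivity)
    if not edges.any():
        raise NoCellError("no edges detected on the amide map")
    smoothed = _morphology_chain(edges, values, config)
    labels, n = ndimage.label(smoothed, structure=_FOUR_CONN)
    if n == 0:
        raise NoCellError("no interior component survives the morphology chain")
    comps = [labels == i for i in range(1, n + 1)]
    comps = [c for c in comps if c.sum() >= config.min_cell_pixels]
    if not comps:
        raise TooSmallCellError(
            f"no component reaches {config.min_cell_pixels} pixels"
        )
    return sorted(comps, key=lambda c: int(c.sum()), reverse=True)


def segment_ice(
    ice_map: IntensityMap | np.ndarray,
    cell: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split supra-threshold OH pixels into extracellular and intracellular ice.

    The threshold is Otsu's bimodal level over the whole map unless an explicit
    value is given.  Intracellular ice components of a single pixel are
    discarded as shot noise.  A degenerate (constant) map yields two empty
    masks.
    """
    values = _as_values(ice_map)
    if threshold is None:
        if np.ptp(values) == 0.0:
            empty = np.zeros_like(cell, dtype=bool)
            return empty, empty.copy()
        threshold = float(filters.threshold_otsu(values))
        # Otsu returns the first bin of its optimal plateau; with a wide
        # empty gap between the OH background and the ice mode that is the
        # gap's bottom edge, where integration jitter misclassifies stray
        # background pixels.  A few ISODATA refinements (threshold = midpoint
        # of the two class means) recenter it between the modes.
        for _ in range(10):
            below = values[values < threshold]
            above = values[values >= threshold]
            if not below.size or not above.size:
                break
            new = 0.5 * (float(below.mean()) + float(above.mean()))
            if abs(new - threshold) < 1e-9:
                break
            threshold = new
    ice = values >= threshold
    ice_out = ice & ~cell
    ice_in = ice & cell
    if ice_in.any():
        labels, n = ndimage.label(ice_in, structure=_FOUR_CONN)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        for lab, size in enumerate(sizes, start=1):
            if size <= 1:
                ice_in[labels == lab] = False
    return ice_out, ice_in


def derive_channels(cell: np.ndarray, ice_extracellular: np.ndarray) -> np.ndarray:
    """Unfrozen-channel mask: extracellular space that is not ice."""
    if cell.shape != ice_extracellular.shape:
        raise ValueError("masks must share one shape")
    channel = ~cell & ~ice_extracellular
    if not channel.any():
        raise EmptyChannelError("no unfrozen-channel pixels; C_o is undefined")
    return channel


def segment_compartments(
    amide_map: IntensityMap | np.ndarray,
    ice_map: IntensityMap | np.ndarray,
    config: AnalysisConfig | None = None,
) -> CompartmentMasks:
    """Full three-compartment segmentation from the amide I and OH maps."""
    config = config or AnalysisConfig()
    cell = segment_cell(amide_map, config)
    ice_out, ice_in = segment_ice(ice_map, cell, config.ice_threshold)
    channel = derive_channels(cell, ice_out)
    masks = CompartmentMasks(cell, ice_out, ice_in, channel)
    masks.validate()
    return masks
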