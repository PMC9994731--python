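"""Quantitative outputs: partitioning ratio, heterogeneity, ice-area
fraction, line scans, extracellular gap profiles, nucleus/cytosol ratio, and
replicate statistics.

The partitioning ratio of a cryoprotectant is

    P = C_o / C_i

where C_o is the mean integrated DMSO band intensity over the unfrozen
extracellular channel pixels and C_i the mean over the cell pixels.  P > 1
means the solute is enriched outside the cell at the imaging temperature;
P < 1 means it is trapped inside.  Heterogeneity is reported as the
coefficient of variation (sample SD over mean) of the intracellular DMSO
signal, and intracellular ice as the area fraction AIC = |ice in cell| /
|cell|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import filters

from .errors import (
    DegenerateCellError,
    EmptyChannelError,
    InsufficientReplicatesError,
    NoIceError,
    NoNucleusError,
)
from .peak_quant import IntensityMap
from .segmentation import CompartmentMasks
from .spectral_io import AnalysisConfig

__all__ = [
    "PartitioningResult",
    "LineScan",
    "GapProfile",
    "ReplicateSummary",
    "partitioning_ratio",
    "coefficient_of_variation",
    "ice_area_fraction",
    "line_scan",
    "gap_profile",
    "nucleus_cytosol_ratio",
    "replicate_summary",
]


def _values(m: IntensityMap | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, IntensityMap) else np.asarray(m, dtype=float)


@dataclass
class PartitioningResult:
    """All per-cell quantities for one image."""

    C_o: float
    C_i: float
    P: float
    cv_intracellular: float
    aic: float
    n_cell: int
    n_channel: int
    n_ice_in: int
    n_ice_out: int
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "P": self.P,
            "C_o": self.C_o,
            "C_i": self.C_i,
            "cv_intracellular": self.cv_intracellular,
            "aic": self.aic,
            "n_cell": self.n_cell,
            "n_channel": self.n_channel,
            "n_ice_in": self.n_ice_in,
            "n_ice_out": self.n_ice_out,
            "qc": self.qc,
        }


@dataclass
class LineScan:
    """One image row of intensities with per-pixel compartment labels."""

    row: int
    values: np.ndarray
    labels: list[str]


@dataclass
class GapProfile:
    """Mean channel DMSO intensity binned by distance to the nearest ice pixel."""

    distance_bins: np.ndarray  # bin centers, pixels (Chebyshev distance)
    mean_intensity: np.ndarray
    counts: np.ndarray


@dataclass
class ReplicateSummary:
    """Mean +/- standard error over per-cell replicates, with optional t-test."""

    n: int
    mean: float
    se: float
    t: float | None = None
    df: float | None = None
    p: float | None = None
    significant: bool | None = None


def partitioning_ratio(
    dmso_map: IntensityMap | np.ndarray,
    masks: CompartmentMasks,
    config: AnalysisConfig | None = None,
) -> PartitioningResult:
    """Partitioning ratio P = C_o / C_i plus CV and AIC for one image.

    C_o averages over unfrozen-channel pixels only (never extracellular ice,
    which excludes the solute); C_i averages over all cell pixels, including
    intracellular-ice pixels unless ``config.include_ice_in_ci`` is False.
    """
    config = config or AnalysisConfig()
    if isinstance(dmso_map, IntensityMap) and dmso_map.rejected:
        raise ValueError("refusing to quantify a QC-rejected intensity map")
    values = _values(dmso_map)
    counts = masks.counts()
    if counts["n_channel"] == 0:
        raise EmptyChannelError("no channel pixels; C_o undefined")
    if counts["n_cell"] == 0:
        raise DegenerateCellError("no cell pixels; C_i undefined")
    cell_mask = masks.cell if config.include_ice_in_ci else (masks.cell & ~masks.ice_intracellular)
    C_i = float(values[cell_mask].mean())
    C_o = float(values[masks.channel].mean())
    if C_i == 0.0:
        raise DegenerateCellError("intracellular mean is zero; P undefined")
    qc = {"low_confidence": counts["n_cell"] < config.min_cell_pixels}
    if isinstance(dmso_map, IntensityMap):
        qc.update(
            spike_count=dmso_map.spike_count,
            rejected=dmso_map.rejected,
            despike_passes_used=dmso_map.despike_passes_used,
        )
    return PartitioningResult(
        C_o=C_o,
        C_i=C_i,
        P=C_o / C_i,
        cv_intracellular=coefficient_of_variation(values, cell_mask),
        aic=ice_area_fraction(masks),
        **counts,
        qc=qc,
    )


def coefficient_of_variation(
    dmso_map: IntensityMap | np.ndarray, cell: np.ndarray
) -> float:
    """Sample SD over mean of the intracellular signal (scale-free)."""
    values = _values(dmso_map)[np.asarray(cell, dtype=bool)]
    if values.size < 2:
        raise DegenerateCellError("CV needs at least two cell pixels")
    mean = float(values.mean())
    if mean == 0.0:
        raise DegenerateCellError("intracellular mean is zero; CV undefined")
    return float(values.std(ddof=1) / mean)


def ice_area_fraction(masks: CompartmentMasks) -> float:
    """AIC: intracellular-ice pixels over cell pixels (0 when no ice)."""
    n_cell = int(masks.cell.sum())
    if n_cell == 0:
        raise DegenerateCellError("AIC needs a nonempty cell mask")
    return float(masks.ice_intracellular.sum() / n_cell)


def _label_at(masks: CompartmentMasks, row: int, col: int) -> str:
    if masks.cell[row, col]:
        return "cell"
    if masks.ice_extracellular[row, col]:
        return "ice"
    return "channel"


def line_scan(
    m: IntensityMap | np.ndarray, masks: CompartmentMasks, row: int | None = None
) -> LineScan:
    """Intensity profile along one image row with compartment labels.

    Default row is the cell centroid row.
    """
    values = _values(m)
    if row is None:
        row = int(round(ndimage.center_of_mass(masks.cell)[0]))
    if not (0 <= row < values.shape[0]):
        raise IndexError(f"row {row} outside image of height {values.shape[0]}")
    labels = [_label_at(masks, row, c) for c in range(values.shape[1])]
    return LineScan(row=row, values=values[row].copy(), labels=labels)


def line_scan_ratio(
    m: IntensityMap | np.ndarray, masks: CompartmentMasks, n_rows: int = 5
) -> float:
    """Partitioning ratio estimated from line scans through the cell.

    Cross-validation of the mask-based estimate: ``n_rows`` scans centered on
    the cell centroid row are pooled, and the mean of channel-labeled samples
    is divided by the mean of cell-labeled samples.  A handful of rows is
    needed because a single scan crosses only ~2R cell pixels and its mean
    carries the full pixel-to-pixel heterogeneity of the cell interior.
    Samples at a membrane crossing (an along-scan neighbor on the other side
    of the cell/channel transition) are excluded: they straddle the boundary
    and are not representative of either side.  Channel samples next to ice
    are kept — the unfrozen channels are only a few pixels wide, and the ice
    interface carries no solute signal to bleed across.
    """
    values = _values(m)
    center = int(round(ndimage.center_of_mass(masks.cell)[0]))
    half = n_rows // 2
    chan_vals: list[float] = []
    cell_vals: list[float] = []
    for row in range(max(center - half, 0), min(center + half + 1, values.shape[0])):
        scan = line_scan(values, masks, row)
        labs = scan.labels
        for c, (v, lab) in enumerate(zip(scan.values, labs)):
            if lab not in ("cell", "channel"):
                continue
            membrane = False
            for cc in (c - 1, c + 1):
                if 0 <= cc < len(labs):
                    if {lab, labs[cc]} == {"cell", "channel"}:
                        membrane = True
            if membrane:
                continue
            if lab == "cell":
                cell_vals.append(v)
            else:
                chan_vals.append(v)
    if not chan_vals:
        raise EmptyChannelError("line scans cross no channel pixels")
    if not cell_vals:
        raise DegenerateCellError("line scans cross no cell pixels")
    cell_mean = float(np.mean(cell_vals))
    if cell_mean == 0.0:
        raise DegenerateCellError("line-scan cell mean is zero")
    return float(np.mean(chan_vals) / cell_mean)


def gap_profile(
    dmso_map: IntensityMap | np.ndarray,
    masks: CompartmentMasks,
    n_bins: int = 6,
) -> GapProfile:
    """Solute-polarization profile of the unfrozen channels.

    For every channel pixel, the Chebyshev (chessboard) distance to the
    nearest extracellular-ice pixel is computed; distances are split into
    ``n_bins`` equal-width bins and the mean DMSO intensity per bin reported.
    A rising profile indicates solute enrichment toward the channel center.
    """
    values = _values(dmso_map)
    if not masks.ice_extracellular.any():
        raise NoIceError("no extracellular ice; gap profile undefined")
    if not masks.channel.any():
        raise EmptyChannelError("no channel pixels; gap profile undefined")
    dist = ndimage.distance_transform_cdt(
        ~masks.ice_extracellular, metric="chessboard"
    ).astype(float)
    d = dist[masks.channel]
    v = values[masks.channel]
    d_max = float(d.max())
    edges = np.linspace(d.min(), d_max, n_bins + 1) if d_max > d.min() else None
    if edges is None:
        return GapProfile(
            distance_bins=np.array([float(d.min())]),
            mean_intensity=np.array([float(v.mean())]),
            counts=np.array([d.size]),
        )
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    centers, means, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(float(v[sel].mean()))
            counts.append(int(sel.sum()))
    return GapProfile(
        distance_bins=np.array(centers),
        mean_intensity=np.array(means),
        counts=np.array(counts),
    )


def nucleus_cytosol_ratio(
    dmso_map: IntensityMap | np.ndarray,
    dna_map: IntensityMap | np.ndarray,
    cell: np.ndarray,
) -> float:
    """Mean DMSO in the nucleus over mean DMSO in the rest of the cell.

    The nucleus is segmented as the supra-threshold DNA (O-P-O band) region
    inside the cell, threshold by Otsu's method over intracellular DNA
    intensities.
    """
    cell = np.asarray(cell, dtype=bool)
    if not cell.any():
        raise DegenerateCellError("empty cell mask")
    if isinstance(dna_map, IntensityMap) and dna_map.rejected:
        raise ValueError("refusing to use a QC-rejected DNA map")
    dna = _values(dna_map)
    dmso = _values(dmso_map)
    inside = dna[cell]
    if np.ptp(inside) == 0.0:
        raise NoNucleusError("DNA signal is flat inside the cell")
    thresh = float(filters.threshold_otsu(inside))
    nucleus = cell & (dna >= thresh)
    cytosol = cell & ~nucleus
    if not nucleus.any():
        raise NoNucleusError("no supra-threshold DNA pixels inside the cell")
    if not cytosol.any():
        raise NoNucleusError("nucleus fills the whole cell; no cytosol reference")
    cyto_mean = float(dmso[cytosol].mean())
    if cyto_mean == 0.0:
        raise DegenerateCellError("cytosolic DMSO mean is zero")
    return float(dmso[nucleus].mean() / cyto_mean)


def replicate_summary(
    per_cell_P,
    other=None,
    welch: bool = True,
) -> ReplicateSummary:
    """Mean and standard error of per-cell values, with optional two-sample t-test.

    The default test is Welch's unequal-variance t-test (two-sided); pass
    ``welch=False`` for the pooled-variance Student variant.  Significance is
    flagged at the 95% confidence level (p < 0.05).
    """
    a = np.asarray(per_cell_P, dtype=float)
    if a.size < 2:
        raise InsufficientReplicatesError("need at least two replicates")
    summary = ReplicateSummary(
        n=int(a.size),
        mean=float(a.mean()),
        se=float(a.std(ddof=1) / np.sqrt(a.size)),
    )
    if other is not None:
        b = np.asarray(other, dtype=float)
        if b.size < 2:
            raise InsufficientReplicatesError("comparison group needs >= 2 replicates")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        summary.t = float(res.statistic)
        summary.df = float(res.df)
        summary.p = float(res.pvalue)
        summary.significant = bool(res.pvalue < 0.05)
    return summary
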