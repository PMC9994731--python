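"""Spectral-cube containers, band definitions, configuration, and text I/O.

A spectral cube is an H x W raster in which every pixel holds one Raman
spectrum on a shared wavenumber axis (nominal step ~4.83 cm^-1).  The
canonical interchange format is a plain-text table: a header line declaring
the raster shape, then one row per axis sample whose first column is the
wavenumber and whose remaining H*W columns are pixel intensities in row-major
order (row 0 left to right, then row 1, ...).  Tab and comma delimiters are
auto-detected.

Band definitions carry the search range and starting wavenumber of each
marker band: OH stretching for ice, amide I for the cell body, the symmetric
C-S stretch for DMSO, and the O-P-O backbone stretch for DNA.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import AxisError, BandError, FormatError, ShapeError

__all__ = [
    "SpectralAxis",
    "SpectralCube",
    "BandDefinition",
    "AnalysisConfig",
    "default_axis",
    "default_bands",
    "read_cube",
    "write_cube",
    "read_bands",
    "write_bands",
    "write_mask",
    "read_mask",
]

NOMINAL_STEP_CM1 = 4.83


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber grid shared by every pixel spectrum."""

    wavenumbers_cm1: np.ndarray
    step_cm1: float = NOMINAL_STEP_CM1

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers_cm1, dtype=float)
        object.__setattr__(self, "wavenumbers_cm1", wn)
        if wn.ndim != 1 or wn.size < 2:
            raise AxisError("axis needs at least two samples")
        diffs = np.diff(wn)
        if not np.all(diffs > 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        step = float(np.mean(diffs))
        object.__setattr__(self, "step_cm1", step)
        if np.max(np.abs(diffs - step)) > 0.10 * step:
            raise AxisError("axis spacing deviates more than 10% from the mean step")

    def __len__(self) -> int:
        return int(self.wavenumbers_cm1.size)

    def index_nearest(self, wavenumber_cm1: float) -> int:
        return int(np.argmin(np.abs(self.wavenumbers_cm1 - wavenumber_cm1)))

    def band_slice(self, band: "BandDefinition") -> tuple[int, int]:
        """Inclusive index bounds of the band range on this axis.

        Raises BandError when fewer than 9 samples fall inside the range.
        """
        wn = self.wavenumbers_cm1
        inside = np.nonzero((wn >= band.range_low_cm1) & (wn <= band.range_high_cm1))[0]
        if inside.size < 9:
            raise BandError(
                f"band {band.name!r} ({band.range_low_cm1}-{band.range_high_cm1} cm^-1) "
                f"covers only {inside.size} axis samples (need >= 9)"
            )
        return int(inside[0]), int(inside[-1])


@dataclass(frozen=True)
class SpectralCube:
    """H x W raster of per-pixel spectra on a shared axis.

    ``intensities`` has shape (height, width, len(axis)); pixel order is
    row-major from the top-left, 0-based (row, col).
    """

    height: int
    width: int
    axis: SpectralAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", inten)
        if self.height < 9 or self.width < 9:
            raise ShapeError("raster must be at least 9 x 9 pixels")
        expected = (self.height, self.width, len(self.axis))
        if inten.shape != expected:
            raise ShapeError(f"intensities shape {inten.shape} != {expected}")
        if not np.all(np.isfinite(inten)):
            raise FormatError("cube contains non-finite intensities")

    def spectrum(self, row: int, col: int) -> np.ndarray:
        return self.intensities[row, col]


@dataclass(frozen=True)
class BandDefinition:
    """Search window for one marker band.

    range_low/range_high bound the peak search; initial_cm1 is the literature
    band center the search starts from.
    """

    name: str
    range_low_cm1: float
    range_high_cm1: float
    initial_cm1: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if not (self.range_low_cm1 < self.initial_cm1 < self.range_high_cm1):
            raise BandError(
                f"band {self.name!r}: need range_low < initial < range_high, got "
                f"{self.range_low_cm1} / {self.initial_cm1} / {self.range_high_cm1}"
            )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    derivative_sensitivity
        Slope-ratio threshold of the peak-boundary walk (flank stops where the
        outward slope falls to this fraction of the slope one step inward).
    edge_sensitivity
        Multiplier on the automatic gradient threshold used for cell edge
        detection; lower values admit more edges.  The useful range on these
        images is 0.5-0.9.
    max_despike_passes / scatter_reject_threshold
        Cosmic-ray handling: up to this many neighbor-average passes, and
        outright rejection of images with more scattered-signal pixels than
        the threshold.
    spike_qc_band
        Which intensity map(s) the scattered-signal rejection counts spikes
        on: the name of one band, or "union" for the union of the DMSO and
        ice spike masks.
    """

    derivative_sensitivity: float = 0.1
    edge_sensitivity: float = 0.65
    max_despike_passes: int = 3
    scatter_reject_threshold: int = 10
    min_peak_steps: int = 4
    max_peak_steps: int = 8
    spike_k: float = 5.0
    spike_rel_floor: float = 0.10
    spike_abs_floor_frac: float = 0.01
    spike_qc_band: str = "dmso"
    line_strel_length: int = 3
    smooth_erosions: int = 2
    smooth_strel: str = "square"
    boundary_refine: bool = True
    ice_threshold: float | None = None  # None = automatic (Otsu)
    include_ice_in_ci: bool = True
    welch_ttest: bool = True
    allow_iif: bool = False
    iif_reject_aic: float = 0.02
    min_cell_pixels: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.derivative_sensitivity < 1.0):
            raise ValueError("derivative_sensitivity must lie in (0, 1)")
        if not (0.5 <= self.edge_sensitivity <= 0.9):
            raise ValueError("edge_sensitivity must lie in [0.5, 0.9]")
        if not (1 <= self.max_despike_passes <= 3):
            raise ValueError("max_despike_passes must lie in [1, 3]")
        if self.min_peak_steps > self.max_peak_steps:
            raise ValueError("min_peak_steps must be <= max_peak_steps")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_axis(
    low_cm1: float = 600.0, high_cm1: float = 3250.0, step_cm1: float = NOMINAL_STEP_CM1
) -> SpectralAxis:
    """Uniform axis spanning all four default marker bands."""
    n = int(np.floor((high_cm1 - low_cm1) / step_cm1)) + 1
    return SpectralAxis(low_cm1 + step_cm1 * np.arange(n), step_cm1)


def default_bands() -> tuple[BandDefinition, ...]:
    """The four marker bands used throughout.

    The protein/lipid (amide I) range is 1,610-1,710 cm^-1, symmetric about
    the 1,660 cm^-1 band center and comparable in span to the other bands.
    """
    return (
        BandDefinition("ice", 3087.0, 3162.0, 3125.0, "OH stretching"),
        BandDefinition("amide", 1610.0, 1710.0, 1660.0, "Amide I / alkyl C=C stretching"),
        BandDefinition("dmso", 650.0, 740.0, 673.0, "Symmetric CS stretching"),
        BandDefinition("dna", 760.0, 810.0, 785.0, "O-P-O stretching of DNA"),
    )


def band_by_name(bands: Sequence[BandDefinition], name: str) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise BandError(f"no band named {name!r}")


# ---------------------------------------------------------------------------
# cube table I/O


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_cube(path: str | Path | io.TextIOBase) -> SpectralCube:
    """Read a spectral cube from the plain-text table format.

    Line 1: ``# height=H width=W``; line 2 optionally ``# meta ...``; then one
    row per axis sample (wavenumber followed by H*W row-major pixel values).
    """
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8") as fh:
            return read_cube(fh)
    lines = [ln.rstrip("\n") for ln in path if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise FormatError("missing '# height=H width=W' header line")
    header = lines[0].lstrip("#").strip()
    fields = dict(
        item.split("=", 1) for item in header.split() if "=" in item
    )
    try:
        height, width = int(fields["height"]), int(fields["width"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed cube header {lines[0]!r}") from exc
    body = lines[1:]
    while body and body[0].startswith("#"):
        body = body[1:]
    if not body:
        raise FormatError("cube table has no data rows")
    delim = _detect_delimiter(body[0])
    rows = []
    for ln in body:
        parts = ln.split(delim)
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"non-numeric value in row {ln[:60]!r}") from exc
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != height * width + 1:
        raise ShapeError(
            f"expected {height * width} spectral columns for a {height}x{width} raster, "
            f"found {data.shape[1] - 1}"
        )
    axis = SpectralAxis(data[:, 0])
    inten = data[:, 1:].T.reshape(height, width, len(axis))
    return SpectralCube(height, width, axis, inten)


def write_cube(cube: SpectralCube, path: str | Path, meta: dict | None = None) -> None:
    """Write a cube in the canonical text-table format (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# height={cube.height} width={cube.width}\n")
        if meta:
            kv = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"# meta {kv}\n")
        flat = cube.intensities.reshape(cube.height * cube.width, len(cube.axis)).T
        for i, wn in enumerate(cube.axis.wavenumbers_cm1):
            cells = "\t".join(repr(float(v)) for v in flat[i])
            fh.write(f"{float(wn)!r}\t{cells}\n")


# ---------------------------------------------------------------------------
# band-definition and mask I/O


def write_bands(bands: Sequence[BandDefinition], path: str | Path) -> None:
    payload = {
        b.name: {
            "low": b.range_low_cm1,
            "high": b.range_high_cm1,
            "initial": b.initial_cm1,
            "assignment": b.assignment,
        }
        for b in bands
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def read_bands(path: str | Path) -> tuple[BandDefinition, ...]:
    try:
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise FormatError(f"unparseable band file {path}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"band file {path} is not a mapping")
    bands = []
    for name, spec in payload.items():
        try:
            bands.append(
                BandDefinition(
                    name,
                    float(spec["low"]),
                    float(spec["high"]),
                    float(spec["initial"]),
                    str(spec.get("assignment", "")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"band {name!r}: need low/high/initial") from exc
    return tuple(bands)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a 0/1 text grid (one image row per line)."""
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter="\t")


def read_mask(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, delimiter="\t").astype(bool)
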