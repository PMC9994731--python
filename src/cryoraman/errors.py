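"""Exception hierarchy for the analysis pipeline.

Each pipeline stage raises a distinct subclass so the command-line driver can
map failures onto stable exit codes and one-line log reasons.
"""


class CryoRamanError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(CryoRamanError):
    """Malformed spectral-cube table or band-definition file."""

    exit_code = 6


class ShapeError(FormatError):
    """Column count disagrees with the declared raster dimensions."""


class AxisError(CryoRamanError):
    """Wavenumber axis is non-monotone, too short, or too uneven."""

    exit_code = 6


class BandError(CryoRamanError):
    """Band definition does not intersect the axis adequately."""

    exit_code = 6


class GeometryError(CryoRamanError):
    """Synthetic scene parameters are geometrically infeasible."""

    exit_code = 6


class ScatteredSignalError(CryoRamanError):
    """Image rejected: more than the allowed number of cosmic-ray pixels."""

    exit_code = 2


class NoCellError(CryoRamanError):
    """Segmentation found no interior cell component."""

    exit_code = 3


class TooSmallCellError(NoCellError):
    """Cell component below the 50-pixel validation regime."""


class EmptyChannelError(CryoRamanError):
    """No unfrozen-channel pixels: the extracellular mean is undefined."""

    exit_code = 4


class DegenerateCellError(CryoRamanError):
    """Intracellular mean is zero; ratios are undefined."""

    exit_code = 4


class IntracellularIceError(CryoRamanError):
    """Cell rejected for extensive intracellular ice formation."""

    exit_code = 5


class NoNucleusError(CryoRamanError):
    """DNA band gave no supra-threshold nucleus region."""

    exit_code = 4


class NoIceError(CryoRamanError):
    """No extracellular ice: distance-to-ice profiles are undefined."""

    exit_code = 4


class InsufficientReplicatesError(CryoRamanError):
    """Fewer than two replicates in a summary group."""

    exit_code = 6
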