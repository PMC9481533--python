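"""Exception hierarchy.

Every error raised on a violated precondition derives from ``FibrilError`` so
callers can catch package failures without masking programming errors.
"""


class FibrilError(Exception):
    """Base class for all fibrilstab errors."""


class StructureParseError(FibrilError):
    """A coordinate or map file could not be parsed."""


class EmptyStructureError(FibrilError):
    """A parsed structure contained zero atoms."""


class LayerAmbiguityError(FibrilError):
    """A chain spans more than ~1.5 helical rises along the axis."""


class MissingRadiusError(FibrilError):
    """An atom lacks a van der Waals radius needed for SASA."""


class ContextError(FibrilError):
    """A stability map was requested without enough fibril layers."""


class PairingError(FibrilError):
    """Two energy maps could not be paired atom-by-atom."""


class MaskOverlapError(FibrilError):
    """Site and reference masks/selections overlap."""


class EmptyMaskError(FibrilError):
    """A voxel mask came out empty."""


class DegenerateReferenceError(FibrilError):
    """max(reference) <= avg(solvent): occupancy undefined."""


class UndefinedCorrelationError(FibrilError):
    """Observed or simulated density is constant inside the mask."""


class SelectionError(FibrilError):
    """An atom selection is empty or otherwise invalid."""


class InsufficientColumnError(FibrilError):
    """Fewer than two ligand copies: no stacking geometry."""


class ComparabilityError(FibrilError):
    """Objects being compared do not share the required keys/receptor."""


class DegenerateDistributionError(FibrilError):
    """An engine's score distribution has zero spread."""
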