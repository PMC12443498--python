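"""Exception hierarchy for the riversdm pipeline.

Every stage raises a subclass of :class:`RiverSDMError` so the CLI can map
failures to a nonzero exit with the stage name attached.
"""


class RiverSDMError(Exception):
    """Base class for all riversdm errors."""


class ConfigError(RiverSDMError):
    """Configuration failed schema validation."""


class NetworkError(RiverSDMError):
    """Invalid or infeasible stream network."""


class NetworkCycleError(NetworkError):
    """The segment graph contains a cycle (must be a downstream forest)."""


class SyntheticDataError(RiverSDMError):
    """Synthetic riverscape generation failed a precondition."""


class CurationError(RiverSDMError):
    """Occurrence curation failed (e.g., too few eligible pseudoabsence cells)."""


class SelectionError(RiverSDMError):
    """Variable selection failed (zero variance, empty candidates)."""


class ModelingError(RiverSDMError):
    """Ensemble modeling failed (single-class data, no run passed selection)."""


class PriorityError(RiverSDMError):
    """Priority-area derivation failed (invalid polygon, empty region total)."""


class AssessmentError(RiverSDMError):
    """Habitat assessment failed (non-finite reading, unknown stressor category)."""
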