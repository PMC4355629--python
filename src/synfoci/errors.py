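"""Exception hierarchy for the synfoci pipeline."""


class SynfociError(Exception):
    """Base class for all synfoci errors."""


class FormatError(SynfociError):
    """An input file could not be read or has an unsupported layout."""


class ConfigurationError(SynfociError):
    """Required metadata (pixel size, frame interval) is missing and no override was given."""


class ParameterError(SynfociError):
    """An analysis parameter is out of its valid range."""


class PlacementError(SynfociError):
    """The requested number of non-overlapping synthetic objects does not fit the footprint."""


class RidgeError(SynfociError):
    """No moving-object ridge could be extracted from a kymograph."""
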