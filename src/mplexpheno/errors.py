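"""Exception hierarchy shared across the pipeline stages."""


class MplexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MplexError):
    """Invalid panel, tree, order, filter or parameter configuration."""


class GenerationError(MplexError):
    """Scene generation could not satisfy its geometric constraints."""


class LibraryError(MplexError):
    """Spectral-library construction failed (degenerate input image)."""


class UnmixingError(MplexError):
    """Unmixing is ill-posed (rank-deficient sensing matrix) or inputs mismatch."""


class IntegrityError(MplexError):
    """Internal consistency violated (e.g. empty mask for a labelled cell)."""
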