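"""Exception hierarchy shared across sptkin modules."""


class SptkinError(Exception):
    """Base class for all sptkin errors."""


class FormatError(SptkinError, ValueError):
    """A table is missing a required column or has the wrong shape."""


class ParseError(SptkinError, ValueError):
    """A cell could not be parsed; message names the offending row."""


class DuplicateLocalizationError(SptkinError, ValueError):
    """Two localizations share the same (frame, x, y)."""


class EmptyDatasetError(SptkinError, ValueError):
    """No usable jumps could be extracted from the input trajectories."""


class IncompatibleDatasetsError(SptkinError, ValueError):
    """Datasets differ in binning, lags or frame interval and cannot be pooled."""


class ModelValidationError(SptkinError, ValueError):
    """A diffusion model violates its invariants."""


class FitError(SptkinError, RuntimeError):
    """All optimisation starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class IncomparableFitsError(SptkinError, ValueError):
    """Two fits were not performed on the same residual vector."""


class InsufficientDataError(SptkinError, ValueError):
    """Fewer repeats/cultures than the statistic requires."""


class ConfigError(SptkinError, ValueError):
    """Invalid simulation or pipeline configuration."""
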