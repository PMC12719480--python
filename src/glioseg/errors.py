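"""Exception types shared across the pipeline."""


class GlioSegError(Exception):
    """Base class for package-specific errors."""


class ConfigError(GlioSegError, ValueError):
    """Invalid or inconsistent configuration."""


class DegenerateInputError(GlioSegError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant image)."""


class StratificationError(GlioSegError, ValueError):
    """A class has too few subjects (or samples) to stratify."""


class ManifestValidationError(GlioSegError, ValueError):
    """A manifest violates its contract (e.g. a subject with mixed labels)."""


class UndefinedMetricError(GlioSegError, ValueError):
    """A metric is undefined for the given inputs (zero denominator, empty mask)."""
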