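"""Exception hierarchy shared across the pipeline stages."""


class MipipeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MipipeError, ValueError):
    """Invalid parameter or simulation/analysis configuration."""


class FormatError(MipipeError, ValueError):
    """Malformed on-disk data (epochs table, events CSV, EDF montage)."""


class EmptyRecordingError(MipipeError, ValueError):
    """A trial selection produced no trials."""


class UndefinedBaselineError(MipipeError, ValueError):
    """Mu-suppression score requested with non-positive resting power."""


class PipelineError(MipipeError, RuntimeError):
    """A pipeline stage failed; message carries the stage name."""
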