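"""Exception types shared across the pipeline."""


class StrainTrackError(Exception):
    """Base class for all package errors."""


class InputError(StrainTrackError, ValueError):
    """Invalid argument values or malformed inputs."""


class DegenerateDataError(StrainTrackError, ValueError):
    """Data admit no defined answer (e.g. zero variance where a scale is needed)."""


class InconsistencyError(StrainTrackError, ValueError):
    """Internally contradictory state (e.g. reads counted for a strain with no unique content)."""


class ConfigError(StrainTrackError, ValueError):
    """Pipeline configuration failed validation before any compute."""
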