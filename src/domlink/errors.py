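"""Exception hierarchy.

Validation-type errors (bad input files, bad configuration, mismatched model
manifests) are distinguished from runtime errors so the command-line layer can
map them to distinct exit codes (2 vs 3).
"""


class DomLinkError(Exception):
    """Base class for all package errors."""


class ValidationError(DomLinkError):
    """Bad user input: files, configuration, or incompatible artifacts."""


class AlphabetError(ValidationError):
    """A sequence character outside the accepted amino-acid alphabet."""


class DuplicateIdError(ValidationError):
    """Two records in one dataset share an identifier."""


class EmptyDatasetError(ValidationError):
    """A dataset file contained no records."""


class FormatError(ValidationError):
    """A file does not follow its declared format."""


class LengthMismatchError(ValidationError):
    """A per-residue track does not match its sequence length."""


class RangeError(ValidationError):
    """A residue coordinate falls outside [1, L]."""


class ConfigError(ValidationError):
    """An invalid parameter combination."""


class ManifestError(ValidationError):
    """A trained model's manifest is incompatible with the requested encoding."""


class MissingChannelError(ValidationError):
    """A feature channel is enabled but its input track is absent."""


class EvaluationError(DomLinkError):
    """Predictions and ground truth cannot be compared."""
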