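"""Exception hierarchy shared across the package.

Three categories mirror the failure modes a pipeline can hit: bad
configuration (split sets, policy wiring), bad numeric parameters
(SNR <= 0, invalid wavelet level), and dataset I/O problems.
"""


class EmgAugError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmgAugError, ValueError):
    """Inconsistent pipeline configuration (splits, policies, CLI wiring)."""


class ParameterError(EmgAugError, ValueError):
    """Invalid numeric parameter for an operation."""


class DatasetIOError(EmgAugError, IOError):
    """Manifest / record file problems: missing files, fs or shape mismatch."""
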