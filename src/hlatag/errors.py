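"""Exception hierarchy."""


class HlatagError(Exception):
    """Base class for all package errors."""


class AlleleParseError(HlatagError, ValueError):
    """Malformed HLA allele string."""


class PanelError(HlatagError, ValueError):
    """Invalid panel configuration (dangling assay, duplicate id, bad rule)."""


class DataError(HlatagError, ValueError):
    """Inconsistent input data (duplicate calls, foreign alleles, missing reference)."""


class ClusterError(HlatagError, ValueError):
    """Degenerate or unusable fluorescence input."""
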