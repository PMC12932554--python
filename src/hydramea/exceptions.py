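"""Exception hierarchy for hydramea.

All errors derive from :class:`HydrameaError` so callers can catch the
package's failures with one clause; the subclasses distinguish malformed
files, inconsistent data, degenerate signals and bad parameters.
"""


class HydrameaError(Exception):
    """Base class for all hydramea errors."""


class FormatError(HydrameaError, ValueError):
    """A file does not conform to a documented layout."""


class IntegrityError(HydrameaError, ValueError):
    """Data is internally inconsistent (e.g. ragged channel lengths)."""


class DegenerateInputError(HydrameaError, ValueError):
    """Input signal carries no usable information (e.g. identically zero)."""


class ParameterError(HydrameaError, ValueError):
    """A parameter value is invalid or incompatible with the data."""
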