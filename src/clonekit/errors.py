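"""Exception hierarchy for clonekit.

All package-specific failures derive from :class:`ClonekitError`, so callers
can catch one base class at pipeline level while tests can assert on the
specific condition.
"""


class ClonekitError(Exception):
    """Base class for all clonekit errors."""


class FormatError(ClonekitError):
    """A file does not conform to its declared format (names the offending line)."""


class DialectError(FormatError):
    """A genepop file mixes or uses an unsupported allele-code width."""


class ValidationError(ClonekitError):
    """Input values violate a documented invariant (duplicate keys, bad enums...)."""


class CalibrationError(ClonekitError):
    """Clone-threshold calibration failed, e.g. a duplicate-library pair fell
    below the calibrated threshold (a contamination signature)."""


class SpectrumError(ClonekitError):
    """No usable loci remain after the allele-balance filters."""


class NoPeakError(ClonekitError):
    """No peak in the minor-allele fraction spectrum passes the mass filter."""


class StabilityError(ClonekitError):
    """Merging libraries shifted spectrum peaks: the libraries are likely not clonal."""


class InconclusiveError(ClonekitError):
    """A breeding-system call cannot be made from the available evidence."""
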