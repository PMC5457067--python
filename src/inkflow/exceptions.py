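"""Exception hierarchy for inkflow.

All inkflow errors derive from :class:`InkflowError` so callers can catch the
package's failures with a single except clause; the subclasses additionally
derive from ``ValueError`` because they signal invalid argument values.
"""


class InkflowError(Exception):
    """Base class for all inkflow errors."""


class DomainError(InkflowError, ValueError):
    """A physical quantity is outside its admissible domain (e.g. non-positive
    pressure, diameter, shear rate or viscosity)."""


class DegenerateFitError(InkflowError, ValueError):
    """The regression problem is degenerate: fewer than two distinct
    shear rates remain inside the fitting window."""


class ValidationError(InkflowError, ValueError):
    """A data table or record failed schema/consistency validation."""
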