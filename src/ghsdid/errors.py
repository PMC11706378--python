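"""Exception hierarchy for the ghsdid package.

All package-specific failures derive from :class:`GhsdidError` so callers can
catch one base class; subclasses distinguish validation problems (bad input
data), configuration problems, and estimation problems (degenerate designs).
"""


class GhsdidError(Exception):
    """Base class for all ghsdid errors."""


class ValidationError(GhsdidError):
    """An input value violates a documented constraint (e.g. coverage > 100)."""


class VocabularyError(ValidationError):
    """A categorical field is outside its closed vocabulary."""


class DuplicateKeyError(ValidationError):
    """A (country, vaccine, year) key appears more than once."""


class ConfigurationError(GhsdidError):
    """A configuration leaves nothing to analyze (e.g. empty panel)."""


class HierarchyError(GhsdidError):
    """A composite-score hierarchy is malformed or an operation degenerates it."""


class DegenerateAssignmentError(GhsdidError):
    """A cutoff produces an empty treated or control group."""


class EstimationError(GhsdidError):
    """An estimator cannot produce a valid estimate (e.g. all treated dropped)."""
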