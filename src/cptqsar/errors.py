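"""Exception hierarchy for the cptqsar pipeline."""


class CptQsarError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(CptQsarError):
    """A molecule record could not be parsed in the named format."""


class UnsupportedFormatError(CptQsarError):
    """Unknown molecule file format name."""


class ChargeModelError(CptQsarError):
    """Partial-charge assignment failed for an atom."""


class PreparationError(CptQsarError):
    """3D embedding / minimization failed."""


class ScaffoldNotFoundError(CptQsarError):
    """The common scaffold query does not match a molecule."""


class DegenerateAlignmentError(CptQsarError):
    """Too few or collinear atoms for a rigid superposition."""


class GridError(CptQsarError):
    """Grid construction or containment failure."""


class ColumnFilterError(CptQsarError):
    """All field columns were dropped by the minimum-sigma filter."""


class SchemaError(CptQsarError):
    """Tabular input does not match the expected schema."""


class FitError(CptQsarError):
    """A statistical fit could not be carried out (separation, rank, ...)."""


class FixtureIntegrityError(CptQsarError):
    """Packaged data files do not match their recorded checksums."""
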