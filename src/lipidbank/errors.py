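"""Exception hierarchy shared across the toolkit."""


class LipidbankError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(LipidbankError):
    """A metadata file is missing a required key or violates an invariant."""


class NamingError(LipidbankError):
    """A molecule name does not resolve to a known universal name."""


class UnmappedAtomError(LipidbankError):
    """An atom is absent from the force-field mapping table."""


class InputError(LipidbankError):
    """Invalid numerical or structural input to a calculator."""


class UsageError(LipidbankError):
    """Invalid option or sort key passed to a user-facing routine."""


class AlignmentError(LipidbankError):
    """Structure superposition is degenerate (e.g. collinear atoms)."""


class ThicknessUndefinedError(LipidbankError):
    """Lipid and water density profiles do not cross on one membrane side."""


class FeaturizationError(NamingError):
    """A molecule cannot be assigned to a composition feature class."""
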