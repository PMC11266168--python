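"""Exception hierarchy shared across the package."""


class HlagcnError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(HlagcnError):
    """A structure file could not be parsed."""


class EmptyStructureError(HlagcnError):
    """Parsing or chain selection produced no usable residues."""


class AnnotationKeyError(HlagcnError):
    """An external annotation references residues absent from the structure."""


class FeaturizationError(HlagcnError):
    """A residue or atom could not be featurized (e.g. missing C-alpha)."""


class UnsupportedResidueError(HlagcnError):
    """A peptide sequence contains a letter outside the 20 standard residues."""


class SmilesParseError(HlagcnError):
    """A SMILES string could not be parsed into a molecule."""


class ContractError(HlagcnError):
    """An operation was called with arguments violating its contract."""
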