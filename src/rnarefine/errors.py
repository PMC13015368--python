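"""Exception hierarchy for rnarefine.

All package-specific failures derive from :class:`RnaRefineError` so callers
can catch one base class. Sub-classes distinguish I/O problems from domain
rejections (e.g. modified nucleotides) from configuration mistakes.
"""


class RnaRefineError(Exception):
    """Base class for all rnarefine errors."""


class FormatError(RnaRefineError):
    """Input file or record cannot be parsed/written in the stated format."""


class EmptyStructureError(RnaRefineError):
    """No RNA residues remain after parsing or cleaning."""


class ModifiedNucleotideError(RnaRefineError):
    """Structure contains a non-standard (modified) nucleotide and is rejected.

    Distinct from :class:`FormatError`: the file was readable, the content is
    out of the supported chemical space.
    """


class IntegrityError(RnaRefineError):
    """A structural invariant is violated (e.g. a residue with zero atoms)."""


class MissingFivePointError(RnaRefineError):
    """A residue lacks one of its five coarse-grained anchor atoms."""


class CatalogError(RnaRefineError):
    """Atom name not present in the canonical heavy-atom catalog."""


class PseudoknotError(RnaRefineError):
    """Crossing base pairs: pseudoknots are not supported."""


class ConfigError(RnaRefineError):
    """Invalid configuration value (odd positional-encoding dim, bad widths...)."""


class CapabilityError(RnaRefineError):
    """An optional external capability (e.g. MolProbity binaries) is absent."""


class UndefinedRateError(RnaRefineError):
    """Reduction rate requested with zero initial clashes."""


class UndefinedLossError(RnaRefineError):
    """Training loss requested with an empty linker set."""


class AnchoredAtomMissingError(RnaRefineError):
    """A five-point anchor atom is missing; reconstruction cannot be anchored."""


class GenerationError(RnaRefineError):
    """A synthetic fixture could not be generated within its search limits."""


class CorrespondenceError(RnaRefineError):
    """Atom sets of two structures cannot be put in 1:1 correspondence."""
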