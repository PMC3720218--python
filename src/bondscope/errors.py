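"""Exception hierarchy.

All package errors derive from :class:`BondscopeError` so callers can catch
one base class; the subclasses mirror the failure modes of the pipeline
stages (parsing, chemistry rules, typing, graph structure, cleavage,
catalogs, dataset labelling, and model configuration).
"""


class BondscopeError(Exception):
    """Base class for all bondscope errors."""


class FormatError(BondscopeError):
    """Input text is not a syntactically valid molfile/SMILES/SDF record."""


class ChemistryError(BondscopeError):
    """Chemically invalid input: bad valence, disallowed element, disconnected graph."""


class TypingError(BondscopeError):
    """An atom received a label outside the closed connection-number type set."""


class StructureError(BondscopeError):
    """A graph-level precondition failed (e.g. disconnected input to a distance query)."""


class CleavageError(BondscopeError):
    """Bond cleavage was requested for a ring bond (would not give two fragments)."""


class CatalogError(BondscopeError):
    """Unknown preset, out-of-range distance, or inconsistent catalog usage."""


class LabelingError(BondscopeError):
    """Annotated structure records are missing or carry malformed labels."""


class ConfigError(BondscopeError):
    """Invalid model or generator configuration."""
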