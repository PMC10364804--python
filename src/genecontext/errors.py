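"""Exception hierarchy shared across modules.

Errors carry enough context (column names, offending identifiers, line
numbers) for a user to fix the input file without reading the source.
"""

from __future__ import annotations


class GeneContextError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(GeneContextError):
    """An input table is missing a required column or has a bad header."""

    exit_code = 2


class IntegrityError(GeneContextError):
    """Rows violate a database invariant (duplicate IDs, start > end, bad strand)."""

    exit_code = 2


class ParseError(GeneContextError):
    """A line of an input file could not be parsed."""

    exit_code = 2


class EmptyDatabaseError(GeneContextError):
    """The gene table contained no usable rows."""

    exit_code = 2


class EmptySubsetError(GeneContextError):
    """A taxonomic subset matched no genomes."""

    exit_code = 3


class QueryResolutionError(GeneContextError):
    """No gene in the database matched the query."""

    exit_code = 3


class ParameterError(GeneContextError):
    """A parameter is outside its documented range."""

    exit_code = 4


class FixtureSpecError(GeneContextError):
    """A synthetic-database specification is internally inconsistent."""

    exit_code = 4


class FormatError(GeneContextError):
    """A mapping file (e.g. pfam2go) yielded no parsable entries."""

    exit_code = 2
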