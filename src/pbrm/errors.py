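"""Exception hierarchy.

All user-facing failures derive from :class:`PbrmError` so the CLI can map
them onto exit code 1; programming errors propagate as ordinary exceptions.
"""


class PbrmError(Exception):
    """Base class for all validation and configuration failures."""


class CatalogueError(PbrmError):
    """Invalid cost catalogue content."""


class UnresolvedRateError(CatalogueError):
    """A role effort has neither an explicit cost nor a usable per-minute rate."""


class CatalogueLookupError(CatalogueError):
    """A referenced item or visit type is absent from the catalogue."""


class SpecificationError(PbrmError):
    """A case-fee specification is incomplete or inconsistent."""


class ExportValidationError(PbrmError):
    """A system export violates its schema (columns, types, duplicate keys)."""

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {', '.join(map(str, self.rows))})"
        super().__init__(message)


class LinkageIntegrityError(PbrmError):
    """A pseudonym is claimed by more than one reimbursement case."""


class ConfigurationError(PbrmError):
    """A mapping table, rule set or run configuration is invalid."""


class ImputationError(ConfigurationError):
    """No experience value resolvable for an announced visit."""


class SamplingError(PbrmError):
    """An audit sample was requested that the population cannot supply."""


class AnalysisError(PbrmError):
    """A statistical comparison has degenerate degrees of freedom."""


class ComparisonUndefinedError(AnalysisError):
    """The reference funding is zero, so a percentage is undefined."""
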