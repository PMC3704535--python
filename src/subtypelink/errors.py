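"""Exception hierarchy shared by every pipeline stage."""


class SubtypeLinkError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SubtypeLinkError):
    """A file does not conform to its declared dialect (TSV/GCT/GMT/Newick)."""


class LabelError(SubtypeLinkError):
    """Sample/subtype label bookkeeping is inconsistent with the matrix."""


class MappingError(SubtypeLinkError):
    """A probe has no gene mapping where one is required."""


class DesignError(SubtypeLinkError):
    """A synthetic design is internally inconsistent."""


class ConfigError(SubtypeLinkError):
    """A run configuration is missing or misuses a key."""


class PipelineError(SubtypeLinkError):
    """A stage cannot proceed (too few cohorts, features, or gene sets)."""


class DegenerateSetError(SubtypeLinkError):
    """A gene set is degenerate for enrichment scoring (empty overlap or
    covering the entire ranked universe)."""


class UndefinedCorrelationError(SubtypeLinkError):
    """Rank correlation is undefined because a profile has zero rank
    variance (constant vector)."""
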