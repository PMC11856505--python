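"""Exception hierarchy shared across the pipeline."""


class KidlbError(Exception):
    """Base class for all package errors."""


class ConfigError(KidlbError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(KidlbError):
    """A required column or field is absent from an input table."""


class DataError(KidlbError):
    """Input rows violate a domain invariant; the message lists the rows."""


class DataIntegrityError(KidlbError):
    """Structural inconsistency between cycles and embryos (e.g. a DET cycle
    without exactly two embryos)."""


class DegenerateCovariateError(KidlbError):
    """A covariate is constant (or near-constant) where a spread is required."""


class UndefinedAUCError(KidlbError):
    """AUC requested on a sample containing a single outcome class."""


class ContractError(KidlbError):
    """An operation was called outside its documented contract."""


class PipelineError(KidlbError):
    """A pipeline stage failed; the message names the stage."""
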