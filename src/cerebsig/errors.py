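"""Exception hierarchy for the cerebsig pipeline."""


class CerebsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CerebsigError):
    """A simulation or pipeline configuration is invalid."""


class CohortError(CerebsigError):
    """Cohort-level inconsistency (grid mismatch, missing subject, ...)."""


class TableError(CerebsigError):
    """Clinical table malformed or inconsistent with the map set."""


class MaskError(CerebsigError):
    """Empty or invalid analysis mask."""


class RegressionError(CerebsigError):
    """Degenerate brain-size regression (too few subjects, zero variance)."""


class ScalingError(CerebsigError):
    """Non-positive predicted cerebellar volume during brain-size scaling."""


class TemplateError(CerebsigError):
    """Control template cannot be formed (no control subjects)."""


class PipelineError(CerebsigError):
    """Stage ordering or stage execution failure in the full pipeline."""


class ROIError(CerebsigError):
    """Empty or missing region of interest."""
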