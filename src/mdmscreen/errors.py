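"""Exception hierarchy for mdmscreen."""


class MdmError(Exception):
    """Base class for all mdmscreen errors."""


class PanelError(MdmError):
    """Invalid metabolite panel definition."""


class CohortValidationError(MdmError):
    """A cohort table violates a structural or value invariant."""


class NormalizationError(MdmError):
    """Creatinine normalization cannot be carried out as requested."""


class ReferenceRangeError(MdmError):
    """Reference ranges cannot be built from the supplied group."""


class InfeasibleTargetError(MdmError):
    """A requested exceedance fraction cannot be reached by the generator."""


class SingularScatterError(MdmError):
    """Within-class scatter is singular and no ridge was allowed."""


class BudgetExceededError(MdmError):
    """A combinatorial search would exceed the configured budget."""


class PipelineError(MdmError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
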