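"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Invalid or inconsistent user input (bad shapes, ranges, missing data)."""


class EstimationError(RuntimeError):
    """A geometric estimation failed (degenerate point configuration etc.)."""


class ContractViolation(RuntimeError):
    """A pluggable component broke its contract (e.g. a scorer left [0, 1])."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
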