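"""Exception hierarchy shared across the package."""


class TactqgError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TactqgError):
    """A configuration problem: missing columns, bad parameters, invalid YAML."""


class PedigreeValidationError(TactqgError):
    """One or more pedigree rows violate the data-model invariants.

    Carries a list of row-level diagnostic messages so callers can report
    every offending record, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        preview = "; ".join(self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{len(self.problems)} pedigree validation problem(s): {preview}{more}")


class DegenerateDataError(TactqgError):
    """The requested statistic is undefined on this subset (zero variance,
    zero mean fitness, a single factor level, ...)."""


class InsufficientDataError(TactqgError):
    """Too few records or families to fit the requested model."""
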