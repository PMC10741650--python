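"""Exception hierarchy for mrmediate."""


class MRError(Exception):
    """Base class for all mrmediate errors."""


class ConfigurationError(MRError):
    """A config file, column map, or parameter combination is invalid."""


class NoInstrumentsError(MRError):
    """Quality control removed every candidate instrument."""


class InsufficientInstrumentsError(MRError):
    """An estimator was given fewer instruments than it requires."""


class CollinearityError(MRError):
    """The multivariable MR design matrix is rank deficient."""


class PipelineError(MRError):
    """A pipeline stage failed; the message names the stage and trait pair."""
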