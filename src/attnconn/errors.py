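"""Exception types shared across the pipeline."""


class AttnConnError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(AttnConnError, ValueError):
    """Input is structurally valid but too small/constant to analyse."""


class CollinearityError(AttnConnError, ValueError):
    """A design matrix is rank deficient; offending columns are named."""


class ConvergenceError(AttnConnError, RuntimeError):
    """An iterative estimator failed to converge across restarts."""
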