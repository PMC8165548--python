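"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition.

    The message names the offending parameter so callers (and the CLI)
    can report actionable errors.
    """


class EstimationError(RuntimeError):
    """A statistical estimate cannot be formed from the given sample
    (too few points, degenerate design, ...)."""


class RateLookupError(KeyError):
    """A requested (S/V, n_sample) cell is absent from a rate table.

    Budget evaluation performs exact lookups only; interpolating between
    Monte-Carlo grid cells is deliberately not supported.
    """
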