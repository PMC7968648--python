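"""Exception hierarchy for bymap.

All errors derive from :class:`BymapError` so callers can catch the whole
family; the subclasses distinguish bad user input from structural/schema
problems and from numerical degeneracies.
"""


class BymapError(Exception):
    """Base class for all bymap errors."""


class InputError(BymapError, ValueError):
    """Invalid argument value (wrong sign, empty, out of range)."""


class SchemaError(BymapError, ValueError):
    """Containers whose labels/axes do not line up (missing band, region...)."""


class DegenerateGrowthError(BymapError, ValueError):
    """Geometric interpolation from a zero population towards a positive one."""


class RangeError(BymapError, ValueError):
    """Requested year outside the interpolation/extrapolation window."""


class ContractError(BymapError, ValueError):
    """A documented API contract was violated (e.g. non-integer counts)."""


class InitialisationError(BymapError, RuntimeError):
    """MCMC could not start (non-finite log-posterior at the initial state)."""


class DiagnosticError(BymapError, RuntimeError):
    """A diagnostic could not be computed (non-finite deviance, zero fit)."""
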