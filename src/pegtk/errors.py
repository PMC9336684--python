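"""Exception hierarchy for pegtk."""


class PegtkError(Exception):
    """Base class for all pegtk errors."""


class ParameterError(PegtkError, ValueError):
    """A model parameter is outside its physical/mathematical domain."""


class InputError(PegtkError, ValueError):
    """Malformed user input (grids, tables, doses, grades)."""


class ConfigError(PegtkError, ValueError):
    """Malformed configuration (unknown keys, bad sections)."""


class ConvergenceError(PegtkError, RuntimeError):
    """An iterative scheme failed to converge within its cap."""


class InsufficientDataError(PegtkError, ValueError):
    """Too few observations to determine the requested parameters."""


class BracketingError(PegtkError, ValueError):
    """A root/threshold search could not bracket a solution."""


class UnreachableError(PegtkError, ValueError):
    """The requested criterion can never be met (e.g. below baseline)."""
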