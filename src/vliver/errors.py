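"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value or range violates a documented invariant."""


class StructuralError(RuntimeError):
    """A sampled lobule graph violates a structural invariant."""


class SimulationInvariantError(RuntimeError):
    """An object-conservation or state invariant failed during a run.

    Raised with cycle context; this is a bug detector, never a warning.
    """
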