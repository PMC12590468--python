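"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class GridFitError(RuntimeError):
    """Spot-lattice fitting failed (degenerate geometry, missing hints)."""
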