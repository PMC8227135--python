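"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """An input record violates a physical or structural invariant."""


class NoShearBranchError(ValidationError):
    """Raised when a shear-wave quantity is requested for a fluid (c_shear == 0)."""


class NoResonanceError(ValueError):
    """Raised when the shelled-bubble resonance formula has no real root."""


class SingularStackError(RuntimeError):
    """Raised when a layered boundary-condition system is numerically singular."""


class MaterialTableError(ValueError):
    """Raised on a malformed material-table file; names the offending row/column."""
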