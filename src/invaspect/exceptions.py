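"""Exception hierarchy for invalid or degenerate inputs."""


class InvaspectError(Exception):
    """Base class for all package-specific errors."""


class DegenerateBoundaryError(InvaspectError):
    """A boundary with fewer than 3 distinct vertices or zero contour length."""


class UnsupportedFormatError(InvaspectError):
    """A boundary file whose type cannot be interpreted as a closed polygon."""


class UndefinedPhenotypeError(InvaspectError):
    """The spectral phenotype is undefined (no first-harmonic power)."""


class DegenerateFitError(InvaspectError):
    """A maximum-likelihood variance of zero makes the model likelihood singular."""
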