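"""Exception taxonomy for spindletrack."""


class SpindletrackError(Exception):
    """Base class for all spindletrack errors."""


class InvalidParameterError(SpindletrackError, ValueError):
    """A feature parameter is out of its valid domain (e.g. non-positive width)."""


class GeometryError(SpindletrackError, ValueError):
    """Image/model geometry mismatch (shapes or voxel sizes disagree)."""


class DegenerateTangentError(SpindletrackError, ValueError):
    """The XY speed of a parametric curve vanishes where a curvature is requested."""


class StepTooLargeError(SpindletrackError, ValueError):
    """Curve reconstruction step is not smaller than the curve length."""


class UnderDeterminedError(SpindletrackError, ValueError):
    """Too few samples for the requested number of fit coefficients."""


class NoPoleError(SpindletrackError, RuntimeError):
    """No spindle-pole-body candidate found in the image."""


class InvalidPoleError(SpindletrackError, ValueError):
    """A supplied pole position lies outside the image."""


class NoSpindleError(SpindletrackError, RuntimeError):
    """No elongated bright component consistent with a bipolar spindle."""


class EmptyPathError(SpindletrackError, RuntimeError):
    """Curve tracing started in pure background."""


class UndefinedSNRError(SpindletrackError, ValueError):
    """SNR requested for a ground truth without any microtubule."""


class InputError(SpindletrackError, ValueError):
    """Unreadable or malformed input movie/configuration."""
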