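"""Exception hierarchy shared across octaquant modules."""


class OctaquantError(Exception):
    """Base class for all octaquant errors."""


class InvalidParameterError(OctaquantError, ValueError):
    """A parameter is outside its documented domain."""


class UnsupportedModalityError(OctaquantError, ValueError):
    """Operation requested for a modality that cannot provide it
    (e.g. a 3D volume from the purely 2D dye angiography)."""


class RegistrationError(OctaquantError, RuntimeError):
    """Image registration could not produce an acceptable overlap."""


class DegenerateImageError(OctaquantError, ValueError):
    """The image has no intensity contrast to threshold."""


class InsufficientDataError(OctaquantError, ValueError):
    """Too few observations for the requested statistic."""


class FormatError(OctaquantError, IOError):
    """A file could not be read in the declared format."""


class FixtureError(OctaquantError, RuntimeError):
    """A bundled data fixture failed its integrity check."""
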