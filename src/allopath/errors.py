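"""Exception hierarchy.

Every error raised by the library derives from :class:`AllopathError`, so
callers (and the CLI) can distinguish data problems from programming bugs.
"""


class AllopathError(Exception):
    """Base class for all library errors."""


class ParseError(AllopathError):
    """A structure or ensemble file could not be parsed."""


class CongruenceError(AllopathError):
    """Frames / matrices that must share an atom or residue set do not."""


class SelectionError(AllopathError):
    """A selection expression is invalid or matches nothing."""


class DegenerateFitError(AllopathError):
    """Superposition fit set is too small or collinear."""


class SpecError(AllopathError):
    """A synthetic-data specification is inconsistent (e.g. non-PSD request)."""


class ConfigError(AllopathError):
    """A pipeline configuration file is invalid."""
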