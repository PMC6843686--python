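"""Exception hierarchy.

All package errors derive from :class:`ChannelGateError` so callers can
catch one base class; the subclasses distinguish configuration problems
(bad topology documents), selector resolution failures, file-format
problems, degenerate geometry, and invalid numeric input.
"""


class ChannelGateError(Exception):
    """Base class for all channelgate errors."""


class ConfigurationError(ChannelGateError):
    """Invalid or incomplete topology / pipeline configuration."""


class ResolutionError(ChannelGateError):
    """A symbolic residue/atom selection does not resolve to an atom."""


class FormatError(ChannelGateError):
    """Malformed input file (PDB model mismatch, ragged alignment...)."""


class GeometryError(ChannelGateError):
    """Degenerate geometry (collinear/coincident superposition input)."""


class InputError(ChannelGateError):
    """Invalid numeric input (empty series, size mismatch...)."""
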