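"""Exception hierarchy for surfmorph."""


class SurfmorphError(Exception):
    """Base class for all surfmorph errors."""


class UnsupportedFormatError(SurfmorphError):
    """File container is not the expected format (wrong magic number)."""


class FormatParseError(SurfmorphError):
    """File has the right container magic but its contents cannot be parsed."""


class ShapeError(SurfmorphError):
    """Array or field length does not match the mesh or design it is paired with."""


class MeshInvariantError(SurfmorphError):
    """A mesh violates its structural invariants (bad face indices, orphans)."""


class DesignError(SurfmorphError):
    """Design-matrix construction or nesting problem (rank deficiency, non-nested)."""


class ConfigError(SurfmorphError):
    """Run configuration is invalid or incomplete."""
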