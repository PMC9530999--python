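"""Exception hierarchy.

All package-specific failures derive from :class:`HJDimerError` so callers
(and the CLI) can distinguish user/input problems from genuine bugs.
"""


class HJDimerError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HJDimerError):
    """A structure/trajectory file could not be parsed, or required
    metadata (e.g. chain labels) is missing."""


class FrameConsistencyError(HJDimerError):
    """A trajectory frame disagrees with the topology (wrong atom count)."""


class ConfigurationError(HJDimerError):
    """Invalid run parameters (strides, modes, config schema)."""


class SelectionError(HJDimerError):
    """An atom/residue selection matched nothing."""


class DegenerateGeometryError(HJDimerError):
    """Geometry that makes the requested quantity undefined
    (coincident points, zero-length dipole, axis parallel to reference)."""


class TopologyError(HJDimerError):
    """Topology does not satisfy a structural precondition
    (missing residues, strands, etc.)."""


class AnalysisError(HJDimerError):
    """An analysis was requested on an empty or unusable data set."""
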