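"""Exception hierarchy shared across the package."""


class DTAFusionError(Exception):
    """Base class for all package errors."""


class PDBParseError(DTAFusionError):
    """Raised when a PDB stream yields no usable ATOM records."""


class InsufficientGeometryError(DTAFusionError):
    """Raised when a point cloud is too small for tetrahedralization (N < 4)."""


class DegenerateGeometryError(DTAFusionError):
    """Raised when Delaunay tetrahedralization fails (e.g. coplanar points)."""


class NoValidTetrahedraError(DTAFusionError):
    """Raised when every tetrahedron is skipped by the V = 0 rule."""


class UndefinedMetricError(DTAFusionError):
    """Raised when a metric is undefined for its inputs (e.g. all labels tied)."""


class ConfigError(DTAFusionError):
    """Raised for invalid model or training configuration."""
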