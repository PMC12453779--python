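"""Protein surface curvature from Delaunay tetrahedralization.

The protein is reduced to a 3D point cloud (all heavy atoms, or one point
per residue via the C-alpha trace).  The cloud is partitioned into
tetrahedra by Delaunay tetrahedralization; each tetrahedron's circumsphere
radius R is obtained from its six edge lengths through a closed-form
quantity V and a circumradius expression, local curvature is k = 1/R, and
the structure-level descriptor is the mean of k over all valid tetrahedra
(those with V != 0).  Degenerate tetrahedra (V = 0, e.g. perfectly regular
ones under this V) are skipped rather than imputed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .exceptions import (
    DegenerateGeometryError,
    InsufficientGeometryError,
    NoValidTetrahedraError,
    PDBParseError,
)

__all__ = [
    "AtomLevel",
    "AtomCloud",
    "Tetra",
    "CurvatureResult",
    "read_structure",
    "delaunay_tetrahedra",
    "tetra_quantity_V",
    "circum_radius",
    "mean_curvature",
    "write_point_cloud_pdb",
]

#: Relative tolerance (times mean-edge-length cubed) below which V counts as 0.
V_ZERO_RTOL = 1e-12

#: Marker returned by :func:`circum_radius` for invalid (V = 0) tetrahedra.
INVALID_RADIUS = float("nan")


class AtomLevel(str, Enum):
    """Which atoms of a structure enter the point cloud."""

    ALL_ATOMS = "all_atoms"
    C_ALPHA = "c_alpha"


@dataclass(frozen=True)
class AtomCloud:
    """An ordered set of 3D points (Angstrom) extracted from a structure."""

    coords: np.ndarray  # (N, 3) float64
    source_id: str = ""
    level: AtomLevel = AtomLevel.ALL_ATOMS

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def scaled(self, s: float) -> "AtomCloud":
        return AtomCloud(self.coords * float(s), self.source_id, self.level)


@dataclass(frozen=True)
class Tetra:
    """One tetrahedron: vertex indices into an AtomCloud + edge lengths.

    Edge order follows the fixed vertex-pair assignment
    a=|p1-p2|, b=|p1-p3|, c=|p1-p4|, d=|p2-p3|, e=|p2-p4|, f=|p3-p4|.
    """

    vertex_indices: tuple[int, int, int, int]
    edge_lengths: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(set(self.vertex_indices)) != 4:
            raise ValueError("vertex indices must be distinct")
        if any(l < 0 for l in self.edge_lengths):
            raise ValueError("edge lengths must be non-negative")


@dataclass
class CurvatureResult:
    """Mean surface curvature (1/Angstrom) and tetrahedron bookkeeping."""

    mean_curvature: float
    n_valid: int
    n_total: int
    per_tet: Optional[list[tuple[float, float, float]]] = field(default=None)


# fixed vertex-pair order for edges (a..f)
_EDGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def read_structure(pdb_text, level: AtomLevel | str = AtomLevel.ALL_ATOMS,
                   source_id: str = "") -> AtomCloud:
    """Read ATOM records from a PDB text stream into an :class:`AtomCloud`.

    Only the first model of multi-model (NMR-style) files is used; HETATM
    records and hydrogens are excluded.  ``level`` selects all heavy atoms
    or the C-alpha trace (one point per residue).

    Parameters
    ----------
    pdb_text : str or file-like
        PDB-format character stream.
    level : AtomLevel or str
        ``all_atoms`` (default) or ``c_alpha``.
    """
    level = AtomLevel(level)
    if isinstance(pdb_text, str):
        handle = io.StringIO(pdb_text)
    else:
        handle = pdb_text

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(source_id or "structure", handle)
        except Exception as exc:  # malformed stream
            raise PDBParseError(f"could not parse PDB stream: {exc}") from exc

    models = list(structure.get_models())
    if not models:
        raise PDBParseError("no models / ATOM records in PDB stream")
    model = models[0]

    coords: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # HETATM / water
                continue
            for atom in residue:
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                if level is AtomLevel.C_ALPHA and atom.get_name() != "CA":
                    continue
                coords.append(np.asarray(atom.get_coord(), dtype=float))

    if not coords:
        raise PDBParseError("no ATOM records found in PDB stream")
    if len(coords) < 4:
        raise InsufficientGeometryError(
            f"need >= 4 points for tetrahedralization, got {len(coords)}"
        )
    return AtomCloud(np.stack(coords), source_id=source_id, level=level)


def _edge_lengths(points: np.ndarray) -> tuple[float, ...]:
    """Six edge lengths of a 4-point tetrahedron in the fixed (a..f) order."""
    return tuple(
        float(np.linalg.norm(points[i] - points[j])) for i, j in _EDGE_PAIRS
    )


def delaunay_tetrahedra(cloud: AtomCloud, *, joggle: float = 0.0,
                        joggle_seed: int = 0) -> list[Tetra]:
    """Delaunay tetrahedralization of the cloud.

    Every returned tetrahedron's circumsphere contains no other input point
    in its interior (the Delaunay property).  Degenerate input (coplanar
    points) raises :class:`DegenerateGeometryError`; an opt-in seeded
    ``joggle`` (uniform perturbation magnitude, Angstrom) may be supplied to
    break exact degeneracies reproducibly.
    """
    pts = cloud.coords
    if len(pts) < 4:
        raise InsufficientGeometryError(
            f"need >= 4 points, got {len(pts)}"
        )
    if joggle > 0.0:
        rng = np.random.default_rng(joggle_seed)
        pts = pts + rng.uniform(-joggle, joggle, size=pts.shape)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"tetrahedralization failed (degenerate input?): {exc}"
        ) from exc
    if tri.simplices.shape[1] != 4:
        raise DegenerateGeometryError("input is not full-dimensional in 3D")

    out: list[Tetra] = []
    for simplex in tri.simplices:
        # canonical vertex order (ascending input index): the V quantity is
        # not symmetric under vertex relabeling, and Qhull's simplex order is
        # arbitrary, so a fixed order is required for rigid-motion invariance
        idx = tuple(sorted(int(i) for i in simplex))
        out.append(Tetra(idx, _edge_lengths(pts[list(idx)])))
    return out


def tetra_quantity_V(a: float, b: float, c: float,
                     d: float, e: float, f: float) -> float:
    """The validity quantity V = adf + bef + cde - a*e^2 - b*d^2 - c*f^2.

    Computed from the six edge lengths in the fixed (a..f) order.  V = 0
    marks a tetrahedron as invalid for the curvature estimate (this V
    vanishes for highly symmetric tetrahedra, e.g. regular ones).
    """
    for name, val in zip("abcdef", (a, b, c, d, e, f)):
        if val < 0:
            raise ValueError(f"edge length {name} must be >= 0, got {val}")
    return a * d * f + b * e * f + c * d * e - a * e**2 - b * d**2 - c * f**2


def circum_radius(a: float, b: float, c: float, d: float, e: float, f: float,
                  V: float, *, v_tol: float | None = None) -> float:
    """Circumsphere radius from edge lengths and the precomputed V.

    R = [a^2(e^2+f^2-d^2) + b^2(d^2+f^2-e^2) + c^2(d^2+e^2-f^2)] / (16 V).

    Returns NaN (the invalid marker) when |V| is at or below the zero
    tolerance; by default the tolerance scales with the cube of the mean
    edge length so the skip rule is robust to floating point.
    """
    if v_tol is None:
        mean_edge = (a + b + c + d + e + f) / 6.0
        v_tol = V_ZERO_RTOL * mean_edge**3
    if abs(V) <= v_tol:
        return INVALID_RADIUS
    numerator = (
        a**2 * (e**2 + f**2 - d**2)
        + b**2 * (d**2 + f**2 - e**2)
        + c**2 * (d**2 + e**2 - f**2)
    )
    return numerator / (16.0 * V)


def mean_curvature(cloud: AtomCloud, *, sign: str = "abs",
                   return_per_tet: bool = False) -> CurvatureResult:
    """Mean surface curvature of the cloud, averaged over valid tetrahedra.

    Each valid tetrahedron (V != 0) contributes k = 1/|R| under the default
    ``sign="abs"`` policy (curvature as the reciprocal of an unsigned
    radius); ``sign="raw"`` uses k = 1/R with R as computed.

    Raises
    ------
    NoValidTetrahedraError
        If every tetrahedron is skipped by the V = 0 rule.
    """
    if sign not in ("abs", "raw"):
        raise ValueError(f"sign must be 'abs' or 'raw', got {sign!r}")
    tetras = delaunay_tetrahedra(cloud)

    # vectorized over tetrahedra; the scalar functions define the semantics
    L = np.asarray([t.edge_lengths for t in tetras], dtype=float)
    a, b, c, d, e, f = (L[:, i] for i in range(6))
    V = a * d * f + b * e * f + c * d * e - a * e**2 - b * d**2 - c * f**2
    mean_edge = L.mean(axis=1)
    valid = np.abs(V) > V_ZERO_RTOL * mean_edge**3
    numerator = (
        a**2 * (e**2 + f**2 - d**2)
        + b**2 * (d**2 + f**2 - e**2)
        + c**2 * (d**2 + e**2 - f**2)
    )
    R = np.full(len(tetras), np.nan)
    R[valid] = numerator[valid] / (16.0 * V[valid])

    n_total = len(tetras)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise NoValidTetrahedraError(
            f"all {n_total} tetrahedra have V = 0; curvature undefined"
        )
    k = np.full(n_total, np.nan)
    if sign == "abs":
        k[valid] = 1.0 / np.abs(R[valid])
    else:
        k[valid] = 1.0 / R[valid]
    kbar = float(k[valid].sum() / n_valid)

    per_tet = None
    if return_per_tet:
        per_tet = [(float(V[i]), float(R[i]), float(k[i]))
                   for i in range(n_total)]
    return CurvatureResult(kbar, n_valid, n_total, per_tet)


def write_point_cloud_pdb(coords: Sequence[Sequence[float]],
                          source_id: str = "SYNT") -> str:
    """Serialize a point cloud as minimal PDB ATOM records (one CA per point).

    Used by the synthetic generator so the PDB reading path is exercised on
    generated data; each point becomes a glycine C-alpha pseudo-atom.
    """
    lines = []
    coords = np.asarray(coords, dtype=float)
    for i, (x, y, z) in enumerate(coords, start=1):
        serial = i % 100000
        resseq = ((i - 1) % 9999) + 1
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
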