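"""Physicochemical descriptor vectors for drugs and proteins.

Drugs carry a 16-dimensional vector: seven PubChem-style descriptors
(lipophilicity/logP, topological polar surface area, complexity, H-bond
donors, H-bond acceptors, heavy-atom count, total charge) followed by nine
atom counts (C, H, N, O, F, S, Cl, Br, I) derived from the SMILES with
implicit hydrogens counted.  Missing descriptor values are stored as
exactly 0; present values are kept raw (no normalization).

Proteins carry a 5-dimensional vector: GRAVY hydrophobicity (mean
Kyte-Doolittle over residues with a defined scale entry), average
molecular weight (Da), isoelectric point, a total electrostatic potential
scalar consumed from an external Poisson-Boltzmann run (missing -> 0), and
the mean surface curvature from :mod:`dtafusion.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "DRUG_PC_FIELDS",
    "PROTEIN_PC_FIELDS",
    "ATOM_COUNT_ELEMENTS",
    "drug_pc_vector",
    "protein_pc_vector",
    "assemble_pc_matrix",
    "PCMatrix",
]

#: Ordered names of the seven tabulated drug descriptors (CSV column names).
DRUG_DESCRIPTOR_FIELDS = (
    "xlogp", "tpsa", "complexity", "hbond_donor", "hbond_acceptor",
    "heavy_atom", "charge",
)

#: Elements whose atom counts occupy the last nine drug-vector slots.
ATOM_COUNT_ELEMENTS = ("C", "H", "N", "O", "F", "S", "Cl", "Br", "I")

DRUG_PC_FIELDS = DRUG_DESCRIPTOR_FIELDS + tuple(
    f"n_{el}" for el in ATOM_COUNT_ELEMENTS
)

PROTEIN_PC_FIELDS = (
    "gravy", "molecular_weight", "isoelectric_point",
    "total_electrostatic_potential", "mean_surface_curvature",
)


def _parse_smiles(smiles: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def atom_counts(smiles: str) -> dict[str, int]:
    """Counts of C, H, N, O, F, S, Cl, Br, I in a molecule.

    Hydrogens include implicit ones (matching formula-based counts);
    heavy-element counts are over explicit atoms of the parsed molecule.
    """
    mol = _parse_smiles(smiles)
    counts = {el: 0 for el in ATOM_COUNT_ELEMENTS}
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol in counts:
            counts[symbol] += 1
        counts["H"] += atom.GetTotalNumHs(includeNeighbors=False)
    return counts


def drug_pc_vector(descriptor_row: Mapping[str, Optional[float]] | None,
                   smiles: str) -> np.ndarray:
    """Build the 16-dim drug physicochemical vector.

    ``descriptor_row`` maps descriptor names (a subset of
    :data:`DRUG_DESCRIPTOR_FIELDS`) to values; absent or ``None`` entries
    become exactly 0.  Atom counts are always derived from the SMILES.
    """
    descriptor_row = descriptor_row or {}
    unknown = set(descriptor_row) - set(DRUG_DESCRIPTOR_FIELDS)
    if unknown:
        raise KeyError(f"unknown descriptor fields: {sorted(unknown)}")

    values = []
    for name in DRUG_DESCRIPTOR_FIELDS:
        v = descriptor_row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            v = 0.0
        values.append(float(v))
    counts = atom_counts(smiles)
    values.extend(float(counts[el]) for el in ATOM_COUNT_ELEMENTS)
    return np.asarray(values, dtype=float)


# Kyte-Doolittle hydropathy scale (defined for the 20 standard residues).
_KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def _gravy(sequence: str) -> float:
    vals = [_KD_SCALE[aa] for aa in sequence if aa in _KD_SCALE]
    if not vals:
        return 0.0
    return float(np.mean(vals))


def _molecular_weight(sequence: str) -> float:
    """Average molecular weight; letters without a defined residue mass
    (ambiguity codes B/J/X/Z) contribute nothing."""
    from Bio.Data.IUPACData import protein_weights
    from Bio.SeqUtils import molecular_weight as bio_mw

    if all(aa in protein_weights for aa in sequence):
        return float(bio_mw(sequence, seq_type="protein"))
    known = [aa for aa in sequence if aa in protein_weights]
    if not known:
        return 0.0
    water = 18.0153
    total = sum(protein_weights[aa] for aa in known) - water * (len(known) - 1)
    return float(total)


def protein_pc_vector(sequence: str, curvature: float,
                      potential: Optional[float] = None) -> np.ndarray:
    """Build the 5-dim protein physicochemical vector.

    ``curvature`` is the mean surface curvature from the geometry pipeline;
    ``potential`` is the externally computed total electrostatic potential
    scalar (missing -> 0, mirroring the drug missing-value rule).
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    if potential is None or (isinstance(potential, float) and np.isnan(potential)):
        potential = 0.0
    gravy = _gravy(sequence)
    mw = _molecular_weight(sequence)
    pi = float(IsoelectricPoint(sequence).pi())
    return np.asarray([gravy, mw, pi, float(potential), float(curvature)],
                      dtype=float)


@dataclass
class PCMatrix:
    """Stacked physicochemical vectors with an entity-id row index."""

    matrix: np.ndarray            # (n_entities, n_fields)
    ids: tuple[str, ...]
    row_index: dict[str, int]

    def row(self, entity_id: str) -> np.ndarray:
        return self.matrix[self.row_index[entity_id]]


def assemble_pc_matrix(vectors: Sequence[np.ndarray],
                       ids: Iterable[str] | None = None) -> PCMatrix:
    """Stack per-entity vectors (all of one length) into a matrix.

    Row order follows input order; ``ids`` default to stringified indices.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("cannot assemble an empty physicochemical matrix")
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1 or vectors[0].ndim != 1:
        raise ValueError(f"ragged or non-1D vectors: shapes {sorted(lengths)}")
    if ids is None:
        ids = [str(i) for i in range(len(vectors))]
    ids = tuple(str(i) for i in ids)
    if len(ids) != len(vectors):
        raise ValueError("ids and vectors length mismatch")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate entity ids")
    return PCMatrix(np.stack(vectors), ids, {e: i for i, e in enumerate(ids)})


def pc_matrix_to_csv(pcm: PCMatrix, fields: Sequence[str], path) -> None:
    """Write a PCMatrix as CSV with an id column and a header row."""
    import pandas as pd

    df = pd.DataFrame(pcm.matrix, columns=list(fields))
    df.insert(0, "id", list(pcm.ids))
    df.to_csv(path, index=False)
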