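"""Deterministic synthetic corpora for end-to-end exercising of the
pipeline: geometry, featurization, loaders, model and training.

Proteins are random sequences over the 25-letter alphabet with a
3-points-per-residue perturbed-helix atom cloud (non-degenerate for
Delaunay tetrahedralization by construction) and a standard-normal
electrostatic-potential scalar.  Drugs are SMILES assembled from a closed
fragment grammar (linear chains with optional branches and one optional
ring over C/N/O/S plus halogen substituents), guaranteed parseable, with
descriptor rows computed from the molecule and ~10% of fields knocked out
to exercise the missing->0 rule.  Affinity labels are planted as a linear
function of standardized selected drug + protein descriptors plus
Gaussian noise, so a trained model's signal recovery is measurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import AtomCloud, mean_curvature, write_point_cloud_pdb
from .model import DrugRecord, ModelConfig, ProteinRecord
from .physchem import (
    DRUG_DESCRIPTOR_FIELDS, drug_pc_vector, protein_pc_vector,
)
from .seqdata import AA_ALPHABET, AffinityPair, LabelKind
from .training import PairDataset

__all__ = ["SynthSpec", "SynthCorpus", "gen_protein", "gen_drug",
           "gen_dataset", "write_dataset", "build_pair_dataset"]

# descriptor columns carrying the planted signal
DRUG_SIGNAL_SLOTS = (0, 1, 5)      # xlogp, tpsa, heavy_atom
PROTEIN_SIGNAL_SLOTS = (0, 3, 4)   # gravy, potential, curvature

DEFAULT_EFFECT_WEIGHTS = (0.8, -0.6, 0.5, 0.7, 0.6, -0.5)


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions of a synthetic corpus; same spec => same corpus."""

    n_drugs: int = 30
    n_proteins: int = 25
    pair_density: float = 0.8
    noise_sd: float = 0.1
    effect_weights: tuple[float, ...] = DEFAULT_EFFECT_WEIGHTS
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pair_density <= 1):
            raise ValueError("pair_density must be in (0, 1]")
        if len(self.effect_weights) != len(DRUG_SIGNAL_SLOTS) + len(PROTEIN_SIGNAL_SLOTS):
            raise ValueError("effect_weights must have 6 entries")


def gen_protein(seed: int) -> tuple[str, AtomCloud, float]:
    """One synthetic protein: (sequence, atom cloud, potential scalar).

    Sequence length is uniform in [50, 300]; the cloud places three jittered
    points per residue along an idealized helix (radius 2.3 A, rise 1.5 A,
    100 degrees per residue), which is never coplanar.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(50, 301))
    sequence = "".join(rng.choice(list(AA_ALPHABET), size=length))

    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    r = np.arange(length)
    base = np.stack([radius * np.cos(turn * r),
                     radius * np.sin(turn * r),
                     rise * r], axis=1)
    offsets = np.array([[0.0, 0.0, 0.0], [1.2, 0.4, 0.3], [-0.5, 1.1, -0.4]])
    pts = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    pts = pts + rng.normal(0.0, 0.2, size=pts.shape)
    cloud = AtomCloud(pts, source_id=f"synth-{seed}")
    potential = float(rng.normal(0.0, 1.0))
    return sequence, cloud, potential


_CHAIN_ATOMS = ("C", "C", "C", "C", "N", "O", "S")   # carbon-weighted
_BRANCH_ATOMS = ("C", "O", "F", "Cl", "Br", "I")
_RINGS = ("C1CCCCC1", "c1ccccc1", "C1CCNCC1", "C1CCOC1")


def _random_smiles(rng: np.random.Generator) -> str:
    """Closed fragment grammar: chain + optional single branch at a carbon +
    optional terminal ring.  Branches attach only at carbons and halogens
    appear only as branch terminals, so every string is valence-valid."""
    n = int(rng.integers(3, 9))
    atoms = [str(rng.choice(_CHAIN_ATOMS)) for _ in range(n)]
    atoms[0] = "C"  # simple start
    parts = []
    branch_at = int(rng.integers(1, n)) if rng.random() < 0.6 else -1
    for i, a in enumerate(atoms):
        parts.append(a)
        if i == branch_at and a == "C":
            parts.append(f"({rng.choice(_BRANCH_ATOMS)})")
    if rng.random() < 0.5:
        parts.append(str(rng.choice(_RINGS)))
    return "".join(parts)


def gen_drug(seed: int, missing_rate: float = 0.10) -> tuple[str, dict]:
    """One synthetic drug: (SMILES, descriptor row).

    Descriptor values are simple computed surrogates (Crippen logP, TPSA,
    Bertz complexity, H-bond donor/acceptor counts, heavy atoms, formal
    charge); each field is independently missing (None) at ``missing_rate``.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    rng = np.random.default_rng(seed)
    smiles = _random_smiles(rng)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # the grammar guarantees this never happens
        raise RuntimeError(f"fragment grammar produced invalid SMILES {smiles!r}")
    values = {
        "xlogp": float(Crippen.MolLogP(mol)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(mol)),
        "complexity": float(Descriptors.BertzCT(mol)),
        "hbond_donor": float(rdMolDescriptors.CalcNumHBD(mol)),
        "hbond_acceptor": float(rdMolDescriptors.CalcNumHBA(mol)),
        "heavy_atom": float(mol.GetNumHeavyAtoms()),
        "charge": float(Chem.GetFormalCharge(mol)),
    }
    row = {k: (None if rng.random() < missing_rate else v)
           for k, v in values.items()}
    return smiles, row


@dataclass
class SynthCorpus:
    """A generated corpus plus the exact planted-label inputs."""

    spec: SynthSpec
    smiles: dict[str, str]
    descriptor_rows: dict[str, dict]
    sequences: dict[str, str]
    clouds: dict[str, AtomCloud]
    potentials: dict[str, float]
    drug_pc: dict[str, np.ndarray]
    protein_pc: dict[str, np.ndarray]
    pairs: list[AffinityPair]
    noiseless_labels: dict[tuple[str, str], float] = field(default_factory=dict)


def _standardize_columns(mat: np.ndarray) -> np.ndarray:
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return (mat - mat.mean(axis=0)) / sd


def gen_dataset(spec: SynthSpec) -> SynthCorpus:
    """Generate a full corpus under ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    drug_seeds = rng.integers(0, 2**31 - 1, size=spec.n_drugs)
    prot_seeds = rng.integers(0, 2**31 - 1, size=spec.n_proteins)

    smiles, rows, drug_pc = {}, {}, {}
    for i, s in enumerate(drug_seeds):
        did = f"D{i:03d}"
        smi, row = gen_drug(int(s), spec.missing_rate)
        smiles[did], rows[did] = smi, row
        drug_pc[did] = drug_pc_vector(row, smi)

    sequences, clouds, potentials, protein_pc = {}, {}, {}, {}
    for j, s in enumerate(prot_seeds):
        pid = f"P{j:03d}"
        seq, cloud, pot = gen_protein(int(s))
        sequences[pid], clouds[pid], potentials[pid] = seq, cloud, pot
        curv = mean_curvature(cloud).mean_curvature
        protein_pc[pid] = protein_pc_vector(seq, curv, pot)

    drug_ids = list(smiles)
    prot_ids = list(sequences)
    dmat = _standardize_columns(
        np.stack([drug_pc[d][list(DRUG_SIGNAL_SLOTS)] for d in drug_ids]))
    pmat = _standardize_columns(
        np.stack([protein_pc[p][list(PROTEIN_SIGNAL_SLOTS)] for p in prot_ids]))
    w = np.asarray(spec.effect_weights, dtype=float)
    wd, wp = w[: len(DRUG_SIGNAL_SLOTS)], w[len(DRUG_SIGNAL_SLOTS):]

    # pair sampling; re-sample until every entity participates
    for attempt in range(100):
        mask = rng.random((spec.n_drugs, spec.n_proteins)) < spec.pair_density
        if mask.any(axis=1).all() and mask.any(axis=0).all():
            break
        warnings.warn("pair density left an entity without pairs; re-sampling")
    else:
        raise RuntimeError("could not sample a pair set covering all entities")

    pairs: list[AffinityPair] = []
    noiseless: dict[tuple[str, str], float] = {}
    signal = dmat @ wd
    for i, did in enumerate(drug_ids):
        for j, pid in enumerate(prot_ids):
            if not mask[i, j]:
                continue
            mu = float(signal[i] + pmat[j] @ wp)
            label = mu + float(rng.normal(0.0, spec.noise_sd)) \
                if spec.noise_sd > 0 else mu
            noiseless[(did, pid)] = mu
            pairs.append(AffinityPair(did, pid, label, LabelKind.SYNTHETIC))

    return SynthCorpus(spec, smiles, rows, sequences, clouds, potentials,
                       drug_pc, protein_pc, pairs, noiseless)


def build_pair_dataset(corpus: SynthCorpus, cfg: ModelConfig) -> PairDataset:
    """Materialize model-ready records (tokens, graphs, descriptors)."""
    drugs = {
        did: DrugRecord.build(did, smi, corpus.drug_pc[did],
                              max_len=cfg.max_drug_len)
        for did, smi in corpus.smiles.items()
    }
    proteins = {
        pid: ProteinRecord.build(pid, seq, corpus.protein_pc[pid],
                                 max_len=cfg.max_protein_len)
        for pid, seq in corpus.sequences.items()
    }
    return PairDataset(drugs, proteins, list(corpus.pairs))


def write_dataset(corpus: SynthCorpus, outdir, layout: str = "kiba") -> None:
    """Serialize a corpus in the benchmark-loader directory layout.

    ``layout="kiba"`` writes labels unchanged; ``layout="davis"`` writes
    Kd (nM) cells such that the pKd transform recovers the labels.  Also
    emits descriptor/potential CSVs and per-protein PDB point clouds.
    """
    if layout not in ("kiba", "davis"):
        raise ValueError("layout must be 'kiba' or 'davis'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    drug_ids = list(corpus.smiles)
    prot_ids = list(corpus.sequences)
    label = {(p.drug_id, p.protein_id): p.label for p in corpus.pairs}
    lines = []
    for did in drug_ids:
        cells = []
        for pid in prot_ids:
            if (did, pid) in label:
                y = label[(did, pid)]
                cells.append(repr(1e9 * 10 ** (-y)) if layout == "davis"
                             else repr(y))
            else:
                cells.append("nan")
        lines.append("\t".join(cells))
    (outdir / "affinities.txt").write_text("\n".join(lines) + "\n")
    (outdir / "ligands.json").write_text(json.dumps(corpus.smiles, indent=0))
    (outdir / "proteins.json").write_text(json.dumps(corpus.sequences, indent=0))

    with open(outdir / "descriptors.csv", "w") as fh:
        fh.write("drug_id," + ",".join(DRUG_DESCRIPTOR_FIELDS) + "\n")
        for did in drug_ids:
            row = corpus.descriptor_rows[did]
            cells = ["" if row.get(f) is None else repr(row[f])
                     for f in DRUG_DESCRIPTOR_FIELDS]
            fh.write(did + "," + ",".join(cells) + "\n")
    with open(outdir / "potentials.csv", "w") as fh:
        fh.write("protein_id,potential\n")
        for pid in prot_ids:
            fh.write(f"{pid},{corpus.potentials[pid]!r}\n")

    pdb_dir = outdir / "pdb"
    pdb_dir.mkdir(exist_ok=True)
    for pid in prot_ids:
        (pdb_dir / f"{pid}.pdb").write_text(
            write_point_cloud_pdb(corpus.clouds[pid].coords, pid))
    manifest = {"spec": {**corpus.spec.__dict__,
                         "effect_weights": list(corpus.spec.effect_weights)},
                "layout": layout, "n_pairs": len(corpus.pairs)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
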