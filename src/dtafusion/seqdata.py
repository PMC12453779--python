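"""Sequence vocabularies, tokenization, affinity labels, loaders and splits.

SMILES strings and protein sequences are digitized character-by-character
against frozen vocabularies (62 SMILES symbols, 25 amino-acid letters),
truncated/right-padded to fixed maximum lengths.  Dissociation constants
(nM) become pKd labels; KIBA scores are used unchanged.  Benchmark corpora
are read from a directory holding a tab-separated drug x protein affinity
matrix plus ligand and protein lists (JSON mapping or two-column TSV) --
the layout of the public Davis/KIBA distributions and of the synthetic
generator's output.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SMILES_ALPHABET", "AA_ALPHABET", "Vocab", "SMILES_VOCAB", "AA_VOCAB",
    "TokenizedSeq", "LabelKind", "AffinityPair", "DatasetSplit",
    "kd_to_pkd", "tokenize", "detokenize",
    "load_davis", "load_kiba", "make_splits",
]

# Frozen 62-symbol SMILES character set (versioned asset: changing it breaks
# tokenization bit-stability).  Character-dictionary convention for
# integer-labelled SMILES, reduced to 62 entries.
SMILES_ALPHABET = (
    "#%()+-./0123456789=@ABCDEFGHIKLMNOPRSTUVWXYZ[\\]abcdefhilmnorst"
)

# 25 amino-acid letters: the 20 standard residues plus U, O and the
# ambiguity codes B, Z, X (every letter except J).
AA_ALPHABET = "ABCDEFGHIKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class Vocab:
    """Dense 1-based symbol->id mapping with pad id 0 and a trailing unk id."""

    symbols: str
    name: str = ""

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return len(self.symbols) + 1

    @property
    def size(self) -> int:
        """Number of real symbols (excludes pad and unk)."""
        return len(self.symbols)

    @property
    def n_embeddings(self) -> int:
        """Rows an embedding table needs: pad + symbols + unk."""
        return len(self.symbols) + 2

    def encode_char(self, ch: str) -> int:
        idx = self.symbols.find(ch)
        return idx + 1 if idx >= 0 else self.unk_id

    def decode_id(self, i: int) -> str:
        if 1 <= i <= len(self.symbols):
            return self.symbols[i - 1]
        raise ValueError(f"id {i} is not a symbol id of vocab {self.name!r}")


SMILES_VOCAB = Vocab(SMILES_ALPHABET, name="smiles")
AA_VOCAB = Vocab(AA_ALPHABET, name="amino_acid")

assert SMILES_VOCAB.size == 62 and AA_VOCAB.size == 25


@dataclass(frozen=True)
class TokenizedSeq:
    """Fixed-length integer encoding of one sequence."""

    ids: np.ndarray          # (max_len,) int64
    true_length: int         # pre-padding length (after truncation)

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        object.__setattr__(self, "ids", ids)
        if self.true_length > ids.shape[0]:
            raise ValueError("true_length exceeds max length")


class LabelKind(str, Enum):
    PKD = "pkd"
    KIBA = "kiba"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class AffinityPair:
    drug_id: str
    protein_id: str
    label: float
    label_kind: LabelKind = LabelKind.PKD

    def __post_init__(self) -> None:
        if not math.isfinite(self.label):
            raise ValueError("affinity label must be finite")


def kd_to_pkd(kd_nM: float) -> float:
    """pKd = -log10(Kd / 1e9) with Kd in nanomolar."""
    if kd_nM <= 0:
        raise ValueError(f"Kd must be > 0 nM, got {kd_nM}")
    return -math.log10(kd_nM / 1e9)


def tokenize(seq: str, vocab: Vocab, max_len: int) -> TokenizedSeq:
    """Per-character integer encoding, truncated to ``max_len`` and
    right-padded with the pad id.  Unknown characters map to the unk id
    (with a logged warning)."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    ids = np.zeros(max_len, dtype=np.int64)
    clipped = seq[:max_len]
    unknown = []
    for i, ch in enumerate(clipped):
        code = vocab.encode_char(ch)
        if code == vocab.unk_id:
            unknown.append(ch)
        ids[i] = code
    if unknown:
        logger.warning("tokenize: %d unknown character(s) %r mapped to unk in vocab %s",
                       len(unknown), sorted(set(unknown)), vocab.name)
    return TokenizedSeq(ids, len(clipped))


def detokenize(tok: TokenizedSeq, vocab: Vocab) -> str:
    """Inverse of :func:`tokenize` over the unpadded prefix (in-vocab ids only)."""
    return "".join(vocab.decode_id(int(i)) for i in tok.ids[: tok.true_length])


# ---------------------------------------------------------------------------
# benchmark corpus loading


def _read_entity_list(directory: Path, stem: str) -> dict[str, str]:
    """Read ``stem.json`` (id -> string mapping) or ``stem.txt`` (two-column
    TSV) from ``directory``; insertion order is preserved."""
    json_path = directory / f"{stem}.json"
    txt_path = directory / f"{stem}.txt"
    if json_path.exists():
        with open(json_path) as fh:
            data = json.load(fh)
        return {str(k): str(v) for k, v in data.items()}
    if txt_path.exists():
        out: dict[str, str] = {}
        with open(txt_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, _, value = line.partition("\t")
                out[key] = value
        return out
    raise FileNotFoundError(
        f"expected {json_path.name} or {txt_path.name} in {directory}"
    )


def _read_affinity_matrix(directory: Path) -> np.ndarray:
    path = directory / "affinities.txt"
    if not path.exists():
        raise FileNotFoundError(f"expected {path.name} in {directory}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rows.append([
                float("nan") if cell.strip().lower() in ("", "nan") else float(cell)
                for cell in line.split("\t")
            ])
    return np.asarray(rows, dtype=float)


def _load_benchmark(directory, label_kind: LabelKind,
                    transform) -> tuple[dict, dict, list[AffinityPair]]:
    directory = Path(directory)
    drugs = _read_entity_list(directory, "ligands")
    proteins = _read_entity_list(directory, "proteins")
    Y = _read_affinity_matrix(directory)
    if Y.shape != (len(drugs), len(proteins)):
        raise ValueError(
            f"affinity matrix shape {Y.shape} does not match "
            f"{len(drugs)} drugs x {len(proteins)} proteins"
        )
    drug_ids = list(drugs)
    protein_ids = list(proteins)
    pairs = [
        AffinityPair(drug_ids[i], protein_ids[j], transform(Y[i, j]), label_kind)
        for i in range(Y.shape[0])
        for j in range(Y.shape[1])
        if math.isfinite(Y[i, j])
    ]
    return drugs, proteins, pairs


def load_davis(directory) -> tuple[dict, dict, list[AffinityPair]]:
    """Load a Davis-style corpus: Kd (nM) matrix cells become pKd labels."""
    return _load_benchmark(directory, LabelKind.PKD, kd_to_pkd)


def load_kiba(directory, max_protein_len: Optional[int] = None
              ) -> tuple[dict, dict, list[AffinityPair]]:
    """Load a KIBA-style corpus: scores pass through unchanged.

    When ``max_protein_len`` is set, proteins whose sequence exceeds it are
    removed together with their pairs (logged) -- the memory-driven
    long-protein filter.
    """
    drugs, proteins, pairs = _load_benchmark(directory, LabelKind.KIBA,
                                             float)
    if max_protein_len is not None:
        removed = {pid for pid, seq in proteins.items()
                   if len(seq) > max_protein_len}
        if removed:
            n_before = len(pairs)
            proteins = {pid: s for pid, s in proteins.items()
                        if pid not in removed}
            pairs = [p for p in pairs if p.protein_id not in removed]
            logger.info(
                "load_kiba: removed %d protein(s) longer than %d "
                "(%d pairs dropped)", len(removed), max_protein_len,
                n_before - len(pairs),
            )
    return drugs, proteins, pairs


# ---------------------------------------------------------------------------
# cross-validation splitting


@dataclass
class DatasetSplit:
    """A 5:1 train/test partition with k-fold assignment over the train part."""

    test_indices: np.ndarray
    folds: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    @property
    def train_indices(self) -> np.ndarray:
        return np.concatenate(self.folds) if self.folds else np.array([], int)

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) indices with ``fold`` as the validation fold."""
        val = self.folds[fold]
        train = np.concatenate(
            [f for i, f in enumerate(self.folds) if i != fold]
        )
        return train, val

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "test": self.test_indices.tolist(),
            "folds": [f.tolist() for f in self.folds],
        })


def make_splits(pairs: Sequence, n_folds: int = 5, test_ratio: float = 1 / 6,
                seed: int = 0) -> DatasetSplit:
    """Shuffle, hold out ``test_ratio`` of pairs, split the rest into folds.

    Deterministic under ``seed``; every pair lands in exactly one of
    {test, fold 0..n_folds-1}.
    """
    n = len(pairs)
    if n < n_folds + 1:
        raise ValueError(f"need at least {n_folds + 1} pairs, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_ratio))
    n_test = min(max(n_test, 1), n - n_folds)
    test = np.sort(order[:n_test])
    rest = order[n_test:]
    folds = [np.sort(f) for f in np.array_split(rest, n_folds)]
    return DatasetSplit(test_indices=test, folds=folds, seed=seed)
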