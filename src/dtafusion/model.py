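"""The cross-attention fusion affinity network.

Architecture: a drug branch (molecular-graph GCN block + character-level
transformer encoder over the SMILES) and a protein branch (transformer
encoder over the amino-acid sequence), each fused with its entity's
physicochemical descriptor vector through cross multi-head attention.
The four resulting 128-dim branch vectors -- drug sequence, drug fused,
protein sequence, protein fused -- are concatenated into a 512-dim vector
and passed through a two-layer fully connected head (2048 and 768 units,
ReLU) ending in a single output neuron: the predicted binding affinity.

Every architectural switch (cross-attention Q/K/V assignment, component
ablations) lives in :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError
from .nn.autodiff import Tensor, concat, no_grad
from .nn.layers import (
    Embedding, EncoderLayer, Linear, Module, MultiHeadAttention,
)
from .seqdata import AA_VOCAB, SMILES_VOCAB, TokenizedSeq, tokenize

__all__ = [
    "QKVMode", "ModelConfig", "MolGraph", "DrugRecord", "ProteinRecord",
    "positional_encoding", "gcn_layer", "mol_graph_from_smiles",
    "AffinityNet", "Batch", "collate",
]

#: Initial atom-feature layout: one-hot element over the nine tabulated
#: elements, then degree, then an aromaticity flag.
ATOM_FEATURE_ELEMENTS = ("C", "H", "N", "O", "F", "S", "Cl", "Br", "I")
ATOM_FEATURE_DIM = len(ATOM_FEATURE_ELEMENTS) + 2


class QKVMode(str, Enum):
    """Which cross-attention Q/K/V assignment to use.

    ``methods_text``: the query is the projected physicochemical vector and
    keys/values are the structural features (graph nodes for drugs,
    sequence positions for proteins).  ``table6_best``: for drugs Q = K =
    graph features and V = the physicochemical token; for proteins Q =
    sequence features and K = V = the physicochemical token.  Both
    assignments appear in the source description and disagree; neither is
    guessed to be the intent, so both are implemented.
    """

    METHODS_TEXT = "methods_text"
    TABLE6_BEST = "table6_best"


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter and ablation switch."""

    embed_dim: int = 128            # t = u, shared drug/protein embedding size
    n_heads: int = 4
    max_drug_len: int = 100         # k
    max_protein_len: int = 1000     # e
    branch_dim: int = 128
    fc_dims: tuple[int, int] = (2048, 768)
    ffn_mult: int = 4               # encoder feed-forward width, x embed_dim
    qkv_mode: QKVMode = QKVMode.METHODS_TEXT
    use_drug_pc: bool = True
    use_protein_pc: bool = True
    use_mcat: bool = True
    use_gnn: bool = True
    use_cp_encoder: bool = True
    use_curvature: bool = True
    use_potential: bool = True
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.embed_dim % 2 != 0:
            raise ConfigError("embed_dim must be even (sinusoidal encoding)")
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError("embed_dim must be divisible by n_heads")
        if self.branch_dim * 4 != 512:
            raise ConfigError("four branches must concatenate to 512 dims")
        if self.dtype not in ("float32", "float64"):
            raise ConfigError(f"unsupported dtype {self.dtype!r}")
        object.__setattr__(self, "qkv_mode", QKVMode(self.qkv_mode))
        object.__setattr__(self, "fc_dims", tuple(self.fc_dims))

    @property
    def protein_pc_dim(self) -> int:
        return 5 - (not self.use_curvature) - (not self.use_potential)

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qkv_mode"] = self.qkv_mode.value
        d["fc_dims"] = list(self.fc_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class MolGraph:
    """Molecular graph: initial atom features + symmetric 0/1 adjacency."""

    node_features: np.ndarray   # (N, ATOM_FEATURE_DIM)
    adjacency: np.ndarray       # (N, N), zero diagonal

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero before self-loops")
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(
            self, "node_features", np.asarray(self.node_features, dtype=float)
        )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def mol_graph_from_smiles(smiles: str) -> MolGraph:
    """Parse SMILES into a molecular graph (canonical parsed atom order)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError(f"SMILES {smiles!r} has no atoms")
    X = np.zeros((n, ATOM_FEATURE_DIM))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym in ATOM_FEATURE_ELEMENTS:
            X[i, ATOM_FEATURE_ELEMENTS.index(sym)] = 1.0
        X[i, -2] = atom.GetDegree()
        X[i, -1] = 1.0 if atom.GetIsAromatic() else 0.0
    A = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return MolGraph(X, A)


@dataclass(frozen=True)
class DrugRecord:
    """A drug: SMILES, tokenized sequence, molecular graph, 16-dim descriptors."""

    drug_id: str
    smiles: str
    tokens: TokenizedSeq
    graph: MolGraph
    pc_vector: np.ndarray

    @classmethod
    def build(cls, drug_id: str, smiles: str, pc_vector: np.ndarray,
              max_len: int = 100) -> "DrugRecord":
        return cls(drug_id, smiles, tokenize(smiles, SMILES_VOCAB, max_len),
                   mol_graph_from_smiles(smiles), np.asarray(pc_vector, float))


@dataclass(frozen=True)
class ProteinRecord:
    """A protein: sequence, tokenized sequence, 5-dim descriptor vector."""

    protein_id: str
    sequence: str
    tokens: TokenizedSeq
    pc_vector: np.ndarray

    @classmethod
    def build(cls, protein_id: str, sequence: str, pc_vector: np.ndarray,
              max_len: int = 1000) -> "ProteinRecord":
        return cls(protein_id, sequence, tokenize(sequence, AA_VOCAB, max_len),
                   np.asarray(pc_vector, float))


def positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Sinusoidal positional encoding; positions are indexed from i = 1.

    Row r (0-based) holds position i = r + 1 with
    PE(i, 2j) = sin(i / 10000^(2j/dim)), PE(i, 2j+1) = cos(i / 10000^(2j/dim)).
    """
    if dim % 2 != 0:
        raise ConfigError(f"positional encoding dim must be even, got {dim}")
    i = np.arange(1, n_positions + 1, dtype=float)[:, None]
    j = np.arange(dim // 2, dtype=float)[None, :]
    angle = i / np.power(10000.0, 2.0 * j / dim)
    pe = np.zeros((n_positions, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation matrix D~^-1/2 (A + I) D~^-1/2."""
    A = np.asarray(A, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def gcn_layer(H: np.ndarray, A_tilde: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph-convolution step: ReLU(D~^-1/2 A~ D~^-1/2 H W).

    ``A_tilde`` is the adjacency *with* self-loops (A + I); normalization is
    applied here.  Plain-ndarray reference form used by tests and by the
    network's GNN block (through its differentiable twin).
    """
    A_tilde = np.asarray(A_tilde, dtype=float)
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    S = A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return np.maximum(S @ np.asarray(H, float) @ np.asarray(W, float), 0.0)


class GNNBlock(Module):
    """Two GCN layers with a residual projection of the initial features:
    out = proj(X) + GCN2(GCN1(X))."""

    def __init__(self, in_dim: int, out_dim: int, rng, dtype):
        self.proj = Linear(in_dim, out_dim, rng, bias=False, dtype=dtype)
        self.W1 = Linear(in_dim, out_dim, rng, bias=False, dtype=dtype)
        self.W2 = Linear(out_dim, out_dim, rng, bias=False, dtype=dtype)

    def __call__(self, X: Tensor, S: np.ndarray) -> Tensor:
        """X: (B, N, in_dim) node features; S: (B, N, N) normalized adjacency."""
        S_t = Tensor(S)
        h1 = (S_t @ self.W1(X)).relu()
        h2 = (S_t @ self.W2(h1)).relu()
        return self.proj(X) + h2


class CPEncoder(Module):
    """Three-encoder sequence module: a first encoder whose output is
    residually combined with the embedded input, then two parallel encoders
    with independent parameters whose (projected) outputs are summed into
    the stream:  h = E1(X) + X;  out = h + P2(E2(h)) + P3(E3(h))."""

    def __init__(self, dim: int, n_heads: int, ffn_hidden: int, rng, dtype):
        self.enc1 = EncoderLayer(dim, n_heads, ffn_hidden, rng, dtype=dtype)
        self.enc2 = EncoderLayer(dim, n_heads, ffn_hidden, rng, dtype=dtype)
        self.enc3 = EncoderLayer(dim, n_heads, ffn_hidden, rng, dtype=dtype)
        self.out2 = Linear(dim, dim, rng, bias=False, dtype=dtype)
        self.out3 = Linear(dim, dim, rng, bias=False, dtype=dtype)

    def __call__(self, X: Tensor, key_mask: Optional[np.ndarray] = None) -> Tensor:
        h = self.enc1(X, key_mask=key_mask) + X
        return h + self.out2(self.enc2(h, key_mask=key_mask)) \
                 + self.out3(self.enc3(h, key_mask=key_mask))


@dataclass
class Batch:
    """Padded batch arrays for a forward pass (lengths trimmed to the batch
    maximum; masks are True on real tokens/nodes)."""

    drug_tokens: np.ndarray      # (B, Ld) int64
    drug_mask: np.ndarray        # (B, Ld) bool
    prot_tokens: np.ndarray      # (B, Lp) int64
    prot_mask: np.ndarray        # (B, Lp) bool
    node_features: np.ndarray    # (B, Nmax, ATOM_FEATURE_DIM)
    node_adjacency: np.ndarray   # (B, Nmax, Nmax) normalized, self-loops
    node_mask: np.ndarray        # (B, Nmax) bool
    drug_pc: np.ndarray          # (B, 16)
    protein_pc: np.ndarray       # (B, <=5)

    @property
    def size(self) -> int:
        return self.drug_tokens.shape[0]


def _pc_slice(pc: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Drop the curvature / potential slots when ablated (protein vectors
    are ordered gravy, MW, pI, potential, curvature)."""
    keep = [0, 1, 2]
    if cfg.use_potential:
        keep.append(3)
    if cfg.use_curvature:
        keep.append(4)
    return pc[:, keep]


def collate(drugs: Sequence[DrugRecord], proteins: Sequence[ProteinRecord],
            cfg: ModelConfig,
            pc_transform=None) -> Batch:
    """Assemble padded arrays for aligned lists of drug/protein records.

    ``pc_transform(drug_pc, protein_pc)`` may rescale the descriptor
    matrices (the estimator's internal standardization hook).
    """
    B = len(drugs)
    if len(proteins) != B:
        raise ValueError("drugs and proteins must align one-to-one")
    Ld = max(max(d.tokens.true_length for d in drugs), 1)
    Lp = max(max(p.tokens.true_length for p in proteins), 1)
    drug_tokens = np.stack([d.tokens.ids[:Ld] for d in drugs])
    prot_tokens = np.stack([p.tokens.ids[:Lp] for p in proteins])
    drug_mask = np.arange(Ld)[None, :] < np.asarray(
        [d.tokens.true_length for d in drugs])[:, None]
    prot_mask = np.arange(Lp)[None, :] < np.asarray(
        [p.tokens.true_length for p in proteins])[:, None]

    Nmax = max(d.graph.n_nodes for d in drugs)
    X = np.zeros((B, Nmax, ATOM_FEATURE_DIM))
    S = np.zeros((B, Nmax, Nmax))
    node_mask = np.zeros((B, Nmax), dtype=bool)
    for b, d in enumerate(drugs):
        n = d.graph.n_nodes
        X[b, :n] = d.graph.node_features
        S[b, :n, :n] = normalized_adjacency(d.graph.adjacency)
        # padded nodes get bare self-loops so the propagation matrix stays valid
        for i in range(n, Nmax):
            S[b, i, i] = 1.0
        node_mask[b, :n] = True

    drug_pc = np.stack([d.pc_vector for d in drugs])
    protein_pc = np.stack([p.pc_vector for p in proteins])
    if pc_transform is not None:
        drug_pc, protein_pc = pc_transform(drug_pc, protein_pc)
    protein_pc = _pc_slice(np.asarray(protein_pc, float), cfg)
    return Batch(drug_tokens, drug_mask, prot_tokens, prot_mask,
                 X, S, node_mask, np.asarray(drug_pc, float), protein_pc)


def _masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over the length axis restricted to unmasked positions.

    x: (B, L, D); mask: (B, L) bool.  All-masked rows give zeros.
    """
    m = mask.astype(x.dtype)[:, :, None]
    denom = np.maximum(m.sum(axis=1), 1.0)
    return (x * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)


class AffinityNet(Module):
    """The full drug-target affinity network (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        t = cfg.embed_dim
        dt = cfg.np_dtype
        rng = np.random.default_rng(cfg.seed)
        ffn = cfg.ffn_mult * t

        self.drug_embed = Embedding(SMILES_VOCAB.n_embeddings, t, rng, dtype=dt)
        self.prot_embed = Embedding(AA_VOCAB.n_embeddings, t, rng, dtype=dt)
        self.pe_drug = positional_encoding(cfg.max_drug_len, t).astype(dt)
        self.pe_prot = positional_encoding(cfg.max_protein_len, t).astype(dt)

        if cfg.use_cp_encoder:
            self.drug_encoder = CPEncoder(t, cfg.n_heads, ffn, rng, dt)
            self.prot_encoder = CPEncoder(t, cfg.n_heads, ffn, rng, dt)
        else:
            self.drug_encoder = EncoderLayer(t, cfg.n_heads, ffn, rng, dtype=dt)
            self.prot_encoder = EncoderLayer(t, cfg.n_heads, ffn, rng, dtype=dt)

        if cfg.use_gnn:
            self.gnn = GNNBlock(ATOM_FEATURE_DIM, t, rng, dt)
        if cfg.use_drug_pc:
            self.drug_pc_proj = Linear(16, t, rng, dtype=dt)
            if cfg.use_mcat:
                self.cross_drug = MultiHeadAttention(t, cfg.n_heads, rng, dtype=dt)
                self.drug_fused_pool = Linear(t, cfg.branch_dim, rng, dtype=dt)
            else:
                self.drug_fused_pool = Linear(2 * t, cfg.branch_dim, rng, dtype=dt)
        else:
            self.drug_fused_pool = Linear(t, cfg.branch_dim, rng, dtype=dt)

        if cfg.use_protein_pc:
            self.prot_pc_proj = Linear(cfg.protein_pc_dim, t, rng, dtype=dt)
            if cfg.use_mcat:
                self.cross_prot = MultiHeadAttention(t, cfg.n_heads, rng, dtype=dt)
                self.prot_fused_pool = Linear(t, cfg.branch_dim, rng, dtype=dt)
            else:
                self.prot_fused_pool = Linear(2 * t, cfg.branch_dim, rng, dtype=dt)
        else:
            self.prot_fused_pool = Linear(t, cfg.branch_dim, rng, dtype=dt)

        self.drug_seq_pool = Linear(t, cfg.branch_dim, rng, dtype=dt)
        self.prot_seq_pool = Linear(t, cfg.branch_dim, rng, dtype=dt)

        d1, d2 = cfg.fc_dims
        self.fc1 = Linear(4 * cfg.branch_dim, d1, rng, dtype=dt)
        self.fc2 = Linear(d1, d2, rng, dtype=dt)
        self.out = Linear(d2, 1, rng, dtype=dt)

    # -- sub-computations -------------------------------------------------
    def encode_drug_seq(self, tokens: np.ndarray, mask: np.ndarray) -> Tensor:
        L = tokens.shape[1]
        if L > self.cfg.max_drug_len:
            raise ConfigError("drug token length exceeds max_drug_len")
        X = self.drug_embed(tokens) + Tensor(self.pe_drug[:L])
        return self.drug_encoder(X, key_mask=mask)

    def encode_protein_seq(self, tokens: np.ndarray, mask: np.ndarray) -> Tensor:
        L = tokens.shape[1]
        if L > self.cfg.max_protein_len:
            raise ConfigError("protein token length exceeds max_protein_len")
        X = self.prot_embed(tokens) + Tensor(self.pe_prot[:L])
        return self.prot_encoder(X, key_mask=mask)

    def _cross_fuse(self, pc_token: Tensor, feats: Tensor, mask: np.ndarray,
                    mha: MultiHeadAttention, pool: Linear,
                    protein_side: bool) -> Tensor:
        """Cross multi-head attention between a physicochemical token
        (B, 1, t) and structural/sequence features (B, L, t), pooled to the
        branch dimension."""
        if self.cfg.qkv_mode is QKVMode.METHODS_TEXT:
            fused = mha(pc_token, feats, feats, key_mask=mask)  # (B, 1, t)
            pooled = fused.sum(axis=1)  # single query token -> mean == sum
        elif protein_side:
            # Q = sequence features, K = V = the physicochemical token
            fused = mha(feats, pc_token, pc_token, key_mask=None)  # (B, L, t)
            pooled = _masked_mean(fused, mask)
        else:
            # Q = K = graph features, V = the pc token tiled across keys
            L = feats.shape[1]
            ones = Tensor(np.ones((1, L, 1), dtype=pc_token.dtype))
            v = pc_token * ones  # (B, L, t) uniform value content
            fused = mha(feats, feats, v, key_mask=mask)
            pooled = _masked_mean(fused, mask)
        return pool(pooled)

    # -- forward ----------------------------------------------------------
    def forward(self, batch: Batch) -> Tensor:
        cfg = self.cfg
        dt = cfg.np_dtype

        drug_feats = self.encode_drug_seq(batch.drug_tokens, batch.drug_mask)
        prot_feats = self.encode_protein_seq(batch.prot_tokens, batch.prot_mask)

        drug_seq_vec = self.drug_seq_pool(_masked_mean(drug_feats, batch.drug_mask))
        prot_seq_vec = self.prot_seq_pool(_masked_mean(prot_feats, batch.prot_mask))

        # structural features feeding the drug fusion branch
        if cfg.use_gnn:
            X = Tensor(batch.node_features.astype(dt))
            S = batch.node_adjacency.astype(dt)
            struct_feats, struct_mask = self.gnn(X, S), batch.node_mask
        else:
            struct_feats, struct_mask = drug_feats, batch.drug_mask

        if cfg.use_drug_pc:
            pc_tok = self.drug_pc_proj(
                Tensor(batch.drug_pc.astype(dt))).reshape(
                batch.size, 1, cfg.embed_dim)
            if cfg.use_mcat:
                drug_fused = self._cross_fuse(
                    pc_tok, struct_feats, struct_mask,
                    self.cross_drug, self.drug_fused_pool, protein_side=False)
            else:
                pooled = _masked_mean(struct_feats, struct_mask)
                drug_fused = self.drug_fused_pool(
                    concat([pooled, pc_tok.sum(axis=1)], axis=-1))
        else:
            drug_fused = self.drug_fused_pool(
                _masked_mean(struct_feats, struct_mask))

        if cfg.use_protein_pc:
            pc_tok = self.prot_pc_proj(
                Tensor(batch.protein_pc.astype(dt))).reshape(
                batch.size, 1, cfg.embed_dim)
            if cfg.use_mcat:
                prot_fused = self._cross_fuse(
                    pc_tok, prot_feats, batch.prot_mask,
                    self.cross_prot, self.prot_fused_pool, protein_side=True)
            else:
                pooled = _masked_mean(prot_feats, batch.prot_mask)
                prot_fused = self.prot_fused_pool(
                    concat([pooled, pc_tok.sum(axis=1)], axis=-1))
        else:
            prot_fused = self.prot_fused_pool(
                _masked_mean(prot_feats, batch.prot_mask))

        z = concat([drug_seq_vec, drug_fused, prot_seq_vec, prot_fused],
                   axis=-1)
        if z.shape[-1] != 4 * cfg.branch_dim:
            raise ConfigError("concatenated branch vector has wrong length")
        h = self.fc2(self.fc1(z).relu()).relu()
        out = self.out(h).reshape(batch.size)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite affinity prediction")
        return out

    __call__ = forward

    def predict(self, drugs: Sequence[DrugRecord],
                proteins: Sequence[ProteinRecord],
                pc_transform=None, batch_size: int = 64) -> np.ndarray:
        """Inference over aligned record lists (no gradient tape)."""
        outs = []
        with no_grad():
            for lo in range(0, len(drugs), batch_size):
                batch = collate(drugs[lo:lo + batch_size],
                                proteins[lo:lo + batch_size], self.cfg,
                                pc_transform=pc_transform)
                outs.append(self.forward(batch).numpy())
        return np.concatenate(outs) if outs else np.empty(0)


def predict_affinity(drug: DrugRecord, protein: ProteinRecord,
                     config: ModelConfig) -> float:
    """Single-pair forward pass through a freshly initialized network."""
    net = AffinityNet(config)
    return float(net.predict([drug], [protein])[0])
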