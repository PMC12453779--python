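"""Scikit-learn-style estimator wrapping the affinity network.

``DTARegressor`` follows the sklearn estimator contract: all constructor
arguments are hyperparameters stored verbatim (so ``get_params`` /
``set_params`` and ``clone`` work), ``fit(X, y)`` learns from a sequence
of (DrugRecord, ProteinRecord) pairs with float affinity targets, and
fitted state lives in trailing-underscore attributes.  ``predict``
returns a float array of predicted affinities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .model import AffinityNet, DrugRecord, ModelConfig, ProteinRecord
from .seqdata import AffinityPair, LabelKind
from .training import PairDataset, TrainConfig, train

__all__ = ["DTARegressor"]


class DTARegressor(BaseEstimator, RegressorMixin):
    """Drug-target affinity regressor (cross-attention fusion network).

    Parameters mirror the model and training configuration; see
    :class:`~dtafusion.model.ModelConfig` and
    :class:`~dtafusion.training.TrainConfig` for semantics.

    Examples
    --------
    >>> reg = DTARegressor(embed_dim=16, max_epochs=5, seed=0)
    >>> reg.fit(pairs, y)            # pairs: [(DrugRecord, ProteinRecord)]
    >>> y_hat = reg.predict(pairs)
    """

    def __init__(self, embed_dim: int = 128, n_heads: int = 4,
                 max_drug_len: int = 100, max_protein_len: int = 1000,
                 branch_dim: int = 128, fc_dims: tuple = (2048, 768),
                 ffn_mult: int = 4, qkv_mode: str = "methods_text",
                 use_drug_pc: bool = True, use_protein_pc: bool = True,
                 use_mcat: bool = True, use_gnn: bool = True,
                 use_cp_encoder: bool = True, use_curvature: bool = True,
                 use_potential: bool = True, dtype: str = "float64",
                 learning_rate: float = 0.001, batch_size: int = 32,
                 max_epochs: int = 400,
                 early_stop_patience: Optional[int] = None,
                 standardize_pc: bool = True,
                 validation_fraction: float = 0.1, seed: int = 0):
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.max_drug_len = max_drug_len
        self.max_protein_len = max_protein_len
        self.branch_dim = branch_dim
        self.fc_dims = fc_dims
        self.ffn_mult = ffn_mult
        self.qkv_mode = qkv_mode
        self.use_drug_pc = use_drug_pc
        self.use_protein_pc = use_protein_pc
        self.use_mcat = use_mcat
        self.use_gnn = use_gnn
        self.use_cp_encoder = use_cp_encoder
        self.use_curvature = use_curvature
        self.use_potential = use_potential
        self.dtype = dtype
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.standardize_pc = standardize_pc
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- config assembly ---------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            embed_dim=self.embed_dim, n_heads=self.n_heads,
            max_drug_len=self.max_drug_len,
            max_protein_len=self.max_protein_len,
            branch_dim=self.branch_dim, fc_dims=tuple(self.fc_dims),
            ffn_mult=self.ffn_mult, qkv_mode=self.qkv_mode,
            use_drug_pc=self.use_drug_pc, use_protein_pc=self.use_protein_pc,
            use_mcat=self.use_mcat, use_gnn=self.use_gnn,
            use_cp_encoder=self.use_cp_encoder,
            use_curvature=self.use_curvature,
            use_potential=self.use_potential,
            seed=self.seed, dtype=self.dtype,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, seed=self.seed,
            early_stop_patience=self.early_stop_patience,
            standardize_pc=self.standardize_pc,
        )

    @staticmethod
    def _unpack(X) -> tuple[list[DrugRecord], list[ProteinRecord]]:
        drugs, proteins = [], []
        for item in X:
            d, p = item
            if not isinstance(d, DrugRecord) or not isinstance(p, ProteinRecord):
                raise TypeError(
                    "X must be a sequence of (DrugRecord, ProteinRecord) pairs"
                )
            drugs.append(d)
            proteins.append(p)
        return drugs, proteins

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: Sequence, y) -> "DTARegressor":
        """Fit the network on (DrugRecord, ProteinRecord) pairs and targets."""
        drugs, proteins = self._unpack(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(drugs):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")

        drug_map = {d.drug_id: d for d in drugs}
        prot_map = {p.protein_id: p for p in proteins}
        pairs = [
            AffinityPair(d.drug_id, p.protein_id, float(t), LabelKind.SYNTHETIC)
            for d, p, t in zip(drugs, proteins, y)
        ]
        dataset = PairDataset(drug_map, prot_map, pairs)

        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(pairs))
        n_val = int(round(len(pairs) * self.validation_fraction))
        val_idx = order[:n_val] if n_val > 0 else None
        train_idx = order[n_val:]

        net = AffinityNet(self._model_config())
        net, history = train(net, dataset, train_idx, val_idx,
                             self._train_config())
        self.model_ = net
        self.history_ = history
        self.n_parameters_ = net.n_parameters()
        self.n_features_in_ = 2  # a drug record and a protein record
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        drugs, proteins = self._unpack(X)
        return self.model_.predict(
            drugs, proteins,
            pc_transform=getattr(self.model_, "pc_transform_", None),
            batch_size=max(self.batch_size, 1),
        )
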