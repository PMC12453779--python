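"""Shared configuration presets.

``published_config`` carries the architecture constants of the full-scale
model (embedding width 128, four heads, 2048/768 prediction head,
drug/protein maximum lengths 100/1000).  ``desk_config`` is the reduced
single-CPU preset used for synthetic-data experiments: the architecture
and training procedure are identical, but the embedding width is 16, the
encoder feed-forward multiplier 2, protein sequences are truncated at 128
tokens and parameters are float32 — sizes chosen so a full train/evaluate
cycle on a ~600-pair synthetic corpus completes in well under a minute.
"""

from __future__ import annotations

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["published_config", "desk_config", "desk_train_config"]


def published_config(seed: int = 0, **overrides) -> ModelConfig:
    """Architecture as published: t = u = 128, 4 heads, FC head 2048/768."""
    return ModelConfig(seed=seed, **overrides)


def desk_config(seed: int = 0, **overrides) -> ModelConfig:
    """Single-CPU preset for synthetic corpora (same topology, smaller t)."""
    kw = dict(embed_dim=16, n_heads=4, ffn_mult=2, max_protein_len=128,
              dtype="float32")
    kw.update(overrides)
    return ModelConfig(seed=seed, **kw)


def desk_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Adam lr 0.001, batch 32, up to 20 epochs with patience-4 early stop."""
    kw = dict(max_epochs=20, early_stop_patience=4)
    kw.update(overrides)
    return TrainConfig(seed=seed, **kw)
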