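"""Mini-batch MSE training with Adam, cross-validation and evaluation.

The trainer minimizes mean-squared error on the training folds, tracks
per-epoch train/validation loss, keeps the parameters with the best
validation MSE, and evaluates on the held-out test pairs with the four
affinity metrics (MSE, CI, R^2, rm^2).  Descriptor inputs are
standardized by training-set statistics before entering the network
(raw-valued descriptor matrices stay raw on disk; this is an internal
conditioning step).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .metrics import evaluate_all
from .model import AffinityNet, Batch, DrugRecord, ModelConfig, ProteinRecord, collate
from .nn.layers import Adam
from .seqdata import AffinityPair, DatasetSplit

__all__ = [
    "TrainConfig", "EvalReport", "PairDataset", "train", "cross_validate",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam, MSE loss)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 400
    seed: int = 0
    early_stop_patience: Optional[int] = None
    standardize_pc: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class EvalReport:
    """Metrics on a test set, optionally with per-fold values + mean/SD."""

    mse: float
    ci: float
    r2: float
    rm2: float
    n_pairs: int
    per_fold: Optional[list[dict[str, float]]] = None
    fold_mean: Optional[dict[str, float]] = None
    fold_sd: Optional[dict[str, float]] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PairDataset:
    """Drug/protein record lookups plus the labelled pair list."""

    drugs: Mapping[str, DrugRecord]
    proteins: Mapping[str, ProteinRecord]
    pairs: Sequence[AffinityPair]

    def subset_arrays(self, indices: np.ndarray
                      ) -> tuple[list[DrugRecord], list[ProteinRecord], np.ndarray]:
        ds = [self.drugs[self.pairs[i].drug_id] for i in indices]
        ps = [self.proteins[self.pairs[i].protein_id] for i in indices]
        y = np.asarray([self.pairs[i].label for i in indices], dtype=float)
        return ds, ps, y


class _PCStandardizer:
    """Per-column z-scoring of descriptor matrices, fit on training entities."""

    def __init__(self, drugs: Sequence[DrugRecord],
                 proteins: Sequence[ProteinRecord]):
        dmat = np.stack([d.pc_vector for d in {id(d): d for d in drugs}.values()])
        pmat = np.stack([p.pc_vector for p in {id(p): p for p in proteins}.values()])
        self.d_mean, self.d_sd = dmat.mean(0), dmat.std(0)
        self.p_mean, self.p_sd = pmat.mean(0), pmat.std(0)
        self.d_sd[self.d_sd == 0] = 1.0
        self.p_sd[self.p_sd == 0] = 1.0

    def __call__(self, drug_pc: np.ndarray, protein_pc: np.ndarray):
        return ((drug_pc - self.d_mean) / self.d_sd,
                (protein_pc - self.p_mean) / self.p_sd)


def _epoch_loss(net: AffinityNet, dataset: PairDataset, indices: np.ndarray,
                pc_transform, batch_size: int) -> float:
    """Mean squared error over ``indices`` without parameter updates."""
    from .nn.autodiff import no_grad

    total, n = 0.0, 0
    with no_grad():
        for lo in range(0, len(indices), batch_size):
            sub = indices[lo:lo + batch_size]
            ds, ps, y = dataset.subset_arrays(sub)
            batch = collate(ds, ps, net.cfg, pc_transform=pc_transform)
            pred = net.forward(batch).numpy()
            total += float(((pred - y) ** 2).sum())
            n += len(sub)
    return total / max(n, 1)


def train(net: AffinityNet, dataset: PairDataset,
          train_indices: np.ndarray, val_indices: Optional[np.ndarray],
          cfg: TrainConfig) -> tuple[AffinityNet, list[dict]]:
    """Fit ``net`` in place; returns (net, per-epoch history).

    Each history entry records epoch, train_loss and (when a validation
    set is given) val_loss.  The parameters achieving the best validation
    MSE are restored at the end; with ``max_epochs = 0`` the initialized
    network is returned unchanged.
    """
    rng = np.random.default_rng(cfg.seed)
    params = net.parameters()
    opt = Adam(params, lr=cfg.learning_rate)

    pc_transform = None
    if cfg.standardize_pc:
        ds, ps, _ = dataset.subset_arrays(np.asarray(train_indices))
        pc_transform = _PCStandardizer(ds, ps)
    net.pc_transform_ = pc_transform

    history: list[dict] = []
    best_val = math.inf
    best_state = None
    bad_epochs = 0
    train_indices = np.asarray(train_indices)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_indices))
        total, n = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            sub = train_indices[order[lo:lo + cfg.batch_size]]
            ds, ps, y = dataset.subset_arrays(sub)
            batch = collate(ds, ps, net.cfg, pc_transform=pc_transform)
            pred = net.forward(batch)
            err = pred - np.asarray(y, dtype=pred.dtype)
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sub)
            n += len(sub)
        entry = {"epoch": epoch, "train_loss": total / max(n, 1)}
        if val_indices is not None and len(val_indices):
            val_loss = _epoch_loss(net, dataset, np.asarray(val_indices),
                                   pc_transform, cfg.batch_size)
            entry["val_loss"] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_state = [p.data.copy() for p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if (cfg.early_stop_patience is not None
                        and bad_epochs > cfg.early_stop_patience):
                    history.append(entry)
                    break
        history.append(entry)

    if best_state is not None:
        net.load_state_arrays(best_state)
    return net, history


def evaluate(net: AffinityNet, dataset: PairDataset,
             indices: np.ndarray) -> EvalReport:
    ds, ps, y = dataset.subset_arrays(np.asarray(indices))
    pred = net.predict(ds, ps, pc_transform=getattr(net, "pc_transform_", None))
    m = evaluate_all(y, pred)
    return EvalReport(m["mse"], m["ci"], m["r2"], m["rm2"], len(y))


def train_evaluate(model_cfg: ModelConfig, dataset: PairDataset,
                   split: DatasetSplit, train_cfg: TrainConfig,
                   fold: int = 0) -> tuple[AffinityNet, list[dict], EvalReport]:
    """Train on the non-validation folds, select on fold ``fold``,
    evaluate on the held-out test pairs."""
    net = AffinityNet(model_cfg)
    tr, val = split.fold_split(fold)
    net, history = train(net, dataset, tr, val, train_cfg)
    report = evaluate(net, dataset, split.test_indices)
    return net, history, report


def cross_validate(model_cfg: ModelConfig, dataset: PairDataset,
                   split: DatasetSplit, train_cfg: TrainConfig) -> EvalReport:
    """Rotate the validation fold; report per-fold test metrics + mean/SD."""
    per_fold = []
    for fold in range(len(split.folds)):
        _, _, rep = train_evaluate(model_cfg, dataset, split, train_cfg, fold)
        per_fold.append({"mse": rep.mse, "ci": rep.ci,
                         "r2": rep.r2, "rm2": rep.rm2})
    keys = ("mse", "ci", "r2", "rm2")
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
    sd = {k: float(np.std([f[k] for f in per_fold])) for k in keys}
    return EvalReport(mean["mse"], mean["ci"], mean["r2"], mean["rm2"],
                      len(split.test_indices), per_fold, mean, sd)


def save_checkpoint(path, net: AffinityNet) -> None:
    """Single-file checkpoint: parameters + config (+ pc scaling if fit)."""
    arrays = {f"param_{i}": a for i, a in enumerate(net.state_arrays())}
    pc = getattr(net, "pc_transform_", None)
    if pc is not None:
        arrays.update(pc_d_mean=pc.d_mean, pc_d_sd=pc.d_sd,
                      pc_p_mean=pc.p_mean, pc_p_sd=pc.p_sd)
    np.savez(path, config=json.dumps(net.cfg.to_dict()), **arrays)


def load_checkpoint(path) -> AffinityNet:
    data = np.load(path, allow_pickle=False)
    cfg = ModelConfig.from_dict(json.loads(str(data["config"])))
    net = AffinityNet(cfg)
    n = len(net.parameters())
    net.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    if "pc_d_mean" in data:
        pc = _PCStandardizer.__new__(_PCStandardizer)
        pc.d_mean, pc.d_sd = data["pc_d_mean"], data["pc_d_sd"]
        pc.p_mean, pc.p_sd = data["pc_p_mean"], data["pc_p_sd"]
        net.pc_transform_ = pc
    return net
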