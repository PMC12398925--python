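"""Training loop with per-epoch quartet-score tracking.

Training presents the data quartet-wise: one epoch is one pass over all
quartet splits of the reference tree in shuffled minibatches (default 64
quartets per step).  Every step embeds all taxa — the batch only selects
which quartets (and, for the regularized losses, which within-quartet
pairs) contribute to the loss — evaluates the configured loss,
backpropagates through the latent distance matrix into the encoder, and
takes one Adam step.  The pure siamese loss is handled the same way with
taxon pairs as the unit.  After each epoch the model is re-evaluated
without dropout to record the loss, the quartet score over all reference
quartets, and the mean latent vector norm.

The norm trajectory is the collapse diagnostic: the pure quartet loss
admits the all-zero embedding as a perfect minimizer, and a run that falls
into it shows the mean norm decaying to ~0 while the quartet score drops
(all quartets then have e = f = 0, failing the strict |e| < f rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, write_nexus, write_phylip
from .encoder import SequenceEncoder, encode_batch, pairwise_distances
from .losses import LossConfig, loss_and_grad, siamese_pairs_grad
from .quartets import QuartetTable, quartet_score
from .trees import ReferenceTree, enumerate_quartets, patristic_matrix

__all__ = [
    "EpochRecord",
    "TrainingLog",
    "Adam",
    "train",
    "detect_collapse",
    "run_replicates",
    "replicate_summary",
    "export_distances",
]


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    loss: float
    quartet_score: float
    mean_norm: float


@dataclass
class TrainingLog:
    """Per-epoch diagnostics of one training run (epoch 0 = untrained)."""

    records: list[EpochRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.quartet_score for r in self.records])

    @property
    def norms(self) -> np.ndarray:
        return np.array([r.mean_norm for r in self.records])

    @property
    def losses(self) -> np.ndarray:
        return np.array([r.loss for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [r.epoch for r in self.records],
                "loss": self.losses,
                "quartet_score": self.scores,
                "mean_norm": self.norms,
            }
        )


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _distance_grad_to_features(F: np.ndarray, D: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Chain d loss / d D (per unordered pair, symmetric G) into d loss / d F."""
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(D > 0, G / np.where(D > 0, D, 1.0), 0.0)
    diff = F[:, None, :] - F[None, :, :]
    return (R[:, :, None] * diff).sum(axis=1)


def _validate_inputs(tree: ReferenceTree, sequences: Mapping[str, str],
                     loss_cfg: LossConfig) -> None:
    seq_ids, leaf_ids = set(sequences), set(tree.leaves)
    if seq_ids != leaf_ids:
        raise ValueError(
            "sequence IDs do not match tree leaves; "
            f"only in FASTA: {sorted(seq_ids - leaf_ids)}, "
            f"only in tree: {sorted(leaf_ids - seq_ids)}"
        )
    if len({len(s) for s in sequences.values()}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    if loss_cfg.needs_branch_lengths and not tree.has_branch_lengths:
        raise ValueError(
            f"loss {loss_cfg.kind!r} requires branch lengths on the "
            "reference tree; use the quartet loss for topology-only trees"
        )


def train(
    tree: ReferenceTree,
    sequences: Mapping[str, str],
    loss_cfg: LossConfig,
    epochs: int = 100,
    lr: float = 7e-3,
    seed: int = 0,
    batch_size: int = 64,
    model_kwargs: Optional[dict] = None,
    table: Optional[QuartetTable] = None,
) -> tuple[SequenceEncoder, TrainingLog]:
    """Train the encoder against the reference tree.

    One epoch passes once over the training units — quartet splits for the
    quartet and combined losses, taxon pairs for the siamese loss — in
    shuffled minibatches of ``batch_size`` units, taking one Adam step per
    batch.  Returns the trained model and a log with epochs 0..epochs,
    where epoch 0 records the untrained model.  Deterministic for a fixed
    seed.
    """
    _validate_inputs(tree, sequences, loss_cfg)
    X, taxa = encode_batch(sequences)
    n = len(taxa)
    if table is None:
        table = enumerate_quartets(tree)
    DT = patristic_matrix(tree).values if loss_cfg.needs_branch_lengths else None
    if loss_cfg.kind == "siamese":
        units = np.column_stack(np.triu_indices(n, k=1))
    else:
        units = table.ijkl

    ss = np.random.SeedSequence(seed)
    init_seed, drop_seed, shuffle_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    model = SequenceEncoder(
        length=X.shape[2], seed=init_seed, **(model_kwargs or {})
    )
    drop_rng = np.random.default_rng(drop_seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    opt = Adam(model.params, lr=lr)
    log = TrainingLog(
        config={
            "loss": loss_cfg.kind,
            "sigma": loss_cfg.sigma,
            "epochs": epochs,
            "lr": lr,
            "batch_size": batch_size,
            "model": model.config(),
        },
        seed=seed,
    )

    def batch_grad(D: np.ndarray, sub: np.ndarray):
        if loss_cfg.kind == "siamese":
            return siamese_pairs_grad(D, DT, sub)
        return loss_and_grad(loss_cfg, D, DT, QuartetTable(sub, n))

    def record(epoch: int) -> None:
        F = model.forward(X, train=False)
        D = pairwise_distances(F)
        loss, _ = loss_and_grad(loss_cfg, D, DT, table)
        log.records.append(
            EpochRecord(
                epoch=epoch,
                loss=loss,
                quartet_score=quartet_score(D, table),
                mean_norm=float(np.linalg.norm(F, axis=1).mean()),
            )
        )

    record(0)
    for epoch in range(1, epochs + 1):
        order = shuffle_rng.permutation(len(units))
        for start in range(0, len(units), batch_size):
            sub = units[order[start : start + batch_size]]
            F, cache = model.forward(X, train=True, rng=drop_rng, want_cache=True)
            D = pairwise_distances(F)
            _, G = batch_grad(D, sub)
            dF = _distance_grad_to_features(F, D, G)
            grads = model.backward(cache, dF)
            opt.step(model.params, grads)
        record(epoch)
    return model, log


def detect_collapse(log: TrainingLog, norm_tol: float = 1e-3) -> Optional[int]:
    """First epoch whose mean latent norm falls below ``norm_tol``, or None."""
    for rec in log.records:
        if rec.mean_norm < norm_tol:
            return rec.epoch
    return None


def run_replicates(
    tree: ReferenceTree,
    sequences: Mapping[str, str],
    loss_cfg: LossConfig,
    n_models: int = 10,
    base_seed: int = 0,
    epochs: int = 100,
    lr: float = 7e-3,
    batch_size: int = 64,
    model_kwargs: Optional[dict] = None,
    return_models: bool = False,
):
    """Train independent replicate models with seeds base_seed + 0..n-1."""
    table = enumerate_quartets(tree)
    models, logs = [], []
    for r in range(n_models):
        model, log = train(
            tree, sequences, loss_cfg, epochs=epochs, lr=lr,
            seed=base_seed + r, batch_size=batch_size,
            model_kwargs=model_kwargs, table=table,
        )
        models.append(model)
        logs.append(log)
    return (models, logs) if return_models else logs


def replicate_summary(logs: list[TrainingLog]) -> pd.DataFrame:
    """Per-epoch quartet-score summary (median, min, max) across replicates."""
    scores = np.stack([log.scores for log in logs])
    return pd.DataFrame(
        {
            "epoch": np.arange(scores.shape[1]),
            "score_median": np.median(scores, axis=0),
            "score_min": scores.min(axis=0),
            "score_max": scores.max(axis=0),
        }
    )


def export_distances(D: DistanceMatrix, path, fmt: str = "nexus") -> dict[str, str]:
    """Write a distance matrix as NEXUS (SplitsTree-loadable) or PHYLIP."""
    if fmt == "nexus":
        return write_nexus(D, path)
    if fmt == "phylip":
        return write_phylip(D, path)
    raise ValueError(f"unknown format {fmt!r}; choose 'nexus' or 'phylip'")
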