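"""Trainable objectives on latent distance matrices.

Three losses drive the encoder toward a tree-consistent latent space:

* **siamese** — mean absolute deviation between latent distances ``D_theta``
  and the patristic distances ``D_T`` of the reference tree, over the
  n(n-1)/2 unordered pairs.  Requires branch lengths and ties the latent
  geometry to them.
* **quartet** — mean of ``e^2`` over the tree's quartet splits, where
  ``e = (D(i,l)+D(j,k)-D(i,k)-D(j,l))/2`` is the non-tree-like box side of
  the splits diagram.  Topology-only, but admits the trivial all-zero
  minimizer (model collapse).
* **quartet + sigma * siamese** — the quartet loss regularized by a
  per-quartet siamese term (mean |D_theta - D_T| over each quartet's six
  within-quartet pairs, averaged over quartets), weighted by ``sigma``.
  Because each pair occurs in many quartets, pairs are implicitly reweighted
  by their quartet multiplicity; this follows the per-quartet indexing of
  the objective and is documented rather than corrected.

All reductions are means so gradient scales are comparable across taxon
counts.  Each ``*_grad`` function returns the loss together with a symmetric
matrix ``G`` with ``G[i, j] = d loss / d D[i, j]`` for the unordered pair
{i, j}; these analytic gradients are what the trainer backpropagates and are
checked against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quartets import QuartetTable

__all__ = [
    "LossConfig",
    "siamese_loss",
    "quartet_loss",
    "combined_loss",
    "siamese_loss_grad",
    "quartet_loss_grad",
    "combined_loss_grad",
    "loss_and_grad",
]

_KINDS = ("siamese", "quartet", "quartet_plus_siamese")
_ALIASES = {"qs": "quartet_plus_siamese", "q+s": "quartet_plus_siamese"}


@dataclass(frozen=True)
class LossConfig:
    """Loss selection: kind and the siamese weight sigma (combined loss only)."""

    kind: str = "quartet_plus_siamese"
    sigma: float = 0.1

    def __post_init__(self):
        kind = _ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in _KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {_KINDS}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def needs_branch_lengths(self) -> bool:
        return self.kind != "quartet"


def _values(D) -> np.ndarray:
    return D.values if hasattr(D, "values") else np.asarray(D, dtype=float)


def _check_pair(Dt: np.ndarray, DT: np.ndarray) -> None:
    if Dt.shape != DT.shape:
        raise ValueError(f"shape mismatch: {Dt.shape} vs {DT.shape}")


def siamese_loss(D_theta, D_T) -> float:
    """Mean |D_theta - D_T| over unordered taxon pairs."""
    Dt, DT = _values(D_theta), _values(D_T)
    _check_pair(Dt, DT)
    iu = np.triu_indices(Dt.shape[0], k=1)
    return float(np.abs(Dt[iu] - DT[iu]).mean())


def siamese_loss_grad(D_theta, D_T):
    Dt, DT = _values(D_theta), _values(D_T)
    _check_pair(Dt, DT)
    n = Dt.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = Dt[iu] - DT[iu]
    G = np.zeros_like(Dt)
    G[iu] = np.sign(diff) / len(diff)
    return float(np.abs(diff).mean()), G + G.T


def siamese_pairs_grad(D_theta, D_T, pairs: np.ndarray):
    """Siamese loss and gradient restricted to a subset of unordered pairs.

    ``pairs`` is a (k, 2) index array; the loss is the mean |D_theta - D_T|
    over those pairs.  This is the per-step objective when the siamese loss
    is trained pair-wise in minibatches.
    """
    Dt, DT = _values(D_theta), _values(D_T)
    _check_pair(Dt, DT)
    a, b = np.asarray(pairs, dtype=np.int64).T
    diff = Dt[a, b] - DT[a, b]
    G = np.zeros_like(Dt)
    np.add.at(G, (a, b), np.sign(diff) / len(a))
    return float(np.abs(diff).mean()), G + G.T


def quartet_loss(D_theta, table: QuartetTable) -> float:
    """Mean e^2 over the quartet splits of the reference tree."""
    if len(table) == 0:
        raise ValueError("empty quartet table")
    V = _values(D_theta)
    i, j, k, l = table.ijkl.T
    e = 0.5 * (V[i, l] + V[j, k] - V[i, k] - V[j, l])
    return float((e**2).mean())


def quartet_loss_grad(D_theta, table: QuartetTable):
    if len(table) == 0:
        raise ValueError("empty quartet table")
    V = _values(D_theta)
    i, j, k, l = table.ijkl.T
    e = 0.5 * (V[i, l] + V[j, k] - V[i, k] - V[j, l])
    m = len(e)
    G = np.zeros_like(V)
    w = e / m  # d mean(e^2) / d D[i,l] = 2 e * (1/2) / m
    np.add.at(G, (i, l), w)
    np.add.at(G, (j, k), w)
    np.add.at(G, (i, k), -w)
    np.add.at(G, (j, l), -w)
    return float((e**2).mean()), G + G.T


def _quartet_siamese_term(Dt, DT, table):
    """Mean over quartets of the mean |D_theta - D_T| over their 6 pairs."""
    i, j, k, l = table.ijkl.T
    pairs = [(i, j), (i, k), (i, l), (j, k), (j, l), (k, l)]
    total = 0.0
    for a, b in pairs:
        total += np.abs(Dt[a, b] - DT[a, b]).sum()
    return total / (6 * len(i))


def combined_loss(D_theta, D_T, table: QuartetTable, sigma: float = 0.1) -> float:
    """Quartet loss plus sigma times the per-quartet siamese term."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    Dt, DT = _values(D_theta), _values(D_T)
    _check_pair(Dt, DT)
    return quartet_loss(Dt, table) + sigma * _quartet_siamese_term(Dt, DT, table)


def combined_loss_grad(D_theta, D_T, table: QuartetTable, sigma: float = 0.1):
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    Dt, DT = _values(D_theta), _values(D_T)
    _check_pair(Dt, DT)
    q, Gq = quartet_loss_grad(Dt, table)
    i, j, k, l = table.ijkl.T
    m = len(i)
    Gs = np.zeros_like(Dt)
    total = 0.0
    for a, b in [(i, j), (i, k), (i, l), (j, k), (j, l), (k, l)]:
        diff = Dt[a, b] - DT[a, b]
        total += np.abs(diff).sum()
        np.add.at(Gs, (a, b), np.sign(diff) / (6 * m))
    return q + sigma * total / (6 * m), Gq + sigma * (Gs + Gs.T)


def loss_and_grad(cfg: LossConfig, D_theta, D_T, table: QuartetTable):
    """Dispatch on the configured loss; returns (loss, dloss/dD matrix)."""
    if cfg.kind == "siamese":
        return siamese_loss_grad(D_theta, D_T)
    if cfg.kind == "quartet":
        return quartet_loss_grad(D_theta, table)
    return combined_loss_grad(D_theta, D_T, table, cfg.sigma)
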