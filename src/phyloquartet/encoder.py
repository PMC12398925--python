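"""One-hot sequence encoding and the convolutional feature extractor.

The encoder ``h_theta`` maps a one-hot encoded nucleotide sequence (4 x L)
to an s-dimensional nonnegative feature vector:

    conv(30 filters, kernel 10, stride 1, valid)
    -> average pool(5, non-overlapping)
    -> dropout(20%, training only)
    -> flatten -> dense(360, ReLU) -> dense(s, ReLU)

with s = 30 by default.  The final ReLU means unused latent dimensions can
be exactly zero, which is what makes "root features" (features active on one
side of the root bipartition and exactly inactive on the other) identifiable.
Pairwise Euclidean distances between taxon feature vectors form the latent
distance matrix the losses operate on.

The network and its backward pass are implemented directly on numpy arrays;
parameters use the standard uniform fan-in initialization.  Gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "BASES",
    "EncodedSequence",
    "FeatureMatrix",
    "one_hot_encode",
    "encode_batch",
    "SequenceEncoder",
    "build_encoder",
    "embed",
    "latent_distances",
    "pairwise_distances",
    "save_model",
    "load_model",
    "read_fasta",
    "write_fasta",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class EncodedSequence:
    """One-hot encoding of one taxon's sequence (rows A, C, G, T)."""

    taxon: Optional[str]
    matrix: np.ndarray  # (4, L)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """Latent feature vectors, one row per taxon in canonical order."""

    vectors: np.ndarray  # (n, s)
    taxa: tuple[str, ...] = field(default=())


def one_hot_encode(sequence: str, taxon: Optional[str] = None) -> EncodedSequence:
    """Encode a nucleotide string as a 4 x L one-hot matrix.

    Case-insensitive; U is treated as T; N and '-' give all-zero columns.
    Any other character raises with its position.
    """
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    M = np.zeros((4, L))
    for pos, ch in enumerate(seq):
        if ch in _BASE_INDEX:
            M[_BASE_INDEX[ch], pos] = 1.0
        elif ch not in ("N", "-"):
            raise ValueError(
                f"invalid character {sequence[pos]!r} at position {pos} "
                f"(alphabet: A,C,G,T,U,N,-)"
            )
    return EncodedSequence(taxon, M)


def encode_batch(sequences: Mapping[str, str]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode a taxon->sequence mapping into an (n, 4, L) array.

    Taxa are sorted by label (canonical order); all sequences must have
    equal length.
    """
    taxa = tuple(sorted(sequences))
    lengths = {len(sequences[t]) for t in taxa}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    X = np.stack([one_hot_encode(sequences[t], t).matrix for t in taxa])
    return X, taxa


class SequenceEncoder:
    """Convolutional encoder mapping (4, L) one-hot inputs to s-vectors.

    Parameters
    ----------
    length
        Input sequence length L (must be >= kernel_size).
    latent_dim
        Output feature dimension s.
    extra_hidden
        If True, use two 360-unit hidden layers instead of one (the
        alternative reading of the fully connected stack).
    seed
        Seed for the parameter initialization.
    """

    def __init__(
        self,
        length: int,
        latent_dim: int = 30,
        n_filters: int = 30,
        kernel_size: int = 10,
        pool_size: int = 5,
        dropout: float = 0.2,
        hidden: int = 360,
        extra_hidden: bool = False,
        seed: int = 0,
    ):
        if length < kernel_size:
            raise ValueError(
                f"sequence length {length} is shorter than the convolution "
                f"kernel ({kernel_size})"
            )
        self.length = length
        self.latent_dim = latent_dim
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dropout = dropout
        self.hidden = hidden
        self.extra_hidden = extra_hidden
        self.seed = seed

        self.conv_positions = length - kernel_size + 1
        self.pooled = self.conv_positions // pool_size
        if self.pooled < 1:
            raise ValueError("sequence too short for the pooling window")
        self.flat = n_filters * self.pooled

        rng = np.random.default_rng(seed)

        def uinit(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        fan_conv = 4 * kernel_size
        self.params: dict[str, np.ndarray] = {
            "Wc": uinit((n_filters, 4, kernel_size), fan_conv),
            "bc": uinit((n_filters,), fan_conv),
            "W1": uinit((hidden, self.flat), self.flat),
            "b1": uinit((hidden,), self.flat),
        }
        top_in = hidden
        if extra_hidden:
            self.params["W2"] = uinit((hidden, hidden), hidden)
            self.params["b2"] = uinit((hidden,), hidden)
        self.params["Wo"] = uinit((latent_dim, top_in), top_in)
        self.params["bo"] = uinit((latent_dim,), top_in)

    # ------------------------------------------------------------------ #

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
        want_cache: bool = False,
    ):
        """Forward pass on a batch (n, 4, L) -> (n, s).

        In training mode inverted dropout is applied after pooling; in
        evaluation mode the pass is deterministic.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != 4 or X.shape[2] != self.length:
            raise ValueError(
                f"expected input shape (n, 4, {self.length}), got {X.shape}"
            )
        p = self.params
        windows = np.lib.stride_tricks.sliding_window_view(
            X, self.kernel_size, axis=2
        )  # (n, 4, P, K)
        C = np.einsum("ncpk,fck->nfp", windows, p["Wc"]) + p["bc"][None, :, None]
        trimmed = C[:, :, : self.pooled * self.pool_size]
        A = trimmed.reshape(X.shape[0], self.n_filters, self.pooled, self.pool_size)
        A = A.mean(axis=3)
        if train and self.dropout > 0:
            if rng is None:
                rng = np.random.default_rng()
            mask = (rng.random(A.shape) >= self.dropout) / (1.0 - self.dropout)
            A = A * mask
        else:
            mask = None
        flat = A.reshape(X.shape[0], self.flat)
        H1 = flat @ p["W1"].T + p["b1"]
        R = np.maximum(H1, 0.0)
        cache_mid = [(H1, flat)]
        if self.extra_hidden:
            H2 = R @ p["W2"].T + p["b2"]
            cache_mid.append((H2, R))
            R = np.maximum(H2, 0.0)
        Ho = R @ p["Wo"].T + p["bo"]
        F = np.maximum(Ho, 0.0)
        if not want_cache:
            return F
        cache = {
            "windows": windows,
            "mask": mask,
            "mid": cache_mid,
            "R_top": R,
            "Ho": Ho,
            "n": X.shape[0],
        }
        return F, cache

    def backward(self, cache: dict, dF: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d loss / d F into parameter gradients."""
        p = self.params
        dHo = dF * (cache["Ho"] > 0)
        grads = {
            "Wo": dHo.T @ cache["R_top"],
            "bo": dHo.sum(axis=0),
        }
        dR = dHo @ p["Wo"]
        if self.extra_hidden:
            H2, R1 = cache["mid"][1]
            dH2 = dR * (H2 > 0)
            grads["W2"] = dH2.T @ R1
            grads["b2"] = dH2.sum(axis=0)
            dR = dH2 @ p["W2"]
        H1, flat = cache["mid"][0]
        dH1 = dR * (H1 > 0)
        grads["W1"] = dH1.T @ flat
        grads["b1"] = dH1.sum(axis=0)
        dflat = dH1 @ p["W1"]
        dA = dflat.reshape(cache["n"], self.n_filters, self.pooled)
        if cache["mask"] is not None:
            dA = dA * cache["mask"]
        dtrim = np.repeat(dA / self.pool_size, self.pool_size, axis=2)
        dC = np.zeros((cache["n"], self.n_filters, self.conv_positions))
        dC[:, :, : self.pooled * self.pool_size] = dtrim
        grads["Wc"] = np.einsum("nfp,ncpk->fck", dC, cache["windows"])
        grads["bc"] = dC.sum(axis=(0, 2))
        return grads

    def config(self) -> dict:
        return {
            "length": self.length,
            "latent_dim": self.latent_dim,
            "n_filters": self.n_filters,
            "kernel_size": self.kernel_size,
            "pool_size": self.pool_size,
            "dropout": self.dropout,
            "hidden": self.hidden,
            "extra_hidden": self.extra_hidden,
            "seed": self.seed,
        }


def build_encoder(
    length: int, latent_dim: int = 30, seed: int = 0, **kwargs
) -> SequenceEncoder:
    """Construct a :class:`SequenceEncoder` with deterministic initialization."""
    return SequenceEncoder(length, latent_dim=latent_dim, seed=seed, **kwargs)


def embed(
    model: SequenceEncoder,
    sequences: Mapping[str, str] | Sequence[EncodedSequence],
) -> FeatureMatrix:
    """Evaluation-mode feature vectors for a set of taxa (canonical order)."""
    if isinstance(sequences, Mapping):
        X, taxa = encode_batch(sequences)
    else:
        taxa = tuple(s.taxon for s in sequences)
        X = np.stack([s.matrix for s in sequences])
    if X.shape[2] != model.length:
        raise ValueError(
            f"sequence length {X.shape[2]} does not match model length "
            f"{model.length}"
        )
    return FeatureMatrix(model.forward(X, train=False), taxa)


def pairwise_distances(vectors: np.ndarray) -> np.ndarray:
    """Euclidean distances between rows (plain array form)."""
    diff = vectors[:, None, :] - vectors[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return D


def latent_distances(F: FeatureMatrix):
    """Euclidean distance matrix between taxon feature vectors."""
    from .distances import DistanceMatrix

    return DistanceMatrix(pairwise_distances(np.asarray(F.vectors, dtype=float)), F.taxa)


# ---------------------------------------------------------------------- #
# persistence and FASTA I/O


def save_model(model: SequenceEncoder, path) -> None:
    """Save architecture and parameters to a .npz checkpoint."""
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(model.config()).encode(), dtype=np.uint8
        ),
        **model.params,
    )


def load_model(path) -> SequenceEncoder:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        model = SequenceEncoder(**cfg)
        for key in model.params:
            model.params[key] = data[key]
    return model


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a taxon -> sequence dict (IDs must be unique)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(sequences):
            fh.write(f">{taxon}\n{sequences[taxon]}\n")
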